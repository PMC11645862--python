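"""Contact extraction, interface statistics, avg_models, pDockQ, flags."""

import math

import numpy as np
import pytest

from foldscreen import (
    ConfidenceSpec,
    ContactParams,
    InterfaceSpec,
    avg_models_score,
    confidence_calls,
    extract_contacts,
    interface_stats,
    make_confidence,
    make_interface_pair,
    pdockq,
    score_pair,
)
from foldscreen.errors import ParamsMismatchError, SingleChainError
from foldscreen.interface import Contact, ContactSet, InterfaceMetrics
from foldscreen.model import (
    Atom,
    Chain,
    ConfidenceBundle,
    Residue,
    StructureModel,
    build_residue_index,
)
from tests.oracles import (
    avg_models_enumeration,
    brute_force_contacts,
    pdockq_interface_reference,
    pdockq_reference,
)


def pair_at(distance: float, plddt=(90.0, 90.0), pae=(5.0, 5.0)):
    """Two single-residue chains separated by `distance` along x, with
    fixed confidence values."""
    a = Residue("A", 1, "GLY", [Atom("CA", "C", np.array([0.0, 0.0, 0.0]))])
    b = Residue("B", 1, "GLY", [Atom("CA", "C", np.array([distance, 0.0, 0.0]))])
    model = StructureModel("m", [Chain("A", [a]), Chain("B", [b])])
    idx = build_residue_index(model)
    pae_m = np.full((2, 2), 30.0)
    pae_m[0, 1], pae_m[1, 0] = pae
    np.fill_diagonal(pae_m, 0.0)
    conf = ConfidenceBundle(np.array(plddt, dtype=float), pae_m, idx)
    return model, conf


class TestExtractContacts:
    def test_distance_boundary_is_strict(self):
        """A pair at exactly the 5 Å cutoff is excluded; just under passes."""
        model, conf = pair_at(5.0)
        assert len(extract_contacts(model, conf)) == 0
        model, conf = pair_at(4.999)
        assert len(extract_contacts(model, conf)) == 1

    def test_plddt_boundary_is_strict(self):
        model, conf = pair_at(4.0, plddt=(50.0, 90.0))
        assert len(extract_contacts(model, conf)) == 0
        model, conf = pair_at(4.0, plddt=(50.01, 90.0))
        assert len(extract_contacts(model, conf)) == 1

    def test_pae_combine_rules(self):
        """min passes if either direction is confident; both_must_pass
        requires both; mean sits in between."""
        model, conf = pair_at(4.0, pae=(5.0, 20.0))
        assert len(extract_contacts(model, conf, ContactParams(pae_combine="min"))) == 1
        assert len(extract_contacts(model, conf, ContactParams(pae_combine="both_must_pass"))) == 0
        assert len(extract_contacts(model, conf, ContactParams(pae_combine="mean"))) == 1
        model, conf = pair_at(4.0, pae=(5.0, 28.0))
        assert len(extract_contacts(model, conf, ContactParams(pae_combine="mean"))) == 0

    def test_single_chain_raises(self):
        model, conf = pair_at(4.0)
        model.chains = model.chains[:1]
        idx = build_residue_index(model)
        conf1 = ConfidenceBundle(conf.plddt[:1], conf.pae[:1, :1], idx)
        with pytest.raises(SingleChainError):
            extract_contacts(model, conf1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("combine", ["min", "both_must_pass"])
    def test_matches_brute_force_oracle(self, seed, combine):
        """Contact sets equal the all-pairs brute-force filter exactly,
        including with noisy mid-range confidence values."""
        fix = make_interface_pair(
            InterfaceSpec(n_res_a=50, n_res_b=45, n_true_contacts=15, seed=seed)
        )
        conf = make_confidence(
            fix.model,
            fix.planted,
            ConfidenceSpec(
                interface_plddt_mean=70, interface_plddt_sd=25,
                background_plddt_mean=55, background_plddt_sd=15,
                interface_pae_mean=13, interface_pae_sd=5,
                background_pae_mean=17, background_pae_sd=5,
                seed=seed,
            ),
        )
        params = ContactParams(pae_combine=combine)
        got = extract_contacts(fix.model, conf, params).keys()
        expected = brute_force_contacts(fix.model, conf, params)
        assert got == expected

    def test_chain_order_independence(self):
        """Swapping chain labels/order leaves the contact set invariant."""
        fix = make_interface_pair(InterfaceSpec(n_res_a=20, n_res_b=20, n_true_contacts=6, seed=9))
        conf = make_confidence(fix.model, fix.planted, ConfidenceSpec(seed=9))
        keys1 = extract_contacts(fix.model, conf).keys()

        swapped = fix.model.copy()
        swapped.chains.reverse()
        idx = build_residue_index(swapped)
        n_a = len(fix.model.chains[0].residues)
        n_b = len(fix.model.chains[1].residues)
        perm = list(range(n_a, n_a + n_b)) + list(range(n_a))
        conf2 = ConfidenceBundle(conf.plddt[perm], conf.pae[np.ix_(perm, perm)], idx)
        assert extract_contacts(swapped, conf2).keys() == keys1

    def test_recorded_thresholds_hold_for_every_contact(self, planted_pair):
        fix, conf = planted_pair
        params = ContactParams()
        cs = extract_contacts(fix.model, conf, params)
        assert len(cs) > 0
        for c in cs.contacts:
            assert c.min_distance < params.distance_cutoff
            assert c.plddt_a > params.plddt_min and c.plddt_b > params.plddt_min
            assert params.combine_pae(c.pae_ab, c.pae_ba) < params.pae_max
            assert c.residue_a < c.residue_b


class TestInterfaceStats:
    def test_single_contact_mean(self):
        cs = ContactSet(
            "m", ContactParams(),
            [Contact(("A", 1), ("B", 1), 4.0, 80.0, 60.0, 6.0, 10.0)],
        )
        n, avg_plddt, avg_pae = interface_stats(cs)
        assert n == 1
        assert avg_plddt == pytest.approx(70.0)
        assert avg_pae == pytest.approx(6.0)  # min combine rule

    def test_empty_set_undefined(self):
        n, avg_plddt, avg_pae = interface_stats(ContactSet("m", ContactParams(), []))
        assert n == 0
        assert math.isnan(avg_plddt) and math.isnan(avg_pae)

    def test_matches_recomputation_from_raw_vectors(self, planted_pair):
        """Stats agree with direct recomputation from pLDDT/PAE arrays."""
        fix, conf = planted_pair
        params = ContactParams()
        cs = extract_contacts(fix.model, conf, params)
        n, avg_plddt, avg_pae = interface_stats(cs)
        keys = sorted(cs.keys())
        exp_plddt = np.mean([
            (conf.plddt_of(*a) + conf.plddt_of(*b)) / 2 for a, b in keys
        ])
        exp_pae = np.mean([
            min(conf.pae_of(a, b), conf.pae_of(b, a)) for a, b in keys
        ])
        assert n == len(keys)
        assert avg_plddt == pytest.approx(exp_plddt)
        assert avg_pae == pytest.approx(exp_pae)

    def test_unique_residue_averaging_option(self):
        contacts = [
            Contact(("A", 1), ("B", 1), 4.0, 80.0, 60.0, 5.0, 5.0),
            Contact(("A", 1), ("B", 2), 4.0, 80.0, 100.0, 5.0, 5.0),
        ]
        cs = ContactSet("m", ContactParams(), contacts)
        _, pair_mean, _ = interface_stats(cs)
        _, uniq_mean, _ = interface_stats(cs, unique_residues=True)
        assert pair_mean == pytest.approx((70 + 90) / 2)
        assert uniq_mean == pytest.approx((80 + 60 + 100) / 3)


def contact_set_from_keys(keys, params=ContactParams()):
    return ContactSet(
        "m", params,
        [Contact(a, b, 4.0, 90.0, 90.0, 5.0, 5.0) for a, b in keys],
    )


class TestAvgModels:
    def test_identical_sets_give_one(self):
        keys = [(("A", i), ("B", i)) for i in range(1, 8)]
        sets = [contact_set_from_keys(keys) for _ in range(5)]
        assert avg_models_score(sets) == 1.0

    def test_single_contact_in_one_of_five(self):
        sets = [contact_set_from_keys([])] * 4 + [
            contact_set_from_keys([(("A", 1), ("B", 1))])
        ]
        assert avg_models_score(sets) == pytest.approx(0.2)

    def test_empty_union_is_zero(self):
        assert avg_models_score([contact_set_from_keys([])] * 5) == 0.0

    def test_mismatched_params_raise(self):
        s1 = contact_set_from_keys([], ContactParams())
        s2 = contact_set_from_keys([], ContactParams(pae_max=10.0))
        with pytest.raises(ParamsMismatchError):
            avg_models_score([s1, s2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [(("A", i), ("B", i + rng.integers(0, 3))) for i in range(1, 30)]
        key_sets = []
        for _ in range(4):
            mask = rng.random(len(universe)) < 0.5
            key_sets.append({k for k, m in zip(universe, mask) if m})
        sets = [contact_set_from_keys(sorted(s)) for s in key_sets]
        got = avg_models_score(sets)
        assert got == pytest.approx(avg_models_enumeration(key_sets, 4))
        assert 0.0 <= got <= 1.0

    def test_duplicating_a_model_changes_nothing(self):
        keys1 = [(("A", 1), ("B", 1)), (("A", 2), ("B", 3))]
        keys2 = [(("A", 1), ("B", 1))]
        sets = [contact_set_from_keys(keys1), contact_set_from_keys(keys2)]
        base = avg_models_score(sets)
        # adding a model identical to an existing one rescales count and M
        # together only when all models are duplicated
        doubled = [contact_set_from_keys(keys1)] * 2 + [contact_set_from_keys(keys2)] * 2
        assert avg_models_score(doubled) == pytest.approx(base)

    def test_removing_a_contact_never_increases(self):
        keys1 = [(("A", 1), ("B", 1)), (("A", 2), ("B", 3))]
        keys2 = [(("A", 1), ("B", 1)), (("A", 2), ("B", 3))]
        full = avg_models_score([contact_set_from_keys(keys1), contact_set_from_keys(keys2)])
        reduced = avg_models_score(
            [contact_set_from_keys(keys1), contact_set_from_keys(keys2[:1])]
        )
        assert reduced <= full


class TestPdockq:
    def test_no_contacts_is_exactly_zero(self):
        model, conf = pair_at(9.5)  # beyond the 8 Å pDockQ cutoff
        assert pdockq(model, conf) == 0.0

    def test_score_strictly_increasing_in_x(self):
        """Larger x = <pLDDT> * ln(contacts) always gives a larger score."""
        plddts = np.linspace(20, 100, 30)
        scores = [pdockq_reference(p, 50) for p in plddts]
        assert all(b > a for a, b in zip(scores, scores[1:]))
        by_contacts = [pdockq_reference(80.0, n) for n in (2, 5, 20, 100, 500)]
        assert all(b > a for a, b in zip(by_contacts, by_contacts[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        """Pipeline pDockQ equals the naive census + direct sigmoid."""
        fix = make_interface_pair(
            InterfaceSpec(n_res_a=40, n_res_b=40, n_true_contacts=10, seed=seed)
        )
        conf = make_confidence(fix.model, fix.planted, ConfidenceSpec(seed=seed))
        expected, n_ref = pdockq_interface_reference(fix.model, conf)
        assert n_ref > 0
        assert pdockq(fix.model, conf) == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= pdockq(fix.model, conf) <= 1.0


class TestConfidenceCalls:
    def metrics(self, **kw):
        base = dict(
            pair_id="p", n_models=5, n_contacts=10, per_model_n_contacts=[10] * 5,
            avg_plddt=82.7, avg_pae=3.8, avg_models=0.86, pdockq=0.5,
        )
        base.update(kw)
        return InterfaceMetrics(**base)

    def test_confident_interface_all_flags(self):
        """The headline confident complex (pLDDT 82.7, avg_models 0.86)
        passes every structural criterion."""
        flags = confidence_calls(self.metrics())
        assert flags == {"avg_plddt": True, "avg_models": True, "pdockq": True}

    @pytest.mark.parametrize(
        "field,value,flag",
        [
            ("avg_plddt", 70.0, False), ("avg_plddt", 70.01, True),
            ("avg_models", 0.5, False), ("avg_models", 0.51, True),
            ("pdockq", 0.23, False), ("pdockq", 0.231, True),
        ],
    )
    def test_boundaries_are_strict(self, field, value, flag):
        assert confidence_calls(self.metrics(**{field: value}))[field] is flag

    def test_classifier_flag_only_when_scored(self):
        assert "classifier" not in confidence_calls(self.metrics())
        flags = confidence_calls(self.metrics(classifier_score=0.5))
        assert flags["classifier"] is False
        flags = confidence_calls(self.metrics(classifier_score=0.51))
        assert flags["classifier"] is True

    def test_nan_never_passes(self):
        flags = confidence_calls(self.metrics(avg_plddt=float("nan")))
        assert flags["avg_plddt"] is False


class TestScorePair:
    def test_single_model_equals_its_stats(self, planted_pair):
        fix, conf = planted_pair
        cs = extract_contacts(fix.model, conf)
        n, avg_plddt, avg_pae = interface_stats(cs)
        m = score_pair([fix.model], [conf])
        assert (m.n_models, m.n_contacts) == (1, n)
        assert m.avg_plddt == pytest.approx(avg_plddt)
        assert m.avg_pae == pytest.approx(avg_pae)
        assert m.avg_models == 1.0  # every contact present in the only model
        assert m.pdockq == pytest.approx(pdockq(fix.model, conf))

    def test_pipeline_equals_stage_by_stage(self):
        """score_pair's fields equal the manual composition of stages."""
        from foldscreen import EnsembleSpec, make_ensemble

        ens = make_ensemble(
            InterfaceSpec(n_res_a=30, n_res_b=30, n_true_contacts=10, seed=5),
            ConfidenceSpec(seed=5),
            EnsembleSpec(seed=5, reproducibility=0.6),
        )
        m = score_pair(ens.models, ens.confs, pair_id="pair")
        sets = [extract_contacts(mo, co) for mo, co in zip(ens.models, ens.confs)]
        stats = [interface_stats(s) for s in sets]
        rep = min(
            range(len(sets)),
            key=lambda i: (-(stats[i][1] if not math.isnan(stats[i][1]) else -math.inf),
                           ens.models[i].model_id),
        )
        assert m.avg_models == pytest.approx(avg_models_score(sets))
        assert m.n_contacts == stats[rep][0]
        assert m.avg_plddt == pytest.approx(stats[rep][1])
        assert m.pdockq == pytest.approx(pdockq(ens.models[rep], ens.confs[rep]))
        assert m.per_model_n_contacts == [s[0] for s in stats]

    def test_full_reproducibility_gives_avg_models_one(self):
        from foldscreen import EnsembleSpec, make_ensemble

        ens = make_ensemble(
            InterfaceSpec(n_res_a=25, n_res_b=25, n_true_contacts=8, seed=6),
            ConfidenceSpec(seed=6),
            EnsembleSpec(seed=6, reproducibility=1.0),
        )
        assert score_pair(ens.models, ens.confs).avg_models == 1.0

    def test_classifier_hook_invoked(self, planted_pair):
        fix, conf = planted_pair
        seen = {}

        def scorer(metrics, models):
            seen["pair"] = metrics.pair_id
            return 0.9

        m = score_pair([fix.model], [conf], classifier=scorer, pair_id="xy")
        assert seen["pair"] == "xy"
        assert m.classifier_score == 0.9
        assert m.flags["classifier"] is True
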