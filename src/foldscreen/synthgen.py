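"""Deterministic synthetic fixtures for the interface-analysis pipeline.

Generates two-chain (or k-chain) models with a *planted* interface — a
chosen number of residue pairs whose minimum heavy-atom distance sits in a
requested range while every other inter-chain pair stays well beyond the
contact cutoff — plus confidence annotations (pLDDT / PAE) drawn from
separate interface and background distributions, ensembles of M models
with controllable contact reproducibility, and whole screens with planted
true interactors among decoys.

Geometry is an idealised coarse trace (two pseudo-atoms per residue on a
regular spacing), not stereochemically valid protein: only inter-residue
distances and confidence values matter to the analysis under test.
Everything is seeded and reproducible; the same seed yields byte-identical
fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeneratorError
from .interface import ContactParams
from .model import (
    Atom,
    Chain,
    ConfidenceBundle,
    Residue,
    StructureModel,
    build_residue_index,
)
from .structio import stamp_plddt_bfactors, write_confidence, write_structure

__all__ = [
    "InterfaceSpec",
    "ConfidenceSpec",
    "EnsembleSpec",
    "InterfacePairFixture",
    "EnsembleFixture",
    "make_interface_pair",
    "make_confidence",
    "make_ensemble",
    "make_screen",
]

_RES_SPACING = 8.0     # Å between consecutive residues along the trace
_CB_OFFSET = 1.5       # Å pseudo-CB offset perpendicular to the trace
_FAR_OFFSET = 20.0     # Å separation of non-contacting inter-chain residues
_PAE_CAP = 35.0        # Å cap applied to generated PAE values


@dataclass(frozen=True)
class InterfaceSpec:
    """Geometry of a planted two-chain interface."""

    n_res_a: int = 60
    n_res_b: int = 60
    n_true_contacts: int = 20
    contact_distance_range: tuple[float, float] = (3.5, 4.5)  # Å min-distance
    backbone_style: str = "extended"   # extended | helical
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_a < 1 or self.n_res_b < 1:
            raise GeneratorError("chains must have at least one residue")
        if self.n_true_contacts > min(self.n_res_a, self.n_res_b):
            raise GeneratorError(
                "n_true_contacts cannot exceed the shorter chain length"
            )
        lo, hi = self.contact_distance_range
        if not (0 < lo <= hi):
            raise GeneratorError("contact distance range must satisfy 0 < lo <= hi")
        if self.backbone_style not in ("extended", "helical"):
            raise GeneratorError(f"unknown backbone_style {self.backbone_style!r}")


@dataclass(frozen=True)
class ConfidenceSpec:
    """Interface-vs-background confidence distributions.

    Defaults emulate a confident predicted interface (high pLDDT, low
    inter-chain PAE at planted pairs) over an uncertain background.
    """

    interface_plddt_mean: float = 90.0
    interface_plddt_sd: float = 4.0
    background_plddt_mean: float = 60.0
    background_plddt_sd: float = 10.0
    interface_pae_mean: float = 5.0
    interface_pae_sd: float = 2.0
    background_pae_mean: float = 25.0
    background_pae_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sd in (
            self.interface_plddt_sd,
            self.background_plddt_sd,
            self.interface_pae_sd,
            self.background_pae_sd,
        ):
            if sd < 0:
                raise GeneratorError("standard deviations must be >= 0")
        for mean in (self.interface_plddt_mean, self.background_plddt_mean):
            if not 0 <= mean <= 100:
                raise GeneratorError("pLDDT means must lie in [0, 100]")
        for mean in (self.interface_pae_mean, self.background_pae_mean):
            if mean < 0:
                raise GeneratorError("PAE means must be >= 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble of M models with controllable contact reproducibility.

    ``reproducibility`` p is the per-model inclusion probability of each
    true contact.  With the default ``stratified`` sampling each contact
    is reproduced in floor(pM) or ceil(pM) models (stochastic rounding,
    model subset chosen uniformly), which keeps the realized ensemble-
    agreement score unbiased for p; ``bernoulli`` draws each
    (contact, model) inclusion independently instead.
    ``decoy_rate`` is the expected number of spurious confident contacts
    per model, drawn from a planted pool of decoy-able pairs.
    """

    n_models: int = 5
    reproducibility: float = 0.9
    decoy_rate: float = 0.0
    sampling: str = "stratified"   # stratified | bernoulli
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise GeneratorError("ensemble needs at least one model")
        if not 0.0 <= self.reproducibility <= 1.0:
            raise GeneratorError("reproducibility must lie in [0, 1]")
        if self.decoy_rate < 0:
            raise GeneratorError("decoy_rate must be >= 0")
        if self.sampling not in ("stratified", "bernoulli"):
            raise GeneratorError(f"unknown sampling {self.sampling!r}")


@dataclass
class InterfacePairFixture:
    model: StructureModel
    planted: list[tuple[tuple[str, int], tuple[str, int]]]  # canonical residue pairs


def _trace_z(i: int, style: str) -> float:
    # helical style adds a cosmetic z-wobble; contact distances are
    # unaffected because partners are placed relative to the wobbled trace
    if style == "helical":
        return 2.0 * math.sin(2.0 * math.pi * i / 3.6)
    return 0.0


def _make_residue(chain_id: str, resnum: int, ca: np.ndarray) -> Residue:
    cb = ca + np.array([0.0, 0.0, _CB_OFFSET])
    return Residue(
        chain_id=chain_id,
        resnum=resnum,
        resname="ALA",
        atoms=[Atom("CA", "C", ca.copy()), Atom("CB", "C", cb)],
    )


def make_interface_pair(spec: InterfaceSpec) -> InterfacePairFixture:
    """Two-chain model with exactly ``n_true_contacts`` planted contacts.

    Chain A runs along x with one residue per 8 Å; chain B mirrors it at
    a 20 Å offset in y except at the planted positions, where the partner
    residue is placed so the pair's minimum heavy-atom distance falls in
    ``contact_distance_range``.  Every non-planted inter-chain residue
    pair is at least 2 Å beyond the default 5 Å contact cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = min(spec.n_res_a, spec.n_res_b)
    planted_idx = np.sort(
        rng.choice(n_shared, size=spec.n_true_contacts, replace=False)
    )
    lo, hi = spec.contact_distance_range
    planted_d = rng.uniform(lo, hi, size=spec.n_true_contacts)

    chain_a = Chain("A", entity_kind="protein")
    for i in range(spec.n_res_a):
        ca = np.array([i * _RES_SPACING, 0.0, _trace_z(i, spec.backbone_style)])
        chain_a.residues.append(_make_residue("A", i + 1, ca))

    contact_d = {int(i): float(d) for i, d in zip(planted_idx, planted_d)}
    chain_b = Chain("B", entity_kind="protein")
    for i in range(spec.n_res_b):
        if i in contact_d:
            # place relative to A's residue so the CA–CA (and CB–CB)
            # separation is exactly the requested minimum distance
            base = chain_a.residues[i].atoms[0].xyz
            ca = base + np.array([0.0, contact_d[i], 0.0])
        else:
            ca = np.array(
                [i * _RES_SPACING, _FAR_OFFSET, _trace_z(i, spec.backbone_style)]
            )
        chain_b.residues.append(_make_residue("B", i + 1, ca))

    model = StructureModel(
        model_id=f"pair_seed{spec.seed}",
        chains=[chain_a, chain_b],
        metadata={"generator": "make_interface_pair", "seed": spec.seed},
    )
    model.validate()
    planted = [
        (("A", int(i) + 1), ("B", int(i) + 1)) for i in planted_idx
    ]
    return InterfacePairFixture(model=model, planted=planted)


def make_confidence(
    model: StructureModel,
    planted: list[tuple[tuple[str, int], tuple[str, int]]],
    spec: ConfidenceSpec = ConfidenceSpec(),
) -> ConfidenceBundle:
    """Confidence bundle with interface-vs-background statistics.

    Residues participating in planted contacts draw pLDDT from the
    interface distribution, everything else from the background; the PAE
    matrix is background everywhere except at planted pairs, with
    independent draws in each direction (real PAE is asymmetric).
    Values are clipped to legal ranges and rounded to 2 decimals, the
    precision the file formats carry.
    """
    rng = np.random.default_rng(spec.seed)
    index = build_residue_index(model)
    n = index.n_residues

    interface_res = set()
    for a, b in planted:
        interface_res.add(index.global_index(*a))
        interface_res.add(index.global_index(*b))

    plddt = rng.normal(spec.background_plddt_mean, spec.background_plddt_sd, size=n)
    for gi in interface_res:
        plddt[gi] = rng.normal(spec.interface_plddt_mean, spec.interface_plddt_sd)
    plddt = np.clip(plddt, 0.0, 100.0)

    pae = rng.normal(spec.background_pae_mean, spec.background_pae_sd, size=(n, n))
    for a, b in planted:
        gi, gj = index.global_index(*a), index.global_index(*b)
        pae[gi, gj] = rng.normal(spec.interface_pae_mean, spec.interface_pae_sd)
        pae[gj, gi] = rng.normal(spec.interface_pae_mean, spec.interface_pae_sd)
    np.fill_diagonal(pae, 0.0)
    pae = np.clip(pae, 0.0, _PAE_CAP)

    bundle = ConfidenceBundle(
        plddt=np.round(plddt, 2), pae=np.round(pae, 2), index=index
    )
    bundle.validate(model)
    return bundle


@dataclass
class EnsembleFixture:
    models: list[StructureModel]
    confs: list[ConfidenceBundle]
    true_contacts: list[tuple[tuple[str, int], tuple[str, int]]]
    decoy_pool: list[tuple[tuple[str, int], tuple[str, int]]]


def _inclusion_matrix(rng: np.random.Generator, n_contacts: int, espec: EnsembleSpec) -> np.ndarray:
    """(n_contacts, M) boolean: is contact c confident in model m?"""
    m, p = espec.n_models, espec.reproducibility
    if espec.sampling == "bernoulli":
        return rng.random((n_contacts, m)) < p
    # stratified: contact appears in floor(pM) or ceil(pM) models
    out = np.zeros((n_contacts, m), dtype=bool)
    lower = math.floor(p * m)
    frac = p * m - lower
    for c in range(n_contacts):
        k = lower + (1 if rng.random() < frac else 0)
        if k > 0:
            out[c, rng.choice(m, size=min(k, m), replace=False)] = True
    return out


def make_ensemble(
    ispec: InterfaceSpec,
    cspec: ConfidenceSpec = ConfidenceSpec(),
    espec: EnsembleSpec = EnsembleSpec(),
) -> EnsembleFixture:
    """M-model ensemble over one planted interface.

    All models share the planted geometry; reproducibility is imposed
    through confidence: a true contact not 'reproduced' in a model has
    its PAE (both directions) pushed to the background level, so the
    confident-contact rule drops it there.  Decoy contacts, if requested,
    are drawn per model from a separate planted pool at rate
    ``decoy_rate``.
    """
    n_pool = 0 if espec.decoy_rate == 0 else max(4, math.ceil(4 * espec.decoy_rate))
    total = ispec.n_true_contacts + n_pool
    if total > min(ispec.n_res_a, ispec.n_res_b):
        raise GeneratorError(
            "true contacts + decoy pool exceed the shorter chain length"
        )
    geom = make_interface_pair(
        InterfaceSpec(
            n_res_a=ispec.n_res_a,
            n_res_b=ispec.n_res_b,
            n_true_contacts=total,
            contact_distance_range=ispec.contact_distance_range,
            backbone_style=ispec.backbone_style,
            seed=ispec.seed,
        )
    )
    rng = np.random.default_rng(espec.seed)
    pool_pick = (
        sorted(rng.choice(total, size=n_pool, replace=False)) if n_pool else []
    )
    pool_set = set(int(i) for i in pool_pick)
    true_contacts = [p for i, p in enumerate(geom.planted) if i not in pool_set]
    decoy_pool = [p for i, p in enumerate(geom.planted) if i in pool_set]

    include_true = _inclusion_matrix(rng, len(true_contacts), espec)
    q = espec.decoy_rate / n_pool if n_pool else 0.0
    include_decoy = rng.random((n_pool, espec.n_models)) < q

    models, confs = [], []
    index = build_residue_index(geom.model)
    hi_pae = round(max(cspec.background_pae_mean, 25.0), 2)
    for m in range(espec.n_models):
        model_m = geom.model.copy()
        model_m.model_id = f"{geom.model.model_id}_m{m}"
        conf_seed = int(rng.integers(0, 2**31 - 1))
        conf = make_confidence(
            model_m,
            geom.planted,
            ConfidenceSpec(
                interface_plddt_mean=cspec.interface_plddt_mean,
                interface_plddt_sd=cspec.interface_plddt_sd,
                background_plddt_mean=cspec.background_plddt_mean,
                background_plddt_sd=cspec.background_plddt_sd,
                interface_pae_mean=cspec.interface_pae_mean,
                interface_pae_sd=cspec.interface_pae_sd,
                background_pae_mean=cspec.background_pae_mean,
                background_pae_sd=cspec.background_pae_sd,
                seed=conf_seed,
            ),
        )
        for c, pair in enumerate(true_contacts):
            if not include_true[c, m]:
                gi, gj = index.global_index(*pair[0]), index.global_index(*pair[1])
                conf.pae[gi, gj] = hi_pae
                conf.pae[gj, gi] = hi_pae
        for c, pair in enumerate(decoy_pool):
            if not include_decoy[c, m]:
                gi, gj = index.global_index(*pair[0]), index.global_index(*pair[1])
                conf.pae[gi, gj] = hi_pae
                conf.pae[gj, gi] = hi_pae
        models.append(model_m)
        confs.append(conf)
    return EnsembleFixture(
        models=models, confs=confs, true_contacts=true_contacts, decoy_pool=decoy_pool
    )


# ---------------------------------------------------------------------------
# Whole screens


@dataclass
class ScreenFixture:
    """In-memory screen: entries of (pair_id, models, confs) plus truth."""

    bait_id: str
    entries: list[tuple[str, list[StructureModel], list[ConfidenceBundle]]]
    true_pair_ids: list[str]
    params: ContactParams = field(default_factory=ContactParams)


def make_screen(
    n_decoys: int = 100,
    n_true: int = 5,
    true_ispec: InterfaceSpec | None = None,
    cspec: ConfidenceSpec = ConfidenceSpec(),
    espec: EnsembleSpec = EnsembleSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    decoy_n_res: int = 40,
):
    """Synthetic many-pair screen with planted true interactors.

    True pairs get a strong planted interface scored across an M-model
    ensemble; decoys have no planted interface (their chains never come
    within the contact cutoff), so their confident-contact sets are
    empty.  Returns a :class:`ScreenFixture`; with ``out_dir`` set, also
    writes each model as PDB plus a scores-JSON confidence file and a
    manifest TSV, all deterministic per seed.
    """
    true_ispec = true_ispec or InterfaceSpec(n_res_a=40, n_res_b=40, n_true_contacts=20)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_true + n_decoys)]

    entries = []
    true_ids = []
    for t in range(n_true):
        s = child_seeds[t]
        fix = make_ensemble(
            InterfaceSpec(
                n_res_a=true_ispec.n_res_a,
                n_res_b=true_ispec.n_res_b,
                n_true_contacts=true_ispec.n_true_contacts,
                contact_distance_range=true_ispec.contact_distance_range,
                backbone_style=true_ispec.backbone_style,
                seed=s,
            ),
            ConfidenceSpec(
                interface_plddt_mean=cspec.interface_plddt_mean,
                interface_plddt_sd=cspec.interface_plddt_sd,
                background_plddt_mean=cspec.background_plddt_mean,
                background_plddt_sd=cspec.background_plddt_sd,
                interface_pae_mean=cspec.interface_pae_mean,
                interface_pae_sd=cspec.interface_pae_sd,
                background_pae_mean=cspec.background_pae_mean,
                background_pae_sd=cspec.background_pae_sd,
                seed=s,
            ),
            EnsembleSpec(
                n_models=espec.n_models,
                reproducibility=espec.reproducibility,
                decoy_rate=espec.decoy_rate,
                sampling=espec.sampling,
                seed=s,
            ),
        )
        pair_id = f"true_{t:03d}"
        true_ids.append(pair_id)
        entries.append((pair_id, fix.models, fix.confs))

    for d in range(n_decoys):
        s = child_seeds[n_true + d]
        fix = make_ensemble(
            InterfaceSpec(
                n_res_a=decoy_n_res, n_res_b=decoy_n_res, n_true_contacts=0, seed=s
            ),
            ConfidenceSpec(
                interface_plddt_mean=cspec.interface_plddt_mean,
                interface_plddt_sd=cspec.interface_plddt_sd,
                background_plddt_mean=cspec.background_plddt_mean,
                background_plddt_sd=cspec.background_plddt_sd,
                interface_pae_mean=cspec.interface_pae_mean,
                interface_pae_sd=cspec.interface_pae_sd,
                background_pae_mean=cspec.background_pae_mean,
                background_pae_sd=cspec.background_pae_sd,
                seed=s,
            ),
            EnsembleSpec(
                n_models=espec.n_models,
                reproducibility=espec.reproducibility,
                decoy_rate=0.0,
                sampling=espec.sampling,
                seed=s,
            ),
        )
        entries.append((f"decoy_{d:03d}", fix.models, fix.confs))

    fixture = ScreenFixture(
        bait_id=f"bait_seed{seed}", entries=entries, true_pair_ids=true_ids
    )
    if out_dir is not None:
        _write_screen(fixture, Path(out_dir))
    return fixture


def _write_screen(fixture: ScreenFixture, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["pair_id\tmodel_path\tconf_path\tdialect"]
    for pair_id, models, confs in fixture.entries:
        for m, (model, conf) in enumerate(zip(models, confs)):
            stamp_plddt_bfactors(model, conf.plddt)
            mpath = out_dir / f"{pair_id}_m{m}.pdb"
            cpath = out_dir / f"{pair_id}_m{m}_scores.json"
            write_structure(model, mpath, format="pdb")
            write_confidence(conf, cpath, dialect="scores_json")
            lines.append(f"{pair_id}\t{mpath.name}\t{cpath.name}\tscores_json")
    (out_dir / "manifest.tsv").write_text("\n".join(lines) + "\n")
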