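"""Confident inter-chain contacts and interface-confidence metrics.

The screening analysis works on predicted complex structures and asks, for
each candidate pair of proteins, whether the predicted interface looks
trustworthy.  Its primitives:

* **Confident contact** — an inter-chain residue pair whose minimum
  heavy-atom distance is strictly below a cutoff (default 5 Å) and whose
  residues are both predicted confidently: pLDDT strictly above a floor
  (default 50) and pairwise aligned error strictly below a ceiling
  (default 15 Å).
* **Interface statistics** — contact count, mean interface pLDDT, mean
  interface PAE, computed over exactly those contacts.
* **avg_models** — an ensemble-agreement score: over the union of
  confident contacts observed in M independently predicted models, the
  mean fraction of models containing each contact (0 = no agreement,
  1 = perfect agreement).
* **pDockQ** — a sigmoid-calibrated interface-accuracy estimate computed,
  deliberately independently of the contact rule above, from the mean
  pLDDT of interface residues and the log of the interface contact count
  under pDockQ's own definition (CB–CB pairs within 8 Å, CA for glycine).
* **Confidence calls** — boolean flags at the conventional thresholds:
  interface pLDDT > 70, avg_models > 0.5, pDockQ > 0.23, external
  classifier score > 0.5 (all strict).

An external classifier (e.g. a trained structure-plus-omics scorer) can be
plugged in as any callable mapping (metrics, models) -> score in [0, 1];
none ships with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParamsMismatchError, SingleChainError
from .model import ConfidenceBundle, StructureModel

__all__ = [
    "ContactParams",
    "Contact",
    "ContactSet",
    "InterfaceMetrics",
    "Thresholds",
    "extract_contacts",
    "interface_stats",
    "avg_models_score",
    "pdockq",
    "confidence_calls",
    "score_pair",
]

# Published pDockQ sigmoid: p = L / (1 + exp(-k (x - x0))) + b with
# x = <interface pLDDT> * ln(n_contacts)  (Bryant, Pozzati & Elofsson 2022).
PDOCKQ_L = 0.724
PDOCKQ_X0 = 152.611
PDOCKQ_K = 0.052
PDOCKQ_B = 0.018
PDOCKQ_CONTACT_CUTOFF = 8.0  # Å, CB–CB (CA for Gly), non-strict per reference code


@dataclass(frozen=True)
class ContactParams:
    """Thresholds defining a confident inter-chain contact.

    ``pae_combine`` reduces the two directional PAE values of a pair to
    one number: ``min`` (either direction confident), ``mean``, or
    ``both_must_pass`` (the maximum — both directions must clear the
    ceiling).  ``atom_rule`` selects which atoms define residue–residue
    distance: every heavy atom, or CB only (CA for glycine).
    """

    distance_cutoff: float = 5.0   # Å, strict <
    plddt_min: float = 50.0        # strict >
    pae_max: float = 15.0          # Å, strict < on the combined value
    pae_combine: str = "min"       # min | mean | both_must_pass
    atom_rule: str = "any_heavy"   # any_heavy | cbeta

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.plddt_min <= 0 or self.pae_max <= 0:
            raise ValueError("all thresholds must be positive")
        if self.pae_combine not in ("min", "mean", "both_must_pass"):
            raise ValueError(f"unknown pae_combine {self.pae_combine!r}")
        if self.atom_rule not in ("any_heavy", "cbeta"):
            raise ValueError(f"unknown atom_rule {self.atom_rule!r}")

    def combine_pae(self, pae_ab: float, pae_ba: float) -> float:
        if self.pae_combine == "min":
            return min(pae_ab, pae_ba)
        if self.pae_combine == "mean":
            return 0.5 * (pae_ab + pae_ba)
        return max(pae_ab, pae_ba)  # both_must_pass


@dataclass(frozen=True, order=True)
class Contact:
    """One confident inter-chain residue pair, canonically ordered
    (residue_a < residue_b by (chain_id, resnum))."""

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    min_distance: float
    plddt_a: float
    plddt_b: float
    pae_ab: float
    pae_ba: float

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.residue_a, self.residue_b)


@dataclass
class ContactSet:
    model_id: str
    params: ContactParams
    contacts: list[Contact] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contacts)

    def keys(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        return {c.key for c in self.contacts}


def _cbeta_coord(residue) -> np.ndarray | None:
    a = residue.atom("CB")
    if a is None or residue.resname == "GLY":
        a = residue.atom("CA")
    return None if a is None else a.xyz


def _residue_coord_arrays(model: StructureModel, atom_rule: str):
    """Flat atom array + per-atom residue ids, per chain."""
    per_chain = []
    for ci, chain in enumerate(model.chains):
        coords = []
        res_of_atom = []
        for ri, res in enumerate(chain.residues):
            if atom_rule == "cbeta":
                c = _cbeta_coord(res)
                arr = None if c is None else c[None, :]
            else:
                arr = res.coords()
            if arr is None:
                continue
            coords.append(arr)
            res_of_atom.extend([ri] * len(arr))
        per_chain.append(
            (
                chain,
                np.concatenate(coords) if coords else np.empty((0, 3)),
                np.asarray(res_of_atom, dtype=int),
            )
        )
    return per_chain


def extract_contacts(
    model: StructureModel,
    conf: ConfidenceBundle,
    params: ContactParams = ContactParams(),
) -> ContactSet:
    """Extract every confident inter-chain contact of a model.

    Returns exactly the inter-chain residue pairs with minimum heavy-atom
    distance strictly below ``params.distance_cutoff``, both residue
    pLDDTs strictly above ``params.plddt_min`` and combined PAE strictly
    below ``params.pae_max``.  Deterministic and independent of chain
    order (contacts are canonically ordered).
    """
    model.validate()
    conf.validate(model)
    if len(model.chains) < 2:
        raise SingleChainError(
            f"model {model.model_id!r} has a single chain: no inter-chain "
            "interface possible"
        )

    per_chain = _residue_coord_arrays(model, params.atom_rule)
    contacts: list[Contact] = []
    cutoff = params.distance_cutoff

    for i in range(len(per_chain)):
        chain_i, coords_i, res_i = per_chain[i]
        if len(coords_i) == 0:
            continue
        tree_i = cKDTree(coords_i)
        for j in range(i + 1, len(per_chain)):
            chain_j, coords_j, res_j = per_chain[j]
            if len(coords_j) == 0:
                continue
            # atom pairs within the cutoff, reduced to the minimum
            # distance per residue pair (query is <=; rule applied strictly below)
            pairs = tree_i.query_ball_tree(cKDTree(coords_j), cutoff)
            best: dict[tuple[int, int], float] = {}
            for ai, neigh in enumerate(pairs):
                if not neigh:
                    continue
                d_all = np.linalg.norm(coords_j[neigh] - coords_i[ai], axis=1)
                for aj, d in zip(neigh, d_all):
                    rp = (res_i[ai], res_j[aj])
                    if d < best.get(rp, np.inf):
                        best[rp] = float(d)
            for (ri, rj), d in best.items():
                if not (d < cutoff):  # KD query is <=; the rule is strict
                    continue
                res_a = chain_i.residues[ri]
                res_b = chain_j.residues[rj]
                ida = (chain_i.chain_id, res_a.resnum)
                idb = (chain_j.chain_id, res_b.resnum)
                pl_a = conf.plddt_of(*ida)
                pl_b = conf.plddt_of(*idb)
                if not (pl_a > params.plddt_min and pl_b > params.plddt_min):
                    continue
                pae_ab = conf.pae_of(ida, idb)
                pae_ba = conf.pae_of(idb, ida)
                if not (params.combine_pae(pae_ab, pae_ba) < params.pae_max):
                    continue
                if idb < ida:  # canonical ordering by (chain_id, resnum)
                    ida, idb = idb, ida
                    pl_a, pl_b = pl_b, pl_a
                    pae_ab, pae_ba = pae_ba, pae_ab
                contacts.append(
                    Contact(ida, idb, float(d), pl_a, pl_b, pae_ab, pae_ba)
                )
    contacts.sort()
    return ContactSet(model_id=model.model_id, params=params, contacts=contacts)


def interface_stats(contacts: ContactSet, unique_residues: bool = False):
    """(n_contacts, avg_plddt, avg_pae) of a contact set.

    By default the pLDDT average is over per-contact residue-pair means
    (a residue participating in several contacts is counted once per
    contact); ``unique_residues=True`` averages each interface residue
    once instead.  The PAE average uses the set's combine rule.  An empty
    set yields ``(0, nan, nan)``.
    """
    n = len(contacts)
    if n == 0:
        return 0, float("nan"), float("nan")
    params = contacts.params
    if unique_residues:
        seen: dict[tuple[str, int], float] = {}
        for c in contacts.contacts:
            seen[c.residue_a] = c.plddt_a
            seen[c.residue_b] = c.plddt_b
        avg_plddt = float(np.mean(list(seen.values())))
    else:
        avg_plddt = float(
            np.mean([(c.plddt_a + c.plddt_b) / 2.0 for c in contacts.contacts])
        )
    avg_pae = float(
        np.mean([params.combine_pae(c.pae_ab, c.pae_ba) for c in contacts.contacts])
    )
    return n, avg_plddt, avg_pae


def avg_models_score(contact_sets: Sequence[ContactSet]) -> float:
    """Ensemble-agreement score over M models of the same pair.

    Let U be the union of canonical contacts across the M sets; the score
    is the mean over U of (number of models containing the contact) / M.
    Empty union -> 0.  All sets must share identical extraction
    parameters.
    """
    if not contact_sets:
        raise ValueError("need at least one contact set")
    params0 = contact_sets[0].params
    for cs in contact_sets[1:]:
        if cs.params != params0:
            raise ParamsMismatchError(
                "contact sets extracted with different parameters cannot be combined"
            )
    m = len(contact_sets)
    counts: dict = {}
    for cs in contact_sets:
        for key in cs.keys():
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return 0.0
    return float(sum(counts.values()) / (len(counts) * m))


def pdockq(model: StructureModel, conf: ConfidenceBundle) -> float:
    """pDockQ interface-accuracy estimate of a predicted complex.

    Uses pDockQ's own contact definition — CB atoms (CA for glycine)
    from different chains within 8 Å — independent of the confident-
    contact rule.  x = (mean pLDDT over unique interface residues) *
    ln(number of contact pairs); the published sigmoid maps x to [0, 1].
    Returns exactly 0.0 when the interface has no contacts.
    """
    model.validate()
    conf.validate(model)
    if len(model.chains) < 2:
        raise SingleChainError(
            f"model {model.model_id!r} has a single chain: pDockQ undefined"
        )
    per_chain = _residue_coord_arrays(model, "cbeta")
    n_contacts = 0
    interface_res: set[tuple[str, int]] = set()
    for i in range(len(per_chain)):
        chain_i, coords_i, res_i = per_chain[i]
        if len(coords_i) == 0:
            continue
        tree_i = cKDTree(coords_i)
        for j in range(i + 1, len(per_chain)):
            chain_j, coords_j, res_j = per_chain[j]
            if len(coords_j) == 0:
                continue
            pairs = tree_i.query_ball_tree(cKDTree(coords_j), PDOCKQ_CONTACT_CUTOFF)
            for ai, neigh in enumerate(pairs):
                for aj in neigh:
                    n_contacts += 1
                    interface_res.add(
                        (chain_i.chain_id, chain_i.residues[res_i[ai]].resnum)
                    )
                    interface_res.add(
                        (chain_j.chain_id, chain_j.residues[res_j[aj]].resnum)
                    )
    if n_contacts == 0:
        return 0.0
    mean_plddt = float(np.mean([conf.plddt_of(*r) for r in interface_res]))
    x = mean_plddt * math.log(n_contacts)
    return PDOCKQ_L / (1.0 + math.exp(-PDOCKQ_K * (x - PDOCKQ_X0))) + PDOCKQ_B


@dataclass(frozen=True)
class Thresholds:
    """Confidence-call thresholds (all comparisons strict '>')."""

    avg_plddt: float = 70.0
    avg_models: float = 0.5
    pdockq: float = 0.23
    classifier: float = 0.5


@dataclass
class InterfaceMetrics:
    """Per-pair summary of interface confidence."""

    pair_id: str
    n_models: int
    n_contacts: int                       # of the representative model
    per_model_n_contacts: list[int]
    avg_plddt: float                      # representative model, nan if no contacts
    avg_pae: float
    avg_models: float
    pdockq: float
    classifier_score: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    representative_model_id: str = ""
    error: str | None = None              # set when the entry failed to score


def confidence_calls(
    metrics: InterfaceMetrics, thresholds: Thresholds = Thresholds()
) -> dict[str, bool]:
    """Boolean confidence flag per criterion; NaN values never pass.

    Strict inequalities at each threshold, so boundary values (e.g.
    pDockQ exactly 0.23) are called not-confident.
    """
    flags = {
        "avg_plddt": bool(metrics.avg_plddt > thresholds.avg_plddt),
        "avg_models": bool(metrics.avg_models > thresholds.avg_models),
        "pdockq": bool(metrics.pdockq > thresholds.pdockq),
    }
    if metrics.classifier_score is not None:
        flags["classifier"] = bool(metrics.classifier_score > thresholds.classifier)
    return flags


Classifier = Callable[[InterfaceMetrics, Sequence[StructureModel]], float]


def score_pair(
    models: Sequence[StructureModel],
    confs: Sequence[ConfidenceBundle],
    params: ContactParams = ContactParams(),
    classifier: Classifier | None = None,
    thresholds: Thresholds = Thresholds(),
    pair_id: str | None = None,
) -> InterfaceMetrics:
    """Score one candidate pair from its M predicted models.

    Per-model contact sets are extracted and summarised; the single-model
    statistics reported (n_contacts, avg_plddt, avg_pae, pdockq) are
    those of the representative model — the one with the highest own
    average interface pLDDT, ties broken toward the lowest model_id.
    avg_models is computed across all M models.
    """
    if len(models) != len(confs) or not models:
        raise ValueError("need equal-length, nonempty model and confidence lists")
    contact_sets = [
        extract_contacts(m, c, params) for m, c in zip(models, confs)
    ]
    stats = [interface_stats(cs) for cs in contact_sets]

    def rep_rank(i: int):
        avg = stats[i][1]
        return (-(avg if not math.isnan(avg) else -math.inf), models[i].model_id)

    rep = min(range(len(models)), key=rep_rank)
    n_contacts, avg_plddt, avg_pae = stats[rep]
    metrics = InterfaceMetrics(
        pair_id=pair_id or models[0].model_id,
        n_models=len(models),
        n_contacts=n_contacts,
        per_model_n_contacts=[s[0] for s in stats],
        avg_plddt=avg_plddt,
        avg_pae=avg_pae,
        avg_models=avg_models_score(contact_sets),
        pdockq=pdockq(models[rep], confs[rep]),
        representative_model_id=models[rep].model_id,
    )
    if classifier is not None:
        metrics.classifier_score = float(classifier(metrics, models))
    metrics.flags = confidence_calls(metrics, thresholds)
    return metrics
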