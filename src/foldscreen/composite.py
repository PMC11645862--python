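"""Composite structural models by anchored rigid-body superposition.

A composite model positions independently determined (or predicted)
components relative to a reference by least-squares superposition on a
shared chain — e.g. docking a predicted two-protein module onto an
experimental complex via the subunit they have in common, then docking a
third structure onto the placed module via another shared chain.  No
refinement is performed; the result is judged by a steric clash census and
by distance measurements between named atoms.

Superposition is the classic SVD-based least-squares fit (Kabsch), with
the reflection branch corrected so the returned rotation is always proper
(det = +1): rigid bodies cannot be mirrored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AssemblyError,
    DegenerateGeometryError,
    PairingError,
    SelectorError,
)
from .model import StructureModel

__all__ = [
    "RigidTransform",
    "ChainPairing",
    "CompositeModel",
    "ClashRule",
    "VdwOverlapRule",
    "FixedCutoffRule",
    "ClashReport",
    "superpose",
    "align_via_chain",
    "assemble",
    "clash_census",
    "measure_distance",
]

# Bondi (1964) van der Waals radii in Å, extended with common metals;
# unlisted elements fall back to 1.70 Å (carbon).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "MG": 1.73, "MN": 1.97, "FE": 1.94, "CA": 2.31,
    "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63,
}
DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation: x -> rotation @ x + translation."""

    rotation: np.ndarray        # (3, 3), orthogonal, det = +1
    translation: np.ndarray     # (3,)
    rmsd: float                 # Å, residual of the fit
    n_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
            rmsd=float("nan"),
            n_matched=0,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), 0.0, 0)


def superpose(ref_coords: np.ndarray, mobile_coords: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of paired point sets.

    Finds the proper rotation R and translation t minimising
    ||R @ mobile + t - ref||; if the unconstrained optimum is a
    reflection, the smallest singular component's sign is flipped so the
    result stays a rigid-body motion.  Requires >= 3 non-collinear pairs.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mobile must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 matched atoms, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    # collinear point sets leave a free rotation about the line
    s_ref = np.linalg.svd(ref_c, compute_uv=False)
    s_mob = np.linalg.svd(mob_c, compute_uv=False)
    scale = max(s_ref[0], s_mob[0], 1.0)
    if s_ref[1] < 1e-8 * scale or s_mob[1] < 1e-8 * scale:
        raise DegenerateGeometryError("matched atoms are collinear; superposition is underdetermined")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    resid = mob @ rot.T + trans - ref
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd, n_matched=n)


@dataclass(frozen=True)
class ChainPairing:
    """How to match anchor atoms between a reference and a mobile chain.

    Without ``residue_pairs`` the pairing is the intersection of residue
    numbers; ``atom_rule`` selects alpha-carbons only, the full N/CA/C/O
    backbone, or every atom name shared by the paired residues
    (``all_shared`` — useful for coarse traces and nucleic chains).
    """

    ref_chain: str
    mobile_chain: str
    residue_pairs: tuple[tuple[int, int], ...] | None = None  # (ref_resnum, mobile_resnum)
    atom_rule: str = "alpha_carbon"  # alpha_carbon | backbone | all_shared

    def __post_init__(self) -> None:
        if self.atom_rule not in ("alpha_carbon", "backbone", "all_shared"):
            raise ValueError(f"unknown atom_rule {self.atom_rule!r}")


_BACKBONE = ("N", "CA", "C", "O")


def _anchor_coords(
    reference: StructureModel, mobile: StructureModel, pairing: ChainPairing
) -> tuple[np.ndarray, np.ndarray]:
    try:
        ref_chain = reference.chain(pairing.ref_chain)
    except KeyError as exc:
        raise PairingError(
            f"reference model {reference.model_id!r} has no chain {pairing.ref_chain!r}"
        ) from exc
    try:
        mob_chain = mobile.chain(pairing.mobile_chain)
    except KeyError as exc:
        raise PairingError(
            f"mobile model {mobile.model_id!r} has no chain {pairing.mobile_chain!r}"
        ) from exc

    if pairing.residue_pairs is not None:
        pairs = pairing.residue_pairs
    else:
        ref_nums = {r.resnum for r in ref_chain.residues}
        mob_nums = {r.resnum for r in mob_chain.residues}
        pairs = tuple((n, n) for n in sorted(ref_nums & mob_nums))
    ref_pts, mob_pts = [], []
    for ref_num, mob_num in pairs:
        rres = ref_chain.residue(ref_num)
        mres = mob_chain.residue(mob_num)
        if rres is None or mres is None:
            continue
        if pairing.atom_rule == "alpha_carbon":
            names = ("CA",)
        elif pairing.atom_rule == "backbone":
            names = _BACKBONE
        else:  # all_shared
            names = tuple(
                a.name for a in rres.atoms if mres.atom(a.name) is not None
            )
        for name in names:
            ra, ma = rres.atom(name), mres.atom(name)
            if ra is not None and ma is not None:
                ref_pts.append(ra.xyz)
                mob_pts.append(ma.xyz)
    if len(ref_pts) < 3:
        raise PairingError(
            f"pairing {pairing.ref_chain!r}~{pairing.mobile_chain!r} matches "
            f"{len(ref_pts)} atoms; need >= 3"
        )
    return np.array(ref_pts), np.array(mob_pts)


def transform_model(model: StructureModel, t: RigidTransform) -> StructureModel:
    out = model.copy()
    for res in out.iter_residues():
        for atom in res.atoms:
            atom.xyz = t.rotation @ atom.xyz + t.translation
    return out


def align_via_chain(
    reference: StructureModel, mobile: StructureModel, pairing: ChainPairing
) -> tuple[RigidTransform, StructureModel]:
    """Superpose ``mobile`` onto ``reference`` using one shared chain.

    The transform is fit on the paired anchor atoms only and applied to
    every atom of the mobile model.  Returns the transform (with the
    anchor RMSD) and the transformed copy.
    """
    ref_pts, mob_pts = _anchor_coords(reference, mobile, pairing)
    t = superpose(ref_pts, mob_pts)
    return t, transform_model(mobile, t)


@dataclass
class PlacedComponent:
    component_id: str
    model: StructureModel               # coordinates after placement
    transform: RigidTransform
    pairing: ChainPairing | None        # None for the base component
    anchored_to: str | None             # component_id of the reference
    chain_renames: dict[str, str] = field(default_factory=dict)


@dataclass
class CompositeModel:
    """Base model plus sequentially placed components, with provenance."""

    components: list[PlacedComponent]

    def component(self, component_id: str) -> PlacedComponent:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(f"no component {component_id!r}")

    def to_structure(self, model_id: str = "composite") -> StructureModel:
        """Flatten to one StructureModel (chain ids already disambiguated)."""
        chains = []
        for comp in self.components:
            chains.extend(ch for ch in comp.model.chains)
        return StructureModel(model_id=model_id, chains=chains)


@dataclass(frozen=True)
class AssemblyStep:
    mobile: StructureModel
    reference_id: str          # "base" or a previously placed component_id
    pairing: ChainPairing
    component_id: str | None = None


def _disambiguate_chains(
    model: StructureModel, taken: set[str]
) -> tuple[StructureModel, dict[str, str]]:
    renames: dict[str, str] = {}
    out = model.copy()
    for ch in out.chains:
        new_id = ch.chain_id
        k = 1
        while new_id in taken:
            new_id = f"{ch.chain_id}_{k}"
            k += 1
        if new_id != ch.chain_id:
            renames[ch.chain_id] = new_id
            for r in ch.residues:
                r.chain_id = new_id
            ch.chain_id = new_id
        taken.add(new_id)
    return out, renames


def assemble(base: StructureModel, steps: Sequence[AssemblyStep]) -> CompositeModel:
    """Build a composite model by sequential anchored superposition.

    Each step aligns its mobile model onto the base or an already-placed
    component via the step's chain pairing.  Chain-id collisions across
    components are resolved by suffixing (recorded in the component's
    ``chain_renames``).  Transforms are applied exactly once; provenance
    (anchor, transform, RMSD) is kept per component.
    """
    base.validate()
    composite = CompositeModel(
        components=[
            PlacedComponent(
                component_id="base",
                model=base.copy(),
                transform=RigidTransform.identity(),
                pairing=None,
                anchored_to=None,
            )
        ]
    )
    taken = {c.chain_id for c in base.chains}
    for k, step in enumerate(steps, start=1):
        comp_id = step.component_id or f"component_{k}"
        if any(c.component_id == comp_id for c in composite.components):
            raise AssemblyError(f"duplicate component id {comp_id!r}")
        try:
            ref_comp = composite.component(step.reference_id)
        except KeyError as exc:
            raise AssemblyError(
                f"step {comp_id!r} references {step.reference_id!r}, which is not placed"
            ) from exc
        transform, placed = align_via_chain(ref_comp.model, step.mobile, step.pairing)
        placed, renames = _disambiguate_chains(placed, taken)
        placed.model_id = comp_id
        composite.components.append(
            PlacedComponent(
                component_id=comp_id,
                model=placed,
                transform=transform,
                pairing=step.pairing,
                anchored_to=step.reference_id,
                chain_renames=renames,
            )
        )
    return composite


# ---------------------------------------------------------------------------
# Clash census


class ClashRule:
    """Steric criterion for an inter-component heavy-atom pair."""

    def threshold(self, elem_a: str, elem_b: str) -> float:
        raise NotImplementedError

    def max_threshold(self) -> float:
        raise NotImplementedError

    def describe(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class VdwOverlapRule(ClashRule):
    """Major clash: distance < r_vdw(a) + r_vdw(b) - slack (default 1.5 Å).

    The generous slack tolerates normal packing contacts and flags only
    substantial interpenetration.
    """

    slack: float = 1.5

    def threshold(self, elem_a: str, elem_b: str) -> float:
        return vdw_radius(elem_a) + vdw_radius(elem_b) - self.slack

    def max_threshold(self) -> float:
        return 2.0 * max(VDW_RADII.values()) - self.slack

    def describe(self) -> str:
        return f"vdw_overlap(slack={self.slack})"


@dataclass(frozen=True)
class FixedCutoffRule(ClashRule):
    """Clash: distance < a fixed cutoff (default 2.0 Å)."""

    cutoff: float = 2.0

    def threshold(self, elem_a: str, elem_b: str) -> float:
        return self.cutoff

    def max_threshold(self) -> float:
        return self.cutoff

    def describe(self) -> str:
        return f"fixed_cutoff({self.cutoff})"


@dataclass(frozen=True)
class AtomRef:
    component_id: str
    chain_id: str
    resnum: int
    atom_name: str


@dataclass
class ClashReport:
    rule: str
    clashes: list[tuple[AtomRef, AtomRef, float, float]]  # (a, b, distance, overlap)
    counts: dict[tuple[str, str], int]
    excluded_chain_pairs: set[frozenset]

    def __len__(self) -> int:
        return len(self.clashes)


def _component_atoms(comp: PlacedComponent):
    refs, coords, elems = [], [], []
    for ch in comp.model.chains:
        for r in ch.residues:
            for a in r.atoms:
                refs.append(AtomRef(comp.component_id, ch.chain_id, r.resnum, a.name))
                coords.append(a.xyz)
                elems.append(a.element)
    return refs, np.array(coords), elems


def _anchor_exclusions(composite: CompositeModel) -> set[frozenset]:
    """Chain pairs (component_id, chain_id) duplicated by anchoring.

    A placed component's anchor chain is a copy of the chain it was
    aligned to, so the two trivially interpenetrate; the census skips
    those pairs.
    """
    out: set[frozenset] = set()
    for comp in composite.components:
        if comp.pairing is None or comp.anchored_to is None:
            continue
        mob_chain = comp.chain_renames.get(
            comp.pairing.mobile_chain, comp.pairing.mobile_chain
        )
        out.add(
            frozenset(
                {
                    (comp.anchored_to, comp.pairing.ref_chain),
                    (comp.component_id, mob_chain),
                }
            )
        )
    return out


def clash_census(
    composite: CompositeModel,
    rule: ClashRule = VdwOverlapRule(),
    exclusions: Sequence[frozenset] = (),
) -> ClashReport:
    """Enumerate steric clashes between distinct components.

    Inter-component heavy-atom pairs violating the rule are listed with
    their distance and overlap; intra-component pairs, anchor-chain pairs
    and user-excluded (component, chain) pairs are skipped.  A KD-tree
    restricts candidate pairs to the rule's maximum threshold; the rule
    itself is then applied exactly, so the result equals an all-pairs
    scan.
    """
    excluded = _anchor_exclusions(composite) | {frozenset(e) for e in exclusions}
    per_comp = [_component_atoms(c) for c in composite.components]
    trees = [cKDTree(coords) if len(coords) else None for _, coords, _ in per_comp]
    clashes = []
    counts: dict[tuple[str, str], int] = {}
    r_max = rule.max_threshold()
    for (ia, ib) in itertools.combinations(range(len(per_comp)), 2):
        refs_a, coords_a, elems_a = per_comp[ia]
        refs_b, coords_b, elems_b = per_comp[ib]
        if trees[ia] is None or trees[ib] is None or r_max <= 0:
            continue
        comp_pair = (
            composite.components[ia].component_id,
            composite.components[ib].component_id,
        )
        counts.setdefault(comp_pair, 0)
        neighbours = trees[ia].query_ball_tree(trees[ib], r_max)
        for ai, neigh in enumerate(neighbours):
            for bi in neigh:
                a, b = refs_a[ai], refs_b[bi]
                if frozenset({(a.component_id, a.chain_id), (b.component_id, b.chain_id)}) in excluded:
                    continue
                d = float(np.linalg.norm(coords_a[ai] - coords_b[bi]))
                thr = rule.threshold(elems_a[ai], elems_b[bi])
                if d < thr:
                    clashes.append((a, b, d, float(thr - d)))
                    counts[comp_pair] += 1
    return ClashReport(
        rule=rule.describe(),
        clashes=clashes,
        counts=counts,
        excluded_chain_pairs=excluded,
    )


def measure_distance(
    composite: CompositeModel,
    selector_a: tuple[str, str, int, str],
    selector_b: tuple[str, str, int, str],
) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms.

    Selectors are (component_id, chain_id, resnum, atom_name) and are
    resolved against post-placement coordinates.
    """
    def resolve(sel) -> np.ndarray:
        comp_id, chain_id, resnum, atom_name = sel
        try:
            comp = composite.component(comp_id)
            chain = comp.model.chain(chain_id)
        except KeyError as exc:
            raise SelectorError(f"selector {sel!r}: {exc}") from exc
        res = chain.residue(resnum)
        if res is None:
            raise SelectorError(f"selector {sel!r}: no residue {resnum}")
        atom = res.atom(atom_name)
        if atom is None:
            raise SelectorError(f"selector {sel!r}: no atom {atom_name!r}")
        return atom.xyz

    return float(np.linalg.norm(resolve(selector_a) - resolve(selector_b)))
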