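"""In-memory containers for structures and prediction confidence.

A :class:`StructureModel` is a plain chain/residue/atom hierarchy carrying
only what the interface analysis needs: identifiers, heavy-atom coordinates
in Å and per-atom B-factors (which double as pLDDT in predicted models).
A :class:`ConfidenceBundle` pairs a per-residue pLDDT vector (0–100) with a
square predicted-aligned-error (PAE) matrix in Å; the two are glued to the
structure through a :class:`ResidueIndex` that maps a global 0-based residue
index (residues concatenated in file chain order) to ``(chain_id, resnum)``
and back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import (
    ConfidenceMismatchError,
    DuplicateChainError,
    EmptyStructureError,
)

# Residue names used to classify chain entity kind.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL", "UNK",
}
NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I", "N"}


@dataclass
class Atom:
    """A heavy atom: name, element symbol, position in Å, B-factor."""

    name: str
    element: str
    xyz: np.ndarray  # shape (3,), float64, Å
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    resnum: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def mean_bfactor(self) -> float:
        return float(np.mean([a.bfactor for a in self.atoms]))


def classify_entity_kind(residues: list[Residue]) -> str:
    """Majority vote over residue names: protein / nucleic / other."""
    n_prot = sum(r.resname in AMINO_ACIDS for r in residues)
    n_nuc = sum(r.resname in NUCLEOTIDES for r in residues)
    if n_prot >= n_nuc and n_prot > len(residues) // 2:
        return "protein"
    if n_nuc > len(residues) // 2:
        return "nucleic"
    return "other"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    entity_kind: str = "protein"  # protein | nucleic | other

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, resnum: int) -> Residue | None:
        for r in self.residues:
            if r.resnum == resnum:
                return r
        return None


@dataclass
class StructureModel:
    """Hierarchical coordinates: chains -> residues -> heavy atoms."""

    model_id: str
    chains: list[Chain] = field(default_factory=list)
    source_path: str = ""
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.chains:
            raise EmptyStructureError(f"model {self.model_id!r} has no chains")
        seen: set[str] = set()
        for ch in self.chains:
            if ch.chain_id in seen:
                raise DuplicateChainError(
                    f"duplicate chain id {ch.chain_id!r} in model {self.model_id!r}"
                )
            seen.add(ch.chain_id)
            if not ch.residues:
                raise EmptyStructureError(
                    f"chain {ch.chain_id!r} of model {self.model_id!r} is empty"
                )
            nums = [r.resnum for r in ch.residues]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(
                    f"chain {ch.chain_id!r}: residue numbers not strictly increasing"
                )
            for r in ch.residues:
                if not r.atoms:
                    raise EmptyStructureError(
                        f"residue {ch.chain_id}/{r.resnum} has no heavy atoms"
                    )
                names = [a.name for a in r.atoms]
                if len(names) != len(set(names)):
                    raise ValueError(
                        f"residue {ch.chain_id}/{r.resnum}: duplicate atom names"
                    )

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.model_id!r}")

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def all_atom_coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates in chain/residue/atom file order."""
        return np.array(
            [a.xyz for c in self.chains for r in c.residues for a in r.atoms],
            dtype=float,
        )

    def copy(self) -> "StructureModel":
        chains = [
            Chain(
                c.chain_id,
                [
                    Residue(
                        r.chain_id,
                        r.resnum,
                        r.resname,
                        [Atom(a.name, a.element, a.xyz.copy(), a.bfactor) for a in r.atoms],
                    )
                    for r in c.residues
                ],
                c.entity_kind,
            )
            for c in self.chains
        ]
        return StructureModel(self.model_id, chains, self.source_path, dict(self.metadata))


@dataclass
class ResidueIndex:
    """Bijection between global residue index and (chain_id, resnum).

    Global indices run 0..N-1 over residues concatenated in file chain
    order; per-chain ranges are half-open and partition [0, N).
    """

    ranges: dict[str, tuple[int, int]]
    to_global: dict[tuple[str, int], int]
    to_residue: list[tuple[str, int]]

    @property
    def n_residues(self) -> int:
        return len(self.to_residue)

    def global_index(self, chain_id: str, resnum: int) -> int:
        return self.to_global[(chain_id, resnum)]

    def residue_id(self, i: int) -> tuple[str, int]:
        return self.to_residue[i]


def build_residue_index(model: StructureModel) -> ResidueIndex:
    """Derive the global-index mapping from a model's chain order."""
    model.validate()
    ranges: dict[str, tuple[int, int]] = {}
    to_global: dict[tuple[str, int], int] = {}
    to_residue: list[tuple[str, int]] = []
    i = 0
    for ch in model.chains:
        start = i
        for r in ch.residues:
            to_global[(ch.chain_id, r.resnum)] = i
            to_residue.append((ch.chain_id, r.resnum))
            i += 1
        ranges[ch.chain_id] = (start, i)
    return ResidueIndex(ranges=ranges, to_global=to_global, to_residue=to_residue)


@dataclass
class ConfidenceBundle:
    """Per-residue pLDDT + pairwise PAE for one structure model.

    ``plddt[i]`` is on the 0–100 scale; ``pae[i, j]`` is the expected
    position error (Å) of residue j when the prediction is aligned on
    residue i — the matrix need not be symmetric.
    """

    plddt: np.ndarray
    pae: np.ndarray
    index: ResidueIndex

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)

    def validate(self, model: StructureModel | None = None) -> None:
        n = self.index.n_residues
        if self.plddt.shape != (n,):
            raise ConfidenceMismatchError(
                f"pLDDT length {self.plddt.shape} != residue count {n}"
            )
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ConfidenceMismatchError(f"PAE matrix not square: {self.pae.shape}")
        if self.pae.shape[0] != n:
            raise ConfidenceMismatchError(
                f"PAE side {self.pae.shape[0]} != residue count {n}"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ConfidenceMismatchError("pLDDT values outside [0, 100]")
        if np.any(self.pae < 0):
            raise ConfidenceMismatchError("negative PAE values")
        if model is not None and model.n_residues != n:
            raise ConfidenceMismatchError(
                f"bundle indexes {n} residues but model has {model.n_residues}"
            )

    def plddt_of(self, chain_id: str, resnum: int) -> float:
        return float(self.plddt[self.index.global_index(chain_id, resnum)])

    def pae_of(self, a: tuple[str, int], b: tuple[str, int]) -> float:
        return float(
            self.pae[self.index.global_index(*a), self.index.global_index(*b)]
        )
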