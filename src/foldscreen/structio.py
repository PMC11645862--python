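"""Coordinate and confidence-file I/O.

Structure files (PDB / mmCIF) are parsed and written through gemmi; this
module reduces them to the heavy-atom hierarchy the analysis needs.
Parsing rules:

* hydrogens (H/D) are dropped;
* alternate locations are collapsed to the highest-occupancy conformer,
  ties resolved toward altloc 'A' (then alphabetically);
* chain order is file order, residue order is file order within a chain.

Confidence files come in two JSON dialects commonly emitted by prediction
pipelines:

* ``scores_json`` — one file holding a per-residue pLDDT array and the
  square PAE matrix.  Accepted keys: ``plddt`` (or ``pLDDT``) and ``pae``
  (or ``predicted_aligned_error``).
* ``pae_json`` / ``bfactor_plddt`` — a PAE-only file keyed
  ``predicted_aligned_error`` (optionally wrapped in a one-element list,
  as deposited-database PAE files are); pLDDT is taken from the
  coordinate file's B-factor column, averaged per residue.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    ConfidenceFormatError,
    ConfidenceMismatchError,
    DuplicateChainError,
    EmptyStructureError,
    StructureReadError,
    StructureWriteError,
)
from .model import (
    Atom,
    Chain,
    ConfidenceBundle,
    Residue,
    StructureModel,
    build_residue_index,
    classify_entity_kind,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_confidence",
    "write_confidence",
    "build_residue_index",
]

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _check_duplicate_chains(path: Path, fmt: gemmi.CoorFormat) -> None:
    """Reject files where a chain id reappears after another chain.

    gemmi silently merges non-contiguous segments that share a chain id,
    which would corrupt the global residue indexing; treat them as the
    distinct "duplicate chain" error instead.
    """
    if fmt == gemmi.CoorFormat.Detect:
        fmt = (
            gemmi.CoorFormat.Mmcif
            if path.suffix.lower() in {".cif", ".mmcif"}
            else gemmi.CoorFormat.Pdb
        )
    order: list[str] = []
    if fmt == gemmi.CoorFormat.Pdb:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("ATOM", "HETATM")):
                    cid = line[21].strip() or line[72:76].strip()
                    if not order or order[-1] != cid:
                        order.append(cid)
                elif line.startswith("ENDMDL"):
                    break
    else:
        try:
            block = gemmi.cif.read(str(path)).sole_block()
        except Exception:
            return  # let gemmi's structure reader report format errors
        col = block.find_loop("_atom_site.auth_asym_id") or block.find_loop(
            "_atom_site.label_asym_id"
        )
        for cid in col:
            if not order or order[-1] != cid:
                order.append(cid)
    if len(order) != len(set(order)):
        dup = next(c for i, c in enumerate(order) if c in order[:i])
        raise DuplicateChainError(f"{path}: duplicate chain id {dup!r}")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties prefer altloc 'A', then alphabetical."""
    def key(a: gemmi.Atom):
        alt = a.altloc or "A"
        return (-a.occ, alt != "A", alt)

    return sorted(atoms, key=key)[0]


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Heavy atoms only; the first model of a multi-model file is used.
    Raises :class:`StructureReadError` for unreadable/garbled files,
    :class:`EmptyStructureError` for chain-less files and
    :class:`DuplicateChainError` when two chains share an identifier.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb|mmcif|auto")
    if not path.is_file():
        raise StructureReadError(f"no such file: {path}")
    _check_duplicate_chains(path, _FORMATS[format])
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureReadError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    gmodel = st[0]

    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        bfactor=float(ga.b_iso),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=gchain.name,
                        resnum=gres.seqid.num,
                        resname=gres.name.strip(),
                        atoms=atoms,
                    )
                )
        if residues:
            chains.append(
                Chain(
                    chain_id=gchain.name,
                    residues=residues,
                    entity_kind=classify_entity_kind(residues),
                )
            )
    model = StructureModel(
        model_id=path.stem,
        chains=chains,
        source_path=str(path),
    )
    model.validate()  # raises DuplicateChainError / EmptyStructureError
    return model


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id[:78]
    gm = gemmi.Model("1")
    for ch in model.chains:
        gc = gemmi.Chain(ch.chain_id)
        for r in ch.residues:
            gr = gemmi.Residue()
            gr.name = r.resname
            gr.seqid = gemmi.SeqId(r.resnum, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = 1.0
                ga.b_iso = float(a.bfactor)
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(
    model: StructureModel, path: str | os.PathLike, format: str = "auto"
) -> None:
    """Write a model as PDB or mmCIF (format 'auto' = by file suffix)."""
    model.validate()
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}; expected pdb|mmcif|auto")
    st = _to_gemmi(model)
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureWriteError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Confidence files


def _extract_pae(obj: object) -> np.ndarray:
    """Accept the bare matrix or the deposited-database wrapping."""
    if isinstance(obj, list) and obj and isinstance(obj[0], dict):
        obj = obj[0]  # [{"predicted_aligned_error": ...}]
    if isinstance(obj, dict):
        for key in ("predicted_aligned_error", "pae"):
            if key in obj:
                obj = obj[key]
                break
        else:
            raise ConfidenceFormatError(
                "no PAE matrix found (expected key 'predicted_aligned_error' or 'pae')"
            )
    pae = np.asarray(obj, dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ConfidenceMismatchError(f"PAE matrix not square: {pae.shape}")
    return pae


def _plddt_from_bfactors(model: StructureModel) -> np.ndarray:
    return np.array([r.mean_bfactor() for r in model.iter_residues()], dtype=float)


def read_confidence(
    path: str | os.PathLike,
    dialect: str,
    model: StructureModel,
) -> ConfidenceBundle:
    """Read prediction confidence for ``model`` from a JSON file.

    ``dialect`` is one of:

    * ``scores_json`` — combined pLDDT + PAE file;
    * ``pae_json`` (alias ``bfactor_plddt``) — PAE-only file, pLDDT read
      from the model's B-factor column;
    * ``auto`` — ``scores_json`` if a pLDDT key is present, else PAE-only.

    The returned bundle is validated against the model (length match,
    square PAE, legal ranges).
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except OSError as exc:
        raise ConfidenceFormatError(f"cannot read {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfidenceFormatError(f"{path}: invalid JSON: {exc}") from exc

    if dialect == "auto":
        has_plddt = isinstance(data, dict) and any(
            k in data for k in ("plddt", "pLDDT")
        )
        dialect = "scores_json" if has_plddt else "pae_json"

    if dialect == "scores_json":
        if not isinstance(data, dict):
            raise ConfidenceFormatError(f"{path}: scores dialect requires a JSON object")
        plddt_raw = data.get("plddt", data.get("pLDDT"))
        if plddt_raw is None:
            raise ConfidenceFormatError(f"{path}: missing 'plddt' key")
        plddt = np.asarray(plddt_raw, dtype=float)
        pae = _extract_pae(data)
    elif dialect in ("pae_json", "bfactor_plddt"):
        pae = _extract_pae(data)
        plddt = _plddt_from_bfactors(model)
    else:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected scores_json|pae_json|bfactor_plddt|auto"
        )

    index = build_residue_index(model)
    bundle = ConfidenceBundle(plddt=plddt, pae=pae, index=index)
    bundle.validate(model)
    return bundle


def write_confidence(
    bundle: ConfidenceBundle,
    path: str | os.PathLike,
    dialect: str = "scores_json",
    ndigits: int | None = None,
) -> None:
    """Write a bundle as a confidence JSON file in the given dialect.

    With ``ndigits=None`` values are written at full precision so a
    write/read round trip is exact.
    """
    def conv(arr: np.ndarray):
        lst = arr.tolist()
        if ndigits is None:
            return lst
        if arr.ndim == 1:
            return [round(v, ndigits) for v in lst]
        return [[round(v, ndigits) for v in row] for row in lst]

    if dialect == "scores_json":
        data = {"plddt": conv(bundle.plddt), "pae": conv(bundle.pae)}
    elif dialect in ("pae_json", "bfactor_plddt"):
        data = {
            "predicted_aligned_error": conv(bundle.pae),
            "max_predicted_aligned_error": float(bundle.pae.max()) if bundle.pae.size else 0.0,
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump(data, fh)


def stamp_plddt_bfactors(model: StructureModel, plddt: np.ndarray) -> None:
    """Write per-residue pLDDT into every atom B-factor (in place).

    Predicted-structure files conventionally carry pLDDT this way, which
    is what the ``pae_json`` dialect relies on.
    """
    plddt = np.asarray(plddt, dtype=float)
    for i, res in enumerate(model.iter_residues()):
        for a in res.atoms:
            a.bfactor = float(plddt[i])
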