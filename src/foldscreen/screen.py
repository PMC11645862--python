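"""Many-pair interaction screens: score every candidate pair, rank, report.

A screen folds one bait protein against a list of candidates; each entry
contributes M predicted models plus confidence files.  Every entry is
scored once (contacts, interface statistics, ensemble agreement, pDockQ,
optional external classifier) and the resulting rows are ranked by a
chosen metric.  Entries that fail to parse or score are recorded with the
failure reason and ranked after all scored entries — a large screen should
tolerate partial failure.
"""

from __future__ import annotations

import datetime
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .errors import EmptyScreenError, FoldscreenError, MissingScoreError
from .interface import (
    Classifier,
    ContactParams,
    InterfaceMetrics,
    Thresholds,
    score_pair,
)
from .model import ConfidenceBundle, StructureModel
from .structio import read_confidence, read_structure

__all__ = [
    "ScreenEntry",
    "ScreenManifest",
    "ScreenResult",
    "RANKING_KEYS",
    "run_screen",
    "rank_rows",
    "read_manifest",
    "write_result",
]

logger = logging.getLogger(__name__)

RANKING_KEYS = ("classifier", "avg_models", "pdockq", "avg_plddt")

_KEY_ATTR = {
    "classifier": "classifier_score",
    "avg_models": "avg_models",
    "pdockq": "pdockq",
    "avg_plddt": "avg_plddt",
}

_TSV_COLUMNS = [
    "rank", "pair_id", "n_models", "n_contacts", "avg_plddt", "avg_pae",
    "avg_models", "pdockq", "classifier", "flags", "status",
]


@dataclass
class ScreenEntry:
    """One candidate pair: either file references or in-memory objects."""

    pair_id: str
    model_paths: list[str] = field(default_factory=list)
    conf_paths: list[str] = field(default_factory=list)
    conf_dialect: str = "auto"
    models: list[StructureModel] | None = None
    confs: list[ConfidenceBundle] | None = None

    def load(self) -> tuple[list[StructureModel], list[ConfidenceBundle]]:
        if self.models is not None and self.confs is not None:
            return self.models, self.confs
        if not self.model_paths or len(self.model_paths) != len(self.conf_paths):
            raise FoldscreenError(
                f"entry {self.pair_id!r}: need matching model and confidence paths"
            )
        models = [read_structure(p) for p in self.model_paths]
        confs = [
            read_confidence(cp, self.conf_dialect, m)
            for cp, m in zip(self.conf_paths, models)
        ]
        return models, confs


@dataclass
class ScreenManifest:
    bait_id: str
    entries: list[ScreenEntry]
    params: ContactParams = field(default_factory=ContactParams)
    ranking_key: str = "avg_models"

    def validate(self) -> None:
        if not self.entries:
            raise EmptyScreenError(f"screen {self.bait_id!r} has no entries")
        ids = [e.pair_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise FoldscreenError(f"screen {self.bait_id!r}: duplicate pair_ids")
        if self.ranking_key not in RANKING_KEYS:
            raise ValueError(
                f"unknown ranking key {self.ranking_key!r}; expected one of {RANKING_KEYS}"
            )


@dataclass
class ScreenResult:
    rows: list[InterfaceMetrics]          # scored, ranked descending by key
    failed: list[InterfaceMetrics]        # entries with an error, in pair_id order
    ranking_key: str
    metadata: dict = field(default_factory=dict)

    @property
    def ranks(self) -> dict[str, int]:
        """pair_id -> 1-based rank (failures rank after all scored rows)."""
        out = {m.pair_id: i + 1 for i, m in enumerate(self.rows)}
        for j, m in enumerate(self.failed):
            out[m.pair_id] = len(self.rows) + j + 1
        return out


def _key_value(row: InterfaceMetrics, key: str) -> float:
    value = getattr(row, _KEY_ATTR[key])
    if value is None:
        raise MissingScoreError(
            f"pair {row.pair_id!r} has no {key!r} score; rank by another key "
            "or register a classifier"
        )
    return float(value)


def rank_rows(
    rows: Sequence[InterfaceMetrics],
    key: str,
    metadata: dict | None = None,
) -> ScreenResult:
    """Rank metric rows descending by ``key``.

    NaN values (e.g. the undefined interface pLDDT of a contact-free
    pair) sort below every number; ties break by pair_id ascending, so
    the ordering is total and deterministic.  Rows carrying an error are
    listed after all scored rows.
    """
    if key not in RANKING_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {RANKING_KEYS}")
    scored = [r for r in rows if r.error is None]
    failed = sorted((r for r in rows if r.error is not None), key=lambda r: r.pair_id)
    missing = [
        r.pair_id for r in scored if getattr(r, _KEY_ATTR[key]) is None
    ]
    if missing:
        raise MissingScoreError(
            f"ranking key {key!r} missing for pairs: {', '.join(sorted(missing))}"
        )

    def sort_key(row: InterfaceMetrics):
        v = _key_value(row, key)
        return (math.isnan(v), -v if not math.isnan(v) else 0.0, row.pair_id)

    ordered = sorted(scored, key=sort_key)
    return ScreenResult(
        rows=ordered, failed=failed, ranking_key=key, metadata=metadata or {}
    )


def run_screen(
    manifest: ScreenManifest,
    classifier: Classifier | None = None,
    thresholds: Thresholds = Thresholds(),
) -> ScreenResult:
    """Score every entry of a screen and rank the results.

    Per-entry failures are logged and recorded (with the exception text)
    but never abort the screen; metrics are computed once and can be
    re-ranked by any key with :func:`rank_rows`.
    """
    manifest.validate()
    rows: list[InterfaceMetrics] = []
    for entry in manifest.entries:
        try:
            models, confs = entry.load()
            metrics = score_pair(
                models,
                confs,
                params=manifest.params,
                classifier=classifier,
                thresholds=thresholds,
                pair_id=entry.pair_id,
            )
            logger.info(
                "scored %s: n_contacts=%d avg_models=%.3f",
                entry.pair_id, metrics.n_contacts, metrics.avg_models,
            )
        except FoldscreenError as exc:
            logger.warning("entry %s failed: %s", entry.pair_id, exc)
            metrics = InterfaceMetrics(
                pair_id=entry.pair_id,
                n_models=0,
                n_contacts=0,
                per_model_n_contacts=[],
                avg_plddt=float("nan"),
                avg_pae=float("nan"),
                avg_models=float("nan"),
                pdockq=float("nan"),
                error=str(exc),
            )
        rows.append(metrics)
    metadata = {
        "bait_id": manifest.bait_id,
        "params": vars(manifest.params) | {},
        "ranking_key": manifest.ranking_key,
        "n_entries": len(manifest.entries),
        "foldscreen_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return rank_rows(rows, manifest.ranking_key, metadata=metadata)


# ---------------------------------------------------------------------------
# Manifest / result I/O


def read_manifest(
    path: str | Path,
    bait_id: str | None = None,
    params: ContactParams = ContactParams(),
    ranking_key: str = "avg_models",
) -> ScreenManifest:
    """Read a manifest TSV (pair_id, model_path, conf_path[, dialect]).

    One row per model; rows sharing a pair_id form that pair's ensemble.
    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "model_path", "conf_path"}
    if not required.issubset(df.columns):
        raise FoldscreenError(
            f"manifest {path} must have columns {sorted(required)}"
        )
    base = path.parent
    entries: dict[str, ScreenEntry] = {}
    for rec in df.itertuples(index=False):
        e = entries.setdefault(
            rec.pair_id,
            ScreenEntry(
                pair_id=rec.pair_id,
                conf_dialect=getattr(rec, "dialect", "auto") or "auto",
            ),
        )
        e.model_paths.append(str(base / rec.model_path))
        e.conf_paths.append(str(base / rec.conf_path))
    return ScreenManifest(
        bait_id=bait_id or path.stem,
        entries=list(entries.values()),
        params=params,
        ranking_key=ranking_key,
    )


def result_frame(result: ScreenResult) -> pd.DataFrame:
    """Ranked table as a DataFrame with the fixed column order."""
    records = []
    ranks = result.ranks
    for m in result.rows + result.failed:
        records.append(
            {
                "rank": ranks[m.pair_id],
                "pair_id": m.pair_id,
                "n_models": m.n_models,
                "n_contacts": m.n_contacts,
                "avg_plddt": m.avg_plddt,
                "avg_pae": m.avg_pae,
                "avg_models": m.avg_models,
                "pdockq": m.pdockq,
                "classifier": m.classifier_score,
                "flags": ",".join(k for k, v in sorted(m.flags.items()) if v),
                "status": "failed" if m.error else "ok",
            }
        )
    return pd.DataFrame.from_records(records, columns=_TSV_COLUMNS)


def write_result(result: ScreenResult, out_dir: str | Path) -> Path:
    """Write the ranked TSV plus a machine-readable metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "screen_ranked.tsv"
    result_frame(result).to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    with open(out_dir / "screen_metadata.json", "w") as fh:
        json.dump(result.metadata, fh, indent=2, default=str)
    return tsv
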