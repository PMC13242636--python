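"""Centroid-table I/O, result writing and the versioned atlas bundle.

Centroid tables are CSV/TSV files with a header row. Coordinates must be
in isotropic physical units (micrometers); anisotropic voxel scaling is
the caller's preprocessing responsibility. Column matching is
case-insensitive and accepts common synonyms (``x``/``pos_x``/``x_um``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("embalign")

BUNDLE_SCHEMA_VERSION = 1

_COLUMN_SYNONYMS = {
    "embryo": ("embryo", "embryo_id", "series"),
    "t": ("t", "time", "frame", "frame_index"),
    "cell": ("cell", "cell_name", "name", "label"),
    "x": ("x", "pos_x", "x_um"),
    "y": ("y", "pos_y", "y_um"),
    "z": ("z", "pos_z", "z_um"),
}


class FormatError(ValueError):
    """Malformed input table (missing or unparseable columns)."""


class BundleError(ValueError):
    """Unreadable or incompatible atlas bundle."""


@dataclass(frozen=True)
class CentroidRecord:
    """One nucleus centroid: (embryo, frame, optional lineage name, xyz in um)."""

    embryo_id: str
    frame_index: int
    cell_name: str  # empty string when unlabeled
    position: np.ndarray  # shape (3,), micrometers

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")


@dataclass
class ObservedFrame:
    """One snapshot: all centroids sharing an (embryo, frame) pair.

    ``canonical_time`` is populated once the owning embryo has been warped
    onto the canonical developmental axis; it is None for raw queries.
    """

    embryo_id: str
    frame_index: int
    records: list[CentroidRecord]
    canonical_time: float | None = None

    def __post_init__(self):
        if not self.records:
            raise ValueError("a frame must contain at least one centroid")
        for r in self.records:
            if r.embryo_id != self.embryo_id or r.frame_index != self.frame_index:
                raise ValueError("all records must share the frame's embryo_id and frame_index")
        named = [r.cell_name for r in self.records if r.cell_name]
        if len(named) != len(set(named)):
            raise ValueError(f"duplicate cell names in frame {self.embryo_id}/{self.frame_index}")

    @property
    def n_cells(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        return np.stack([r.position for r in self.records])

    @property
    def cell_names(self) -> list[str]:
        return [r.cell_name for r in self.records]

    @property
    def is_labeled(self) -> bool:
        return all(r.cell_name for r in self.records)

    def unlabeled(self) -> "ObservedFrame":
        """Copy of this frame with all lineage names stripped."""
        recs = [CentroidRecord(r.embryo_id, r.frame_index, "", r.position) for r in self.records]
        return ObservedFrame(self.embryo_id, self.frame_index, recs, self.canonical_time)


def _resolve_columns(columns: Iterable[str]) -> dict[str, str | None]:
    lowered = {c.lower().strip(): c for c in columns}
    out: dict[str, str | None] = {}
    for canon, synonyms in _COLUMN_SYNONYMS.items():
        out[canon] = next((lowered[s] for s in synonyms if s in lowered), None)
    return out


def read_centroid_table(path: str | Path, dialect: str = "csv") -> list[ObservedFrame]:
    """Read a centroid table into frames grouped by (embryo, frame index).

    Rows lacking a cell column (or with blank cells) become unlabeled
    records. Missing embryo/time columns default to a single embryo at
    frame 0. Parsing is locale-independent (C locale floats).
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="," if dialect == "csv" else "\t", dtype=str,
                     skipinitialspace=True)
    cols = _resolve_columns(df.columns)
    for axis in "xyz":
        if cols[axis] is None:
            raise FormatError(f"missing required coordinate column '{axis}' in {path.name}")

    coords = np.empty((len(df), 3), dtype=float)
    for k, axis in enumerate("xyz"):
        raw = df[cols[axis]]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header
            raise FormatError(
                f"non-numeric value {raw[bad.idxmax()]!r} in column '{axis}' at line {row} of {path.name}")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise FormatError(f"empty coordinate in column '{axis}' at line {row} of {path.name}")
        coords[:, k] = parsed.to_numpy()

    embryos = df[cols["embryo"]].fillna("embryo0") if cols["embryo"] else pd.Series(["embryo0"] * len(df))
    if cols["t"]:
        times = pd.to_numeric(df[cols["t"]], errors="coerce")
        if times.isna().any():
            row = int(times.isna().idxmax()) + 2
            raise FormatError(f"non-numeric frame index at line {row} of {path.name}")
        times = times.astype(int)
    else:
        times = pd.Series([0] * len(df))
    names = df[cols["cell"]].fillna("") if cols["cell"] else pd.Series([""] * len(df))

    frames: dict[tuple[str, int], list[CentroidRecord]] = {}
    for i in range(len(df)):
        key = (str(embryos.iloc[i]), int(times.iloc[i]))
        frames.setdefault(key, []).append(
            CentroidRecord(key[0], key[1], str(names.iloc[i]).strip(), coords[i]))
    return [ObservedFrame(e, t, recs) for (e, t), recs in sorted(frames.items())]


def write_centroid_table(frames: Sequence[ObservedFrame], path: str | Path,
                         dialect: str = "csv") -> None:
    """Write frames back to the CSV/TSV schema accepted by the reader."""
    rows = []
    for f in frames:
        for r in f.records:
            rows.append({"embryo": r.embryo_id, "t": r.frame_index, "cell": r.cell_name,
                         "x": r.position[0], "y": r.position[1], "z": r.position[2]})
    pd.DataFrame(rows).to_csv(path, sep="," if dialect == "csv" else "\t",
                              index=False, float_format="%.9g")


def write_assignments(results: Sequence, path: str | Path) -> None:
    """Write per-cell label assignments of one or more FrameResults.

    One row per cell: embryo, frame, coordinates (original units), the
    assigned lineage name, its Mahalanobis distance, Sinkhorn row entropy
    and (when scored) diagnostic confidence.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty assignment table")
    rows = []
    for res in results:
        conf = res.confidences if res.confidences is not None else [np.nan] * res.frame.n_cells
        for i, rec in enumerate(res.frame.records):
            rows.append({
                "embryo": rec.embryo_id,
                "t": rec.frame_index,
                "x": rec.position[0], "y": rec.position[1], "z": rec.position[2],
                "assigned_name": res.assigned_names[i],
                "mahalanobis": res.mahalanobis[i],
                "entropy": res.entropies[i],
                "confidence": conf[i],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# atlas bundle (single JSON archive, versioned)

def save_atlas_bundle(atlas, path: str | Path) -> None:
    """Serialize a fitted EmbryoAtlas to a single versioned JSON archive."""
    from .atlas import EmbryoAtlas  # local import to avoid a cycle

    if not isinstance(atlas, EmbryoAtlas):
        raise TypeError("save_atlas_bundle expects a fitted EmbryoAtlas")
    payload = {"schema_version": BUNDLE_SCHEMA_VERSION, "atlas": atlas._to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_atlas_bundle(path: str | Path):
    """Load an atlas bundle written by :func:`save_atlas_bundle`."""
    from .atlas import EmbryoAtlas

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise BundleError(f"corrupt atlas bundle {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise BundleError(
            f"atlas bundle schema version {version!r} is incompatible with "
            f"this build (expected {BUNDLE_SCHEMA_VERSION})")
    return EmbryoAtlas._from_dict(payload["atlas"])
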