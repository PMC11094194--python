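"""Pressure-frame data types, mattress zoning and plain-text I/O.

The sensing surface is a 24 x 11 grid of air-spring cells, each read by a
barometric sensor.  Rows run head -> feet, columns run left -> right of the
lying body; both indices are 0-based and row bands are half-open intervals.
The grid is zoned into three row bands: head (4 x 11), trunk (11 x 11) and
legs (9 x 11).  Only the 121 trunk cells feed the recognition pipeline;
head and leg cells are carried through untouched.

Frames are persisted one per CSV file (24 rows x 11 comma-separated
values), with an optional JSON sidecar holding the posture label and the
subject id; cohorts are a directory of frame CSVs plus a manifest table
with columns (path, subject_id, label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FRAME_SHAPE = (24, 11)
TRUNK_SHAPE = (11, 11)

#: Posture label encoding, fixed across the package.
SUPINE = 1
LATERAL = -1


class StructuralError(ValueError):
    """A matrix or container has the wrong shape or layout."""


class DegenerateInputError(ValueError):
    """Input is valid in type but carries no usable signal (e.g. all-zero)."""


@dataclass(frozen=True)
class RegionLayout:
    """Row-band zoning of the 24-row grid into head / trunk / legs.

    Intervals are half-open ``[start, stop)``; they must be ordered,
    disjoint and cover all 24 rows.  Defaults give the 4 / 11 / 9 split.
    """

    head_rows: tuple[int, int] = (0, 4)
    trunk_rows: tuple[int, int] = (4, 15)
    legs_rows: tuple[int, int] = (15, 24)

    def __post_init__(self) -> None:
        h, t, l = self.head_rows, self.trunk_rows, self.legs_rows
        if not (h[0] == 0 and h[1] == t[0] and t[1] == l[0] and l[1] == FRAME_SHAPE[0]):
            raise StructuralError(
                f"region bands must be ordered, disjoint and cover [0, {FRAME_SHAPE[0]}): "
                f"got head={h}, trunk={t}, legs={l}"
            )
        if any(b[1] <= b[0] for b in (h, t, l)):
            raise StructuralError("region bands must be non-empty")

    def rows(self, region: str) -> tuple[int, int]:
        try:
            return {"head": self.head_rows, "trunk": self.trunk_rows, "legs": self.legs_rows}[region]
        except KeyError:
            raise ValueError(f"unknown region {region!r}; expected one of head, trunk, legs") from None


@dataclass
class PressureFrame:
    """One 24 x 11 snapshot of non-negative pressure readings.

    ``label`` is +1 (supine) or -1 (lateral) when known; ``subject_id``
    identifies the person the frame was recorded from.
    """

    values: np.ndarray
    label: int | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def validate_frame(frame: PressureFrame) -> PressureFrame:
    """Check the frame invariants and return the frame unchanged.

    Raises
    ------
    StructuralError
        if the value matrix is not exactly 24 x 11.
    ValueError
        naming the offending cell, if any entry is negative or non-finite.
    """
    v = frame.values
    if v.shape != FRAME_SHAPE:
        raise StructuralError(f"frame must be {FRAME_SHAPE[0]}x{FRAME_SHAPE[1]}, got {v.shape}")
    bad = ~np.isfinite(v) | (v < 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(f"invalid pressure value {v[i, j]!r} at cell ({i}, {j}): "
                         "entries must be finite and >= 0")
    if frame.label is not None and frame.label not in (SUPINE, LATERAL):
        raise ValueError(f"label must be {SUPINE} (supine) or {LATERAL} (lateral), got {frame.label}")
    return frame


def extract_region(frame: PressureFrame, layout: RegionLayout, region: str) -> np.ndarray:
    """Return the row-band submatrix for ``region`` (head, trunk or legs).

    The result is a copy; the input frame is never modified.  With the
    default layout the trunk result is the 11 x 11 matrix Z consumed by
    preprocessing and feature extraction.
    """
    validate_frame(frame)
    start, stop = layout.rows(region)
    return frame.values[start:stop, :].copy()


def validate_trunk(Z: np.ndarray) -> np.ndarray:
    """Check an 11 x 11 trunk matrix: shape, finiteness, non-negativity."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape != TRUNK_SHAPE:
        raise StructuralError(f"trunk matrix must be {TRUNK_SHAPE[0]}x{TRUNK_SHAPE[1]}, got {Z.shape}")
    bad = ~np.isfinite(Z) | (Z < 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(f"invalid trunk value {Z[i, j]!r} at cell ({i}, {j})")
    return Z


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def save_frame(frame: PressureFrame, path: str | Path) -> Path:
    """Write one frame as a 24-row CSV; label/subject go to a JSON sidecar."""
    path = Path(path)
    validate_frame(frame)
    np.savetxt(path, frame.values, delimiter=",", fmt="%.10g")
    if frame.label is not None or frame.subject_id is not None:
        meta = {"label": frame.label, "subject_id": frame.subject_id}
        _meta_path(path).write_text(json.dumps(meta))
    return path


def load_frame(path: str | Path) -> PressureFrame:
    """Read a frame CSV (plus sidecar metadata if present)."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    label = subject_id = None
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
        label = meta.get("label")
        subject_id = meta.get("subject_id")
    return validate_frame(PressureFrame(values, label=label, subject_id=subject_id))


def save_cohort(frames: Sequence[PressureFrame], directory: str | Path,
                manifest_name: str = "manifest.csv") -> Path:
    """Write a directory of frame CSVs plus a (path, subject_id, label) manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    width = max(4, len(str(len(frames))))
    for k, frame in enumerate(frames):
        name = f"frame_{k:0{width}d}.csv"
        save_frame(frame, directory / name)
        rows.append({"path": name, "subject_id": frame.subject_id, "label": frame.label})
    manifest = pd.DataFrame(rows, columns=["path", "subject_id", "label"])
    manifest_path = directory / manifest_name
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(manifest_path: str | Path) -> list[PressureFrame]:
    """Read every frame listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    frames = []
    for rec in manifest.itertuples(index=False):
        frame = load_frame(directory / rec.path)
        if not pd.isna(rec.label):
            frame.label = int(rec.label)
        if isinstance(rec.subject_id, str) or not pd.isna(rec.subject_id):
            frame.subject_id = str(rec.subject_id)
        validate_frame(frame)
        frames.append(frame)
    return frames
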