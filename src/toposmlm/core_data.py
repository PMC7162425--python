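"""Detection-table data model, readers/writers and pre-processing filters.

SMLM data arrives as a delimited text table with one row per detection
(localized blinking event): x/y(/z) coordinates in nanometres, the camera
frame index, the photon count of the event and the estimated localization
precision.  The :class:`DetectionTable` wraps a :class:`pandas.DataFrame`
with those canonical columns, keeps any extra columns for round-tripping,
and preserves a stable integer id per detection so downstream tie-breaking
rules are invariant to row order.

Two standard pre-processing steps are provided: an intensity (photon-count)
filter and the grouping of detections appearing in strictly consecutive
frames within a small distance, which collapses repeated localizations of
one blinking event into a single detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    DataError,
    DetectionFormatError,
    DetectionParseError,
    MissingFieldError,
    ParameterError,
)

#: sentinel for "use the standard column name if the file has it"
AUTO = "__auto__"


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from detection fields to file columns (ThunderSTORM dialect by default).

    Fields set to :data:`AUTO` are used when the corresponding standard header
    is present and silently skipped otherwise; fields set to an explicit
    column name are required; fields set to ``None`` are ignored.
    """

    x: str = "x [nm]"
    y: str = "y [nm]"
    z: str | None = AUTO
    frame: str | None = AUTO
    intensity: str | None = AUTO
    uncertainty: str | None = AUTO
    sep: str = ","

    #: standard header names used to resolve AUTO fields and to write files
    standard_names = {
        "x": "x [nm]",
        "y": "y [nm]",
        "z": "z [nm]",
        "frame": "frame",
        "intensity": "intensity [photon]",
        "uncertainty": "uncertainty [nm]",
    }


THUNDERSTORM = ColumnMap()

_OPTIONAL_FIELDS = ("z", "frame", "intensity", "uncertainty")


class DetectionTable:
    """A localization-microscopy point cloud.

    Parameters
    ----------
    data
        DataFrame with canonical columns ``x``, ``y`` (and optionally ``z``,
        ``frame``, ``intensity``, ``uncertainty``) plus arbitrary extra
        columns.  The index provides the stable per-detection id.
    """

    def __init__(self, data: pd.DataFrame):
        if "x" not in data.columns or "y" not in data.columns:
            raise DetectionFormatError("detection table needs 'x' and 'y' columns")
        coords = data[[c for c in ("x", "y", "z") if c in data.columns]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise DataError("detection coordinates must be finite")
        if "uncertainty" in data.columns:
            unc = data["uncertainty"].to_numpy(float)
            if np.any(unc < 0):
                raise DataError("localization uncertainty must be >= 0")
        if "frame" in data.columns:
            fr = data["frame"].to_numpy()
            if np.any(fr < 0) or not np.allclose(fr, np.round(fr)):
                raise DataError("frame indices must be non-negative integers")
            data = data.assign(frame=np.round(fr).astype(np.int64))
        self._data = data

    # -- basic views -----------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def n(self) -> int:
        return len(self._data)

    def __len__(self) -> int:
        return self.n

    @property
    def dim(self) -> int:
        return 3 if "z" in self._data.columns else 2

    @property
    def coords(self) -> np.ndarray:
        cols = ["x", "y", "z"] if self.dim == 3 else ["x", "y"]
        return self._data[cols].to_numpy(float)

    @property
    def ids(self) -> np.ndarray:
        return self._data.index.to_numpy()

    def _optional(self, name: str) -> np.ndarray | None:
        if name in self._data.columns:
            return self._data[name].to_numpy()
        return None

    @property
    def frame(self) -> np.ndarray | None:
        return self._optional("frame")

    @property
    def intensity(self) -> np.ndarray | None:
        return self._optional("intensity")

    @property
    def uncertainty(self) -> np.ndarray | None:
        return self._optional("uncertainty")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        coords: np.ndarray,
        frame: np.ndarray | None = None,
        intensity: np.ndarray | None = None,
        uncertainty: np.ndarray | None = None,
        ids: np.ndarray | None = None,
    ) -> "DetectionTable":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise DetectionFormatError("coords must be (n, 2) or (n, 3)")
        cols = {"x": coords[:, 0], "y": coords[:, 1]}
        if coords.shape[1] == 3:
            cols["z"] = coords[:, 2]
        for name, arr in (("frame", frame), ("intensity", intensity), ("uncertainty", uncertainty)):
            if arr is not None:
                cols[name] = np.asarray(arr)
        index = np.arange(len(coords)) if ids is None else np.asarray(ids)
        return cls(pd.DataFrame(cols, index=index))

    def select(self, mask_or_index) -> "DetectionTable":
        """Subset rows (boolean mask over rows, or positional indices); ids kept."""
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            return DetectionTable(self._data.loc[arr])
        return DetectionTable(self._data.iloc[arr])

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, DetectionTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self._data, other._data, check_dtype=False)
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_detections(path: str | Path, dialect: ColumnMap | None = None) -> DetectionTable:
    """Read a delimited detection table.

    The dialect maps detection fields to file columns (ThunderSTORM-style
    headers by default).  Unmapped extra columns are kept and written back on
    export.
    """
    dialect = dialect or THUNDERSTORM
    raw = pd.read_csv(path, sep=dialect.sep)
    rename: dict[str, str] = {}
    for field_name in ("x", "y"):
        col = getattr(dialect, field_name)
        if col not in raw.columns:
            raise DetectionFormatError(f"missing mapped column {col!r} for field {field_name!r}")
        rename[col] = field_name
    for field_name in _OPTIONAL_FIELDS:
        col = getattr(dialect, field_name)
        if col is None:
            continue
        if col == AUTO:
            col = ColumnMap.standard_names[field_name]
            if col not in raw.columns:
                continue
        elif col not in raw.columns:
            raise DetectionFormatError(f"missing mapped column {col!r} for field {field_name!r}")
        rename[col] = field_name
    df = raw.rename(columns=rename)
    for field_name in ("x", "y", "z"):
        if field_name not in df.columns:
            continue
        vals = pd.to_numeric(df[field_name], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy(float)))[0]
        if len(bad):
            row = int(bad[0]) + 1
            raise DetectionParseError(
                f"non-numeric {field_name!r} coordinate at data row {row}", row=row
            )
        df[field_name] = vals
    return DetectionTable(df)


def write_detections(
    t: DetectionTable,
    path: str | Path,
    dialect: ColumnMap | None = None,
    labels: np.ndarray | None = None,
) -> None:
    """Write a detection table with standard headers; extras are preserved.

    ``labels`` (per-detection integer cluster labels, 0 = noise) are appended
    as an extra ``cluster`` column.
    """
    dialect = dialect or THUNDERSTORM
    df = t.data.copy()
    rename = {k: v for k, v in ColumnMap.standard_names.items() if k in df.columns}
    df = df.rename(columns=rename)
    if labels is not None:
        if len(labels) != t.n:
            raise DataError("labels length must match detection count")
        df["cluster"] = np.asarray(labels, dtype=int)
    df.to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# Pre-processing filters
# ---------------------------------------------------------------------------

def filter_by_intensity(t: DetectionTable, min_photons: float) -> DetectionTable:
    """Keep detections with intensity >= ``min_photons`` (inclusive); order preserved."""
    if t.intensity is None:
        raise MissingFieldError("intensity is required for the photon-count filter")
    return t.select(t.intensity >= min_photons)


def link_consecutive_frames(t: DetectionTable, max_dist: float = 75.0) -> DetectionTable:
    """Group detections found in strictly consecutive frames within ``max_dist``.

    A chain is grown greedily in frame order: a chain ending at frame ``f``
    claims the nearest unclaimed detection in frame ``f + 1`` within
    ``max_dist`` of its last position (ties broken toward the lower detection
    id; chains are serviced in order of their head id).  Each chain collapses
    to one detection with the intensity-weighted mean position (plain mean if
    intensity is absent), the summed intensity, the first frame and the
    minimum uncertainty of its members.
    """
    if max_dist <= 0:
        raise ParameterError("max_dist must be > 0")
    if t.frame is None:
        raise MissingFieldError("frame indices are required for frame linking")
    if t.n == 0:
        return t

    coords = t.coords
    frames = t.frame
    intensity = t.intensity
    uncertainty = t.uncertainty
    order_in_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        rows = np.nonzero(frames == f)[0]
        order_in_frame[int(f)] = rows[np.argsort(t.ids[rows])]

    chains: list[list[int]] = []          # row indices per chain
    open_by_frame: dict[int, list[int]] = {}  # frame -> chain indices ending there

    for f in sorted(order_in_frame):
        rows = order_in_frame[f]
        claimed = np.zeros(len(rows), dtype=bool)
        tree = cKDTree(coords[rows])
        # chains ending in the previous frame, serviced in head-id order
        for ci in sorted(open_by_frame.pop(f - 1, []), key=lambda c: t.ids[chains[c][0]]):
            last = coords[chains[ci][-1]]
            cand = tree.query_ball_point(last, max_dist)
            cand = [k for k in cand if not claimed[k]]
            if not cand:
                continue
            d = np.linalg.norm(coords[rows[cand]] - last, axis=1)
            best = min(zip(d, t.ids[rows[cand]], cand))[2]
            claimed[best] = True
            chains[ci].append(int(rows[best]))
            open_by_frame.setdefault(f, []).append(ci)
        for k, row in enumerate(rows):
            if not claimed[k]:
                chains.append([int(row)])
                open_by_frame.setdefault(f, []).append(len(chains) - 1)

    heads = [c[0] for c in chains]
    out = t.data.iloc[heads].copy()
    for j, chain in enumerate(chains):
        if len(chain) == 1:
            continue
        w = intensity[chain].astype(float) if intensity is not None else np.ones(len(chain))
        if w.sum() <= 0:
            w = np.ones(len(chain))
        pos = np.average(coords[chain], axis=0, weights=w)
        for a, name in enumerate(["x", "y", "z"][: t.dim]):
            out.iloc[j, out.columns.get_loc(name)] = pos[a]
        out.iloc[j, out.columns.get_loc("frame")] = frames[chain].min()
        if intensity is not None:
            out.iloc[j, out.columns.get_loc("intensity")] = intensity[chain].sum()
        if uncertainty is not None:
            out.iloc[j, out.columns.get_loc("uncertainty")] = uncertainty[chain].min()
    return DetectionTable(out)
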