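"""Trajectory containers and delimited-table import/export.

Internal units are SI throughout: coordinates in metres, the frame interval
``dt`` in seconds.  Import performs all unit conversion, so downstream
modules (descriptors, MSD fitting) never see pixels.  Frame indices are kept
as recorded by the tracker — they may contain gaps, and delay lags are
defined on frame-index differences, not row offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, TableParseError

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "read_trajectories",
    "write_trajectories",
    "filter_min_localizations",
    "DOM_COLUMN_MAP",
    "GENERIC_COLUMN_MAP",
]

#: Default column names for a generic delimited localization table.
GENERIC_COLUMN_MAP: dict[str, str] = {
    "track": "track",
    "frame": "frame",
    "x": "x",
    "y": "y",
    "z": "z",
}

#: Preset for tables exported by the DoM (Detection of Molecules) ImageJ
#: plug-in.  The exact schema varies between plug-in versions, so this preset
#: is always user-overridable via ``column_map``.
DOM_COLUMN_MAP: dict[str, str] = {
    "track": "Track_ID",
    "frame": "Frame_Number",
    "x": "X_(px)",
    "y": "Y_(px)",
    "z": "Z_(px)",
}


@dataclass(frozen=True)
class Trajectory:
    """One particle's time-ordered localizations.

    Parameters
    ----------
    id
        Opaque trajectory identifier (converted to ``str``).
    frames
        Integer frame indices, 0-based, strictly increasing.  Gaps are
        allowed: a tracker that bridges a missed detection produces
        non-consecutive indices.
    coords
        ``(n, d)`` array of positions in metres, ``d`` in {2, 3}.
    """

    id: str
    frames: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise DataError(
                f"trajectory {self.id!r}: coords must be (n, 2) or (n, 3), "
                f"got shape {coords.shape}"
            )
        if frames.ndim != 1 or len(frames) != len(coords):
            raise DataError(
                f"trajectory {self.id!r}: {len(frames)} frames for "
                f"{len(coords)} coordinate rows"
            )
        if len(frames) < 1:
            raise DataError(f"trajectory {self.id!r}: empty trajectory")
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise DataError(
                f"trajectory {self.id!r}: frame indices not strictly increasing"
            )
        if not np.all(np.isfinite(coords)):
            raise DataError(f"trajectory {self.id!r}: non-finite coordinates")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def ndim(self) -> int:
        return self.coords.shape[1]

    @property
    def xy(self) -> np.ndarray:
        """The in-plane (x, y) projection of the coordinates."""
        return self.coords[:, :2]


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing acquisition calibration.

    Parameters
    ----------
    trajectories
        The member trajectories; ids must be unique.
    dt
        Frame interval in seconds.
    pixel_size
        Metres per pixel used at import (1.0 when coordinates were already
        physical).
    labels
        Optional map trajectory id -> population name.
    """

    trajectories: list[Trajectory]
    dt: float
    pixel_size: float = 1.0
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise DataError(f"dt must be positive, got {self.dt}")
        if not self.pixel_size > 0:
            raise DataError(f"pixel_size must be positive, got {self.pixel_size}")
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise DataError("trajectory ids are not unique")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, tid: str) -> Trajectory:
        for t in self.trajectories:
            if t.id == tid:
                return t
        raise KeyError(tid)

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.trajectories]

    def subset(self, ids: Sequence[str]) -> "TrajectorySet":
        """Return a new set restricted to ``ids`` (order follows this set)."""
        keep = set(map(str, ids))
        trajs = [t for t in self.trajectories if t.id in keep]
        labels = {t.id: self.labels[t.id] for t in trajs if t.id in self.labels}
        return TrajectorySet(trajs, self.dt, self.pixel_size, labels)

    def with_labels(self, labels: Mapping[str, str]) -> "TrajectorySet":
        return replace(self, labels=dict(labels))


def _resolve_columns(
    df: pd.DataFrame, colmap: Mapping[str, str]
) -> dict[str, str | None]:
    resolved: dict[str, str | None] = {}
    for key in ("track", "frame", "x", "y"):
        name = colmap.get(key)
        if name is None or name not in df.columns:
            # the track column is allowed to be absent: rows become
            # single-point trajectories
            if key == "track":
                resolved[key] = None
                continue
            raise FormatError(
                f"required column {key!r} (mapped to {name!r}) not found; "
                f"available columns: {list(df.columns)}"
            )
        resolved[key] = name
    zname = colmap.get("z")
    resolved["z"] = zname if zname is not None and zname in df.columns else None
    return resolved


def _numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableParseError(
            f"non-numeric value {raw.iloc[row]!r} in column {col!r}, "
            f"data row {row}"
        )
    return vals.to_numpy(dtype=np.float64)


def read_trajectories(
    path: str | Path,
    *,
    dialect: str = "generic",
    column_map: Mapping[str, str] | None = None,
    pixel_size: float | None = None,
    dt: float | None = None,
    units: str | None = None,
    sep: str | None = None,
) -> TrajectorySet:
    """Read a delimited localization/tracking table into a :class:`TrajectorySet`.

    Parameters
    ----------
    path
        Delimited text file with one row per localization.  If a JSON
        sidecar ``<path>.json`` exists (as written by
        :func:`write_trajectories`), ``dt``, ``pixel_size``, ``units`` and
        population labels default to its values.
    dialect
        ``"generic"`` (column names ``track, frame, x, y[, z]``) or
        ``"dom"`` (preset for DoM ImageJ plug-in exports).  ``column_map``
        entries override the preset.
    column_map
        Map from the logical names ``track/frame/x/y/z`` to the file's
        column headers.
    pixel_size
        Metres per pixel; required when ``units == "pixels"``.
    dt
        Frame interval, seconds.
    units
        ``"pixels"`` (coordinates multiplied by ``pixel_size``) or
        ``"m"`` (already physical; no conversion).  Defaults to ``"pixels"``
        unless the sidecar declares otherwise.
    sep
        Field separator; autodetected when ``None``.

    Returns
    -------
    TrajectorySet
        Rows grouped by track id and sorted by frame; localizations without
        a track id become single-point trajectories.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar: dict = {}
    scpath = path.with_name(path.name + ".json")
    if scpath.exists():
        sidecar = json.loads(scpath.read_text())
    dt = dt if dt is not None else sidecar.get("dt")
    pixel_size = pixel_size if pixel_size is not None else sidecar.get("pixel_size")
    units = units if units is not None else sidecar.get("units", "pixels")
    if dt is None:
        raise FormatError("dt not given and no sidecar provides it")
    if units not in ("pixels", "m"):
        raise FormatError(f"unknown units {units!r}; expected 'pixels' or 'm'")
    if units == "pixels":
        if pixel_size is None:
            raise FormatError("pixel_size required for pixel-unit tables")
        scale = float(pixel_size)
    else:
        scale = 1.0
        pixel_size = pixel_size if pixel_size is not None else 1.0

    if dialect == "dom":
        colmap = dict(DOM_COLUMN_MAP)
    elif dialect == "generic":
        colmap = dict(GENERIC_COLUMN_MAP)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    if column_map:
        colmap.update(column_map)

    if sep is None:
        import csv as _csv

        with open(path) as fh:
            header = fh.readline()
        try:
            sep = _csv.Sniffer().sniff(header, delimiters=",;\t ").delimiter
        except _csv.Error:
            sep = ","
    # round_trip parsing so repr-precision exports reload bit-identically
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = _resolve_columns(df, colmap)

    frames = _numeric(df, cols["frame"]).astype(np.int64)
    xyz = [_numeric(df, cols["x"]) * scale, _numeric(df, cols["y"]) * scale]
    if cols["z"] is not None:
        xyz.append(_numeric(df, cols["z"]) * scale)
    coords = np.column_stack(xyz)

    if cols["track"] is not None:
        track_raw = df[cols["track"]]
    else:
        track_raw = pd.Series([np.nan] * len(df))

    trajectories: list[Trajectory] = []
    has_track = track_raw.notna().to_numpy()

    if has_track.any():
        rows = np.flatnonzero(has_track)
        tids = track_raw[has_track].astype(str).to_numpy()
        tframes = frames[has_track]
        tcoords = coords[has_track]
        order = np.lexsort((tframes, tids))
        tids_s, tframes_s, tcoords_s = tids[order], tframes[order], tcoords[order]
        dup = (tids_s[1:] == tids_s[:-1]) & (tframes_s[1:] == tframes_s[:-1])
        if dup.any():
            i = int(np.flatnonzero(dup)[0]) + 1
            raise DataError(
                f"duplicate (track, frame) pair: track {tids_s[i]!r}, "
                f"frame {tframes_s[i]}"
            )
        bounds = np.flatnonzero(np.r_[True, tids_s[1:] != tids_s[:-1], True])
        groups = [
            (int(rows[order[a:b]].min()), a, b)
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        # keep the file's first-appearance order of tracks
        for _, a, b in sorted(groups):
            trajectories.append(
                Trajectory(tids_s[a], tframes_s[a:b], tcoords_s[a:b])
            )

    for j in np.flatnonzero(~has_track):
        trajectories.append(
            Trajectory(f"_orphan_{j}", frames[j : j + 1], coords[j : j + 1])
        )

    labels = {str(k): str(v) for k, v in sidecar.get("labels", {}).items()}
    labels = {k: v for k, v in labels.items() if k in {t.id for t in trajectories}}
    return TrajectorySet(trajectories, float(dt), float(pixel_size), labels)


def write_trajectories(set_: TrajectorySet, path: str | Path) -> None:
    """Write a trajectory set as a CSV table plus a JSON sidecar.

    Coordinates are written in metres at full ``repr`` precision so that
    ``read_trajectories(write_trajectories(s))`` round-trips ids, frames and
    coordinates exactly.  The sidecar ``<path>.json`` records ``dt``,
    ``pixel_size``, the unit declaration and any population labels.
    """
    path = Path(path)
    ndim = max((t.ndim for t in set_.trajectories), default=2)
    cols = ["track", "frame", "x", "y"] + (["z"] if ndim == 3 else [])
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for t in set_.trajectories:
            for i in range(t.n_points):
                row = [t.id, str(int(t.frames[i]))]
                row += [repr(float(v)) for v in t.coords[i]]
                if ndim == 3 and t.ndim == 2:
                    row.append("nan")
                fh.write(",".join(row) + "\n")
    sidecar = {
        "dt": set_.dt,
        "pixel_size": set_.pixel_size,
        "units": "m",
        "labels": set_.labels,
    }
    path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=1))


def filter_min_localizations(set_: TrajectorySet, min_n: int = 5) -> TrajectorySet:
    """Return the subset of trajectories with at least ``min_n`` localizations.

    Very short tracks carry ill-defined shape descriptors and MSD curves
    with fewer than four points, and spurious localizations from camera
    noise rarely link into tracks of five or more frames — hence the default
    threshold of five.  Order is preserved and the input is not modified.
    """
    if min_n < 1:
        raise DataError(f"min_n must be >= 1, got {min_n}")
    trajs = [t for t in set_.trajectories if t.n_points >= min_n]
    labels = {t.id: set_.labels[t.id] for t in trajs if t.id in set_.labels}
    return TrajectorySet(trajs, set_.dt, set_.pixel_size, labels)
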