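"""Track container, point-table I/O, validation, and pre-analysis filtering.

A :class:`Track` is an ordered, strictly time-increasing sequence of fixes
for one animal, either in geographic coordinates (longitude/latitude,
decimal degrees) or planar coordinates (x/y, kilometres by convention).
Timestamps are stored as seconds since the Unix epoch (UTC) so that
residence-time arithmetic is unambiguous; input parsing accepts ISO 8601
strings and numeric epoch seconds.

Duplicate timestamps are rejected rather than merged: residence-time
accumulation assumes strictly positive time steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DistanceMetric, metric_for

__all__ = [
    "TrackPoint",
    "Track",
    "TrackValidationError",
    "read_track",
    "read_tracks",
    "filter_near_point",
    "write_rst_table",
    "read_rst_table",
]


class TrackValidationError(ValueError):
    """Raised when a point table violates the track invariants."""


@dataclass(frozen=True)
class TrackPoint:
    """One fix: ordinal index, epoch-second timestamp, position, optional label."""

    index: int
    timestamp: float
    x: float
    y: float
    label: str | None = None

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


class Track:
    """An ordered, validated sequence of fixes for one animal.

    Parameters
    ----------
    times
        Epoch seconds (UTC), strictly increasing.
    x, y
        Longitude/latitude in degrees (``crs_mode="geographic"``) or planar
        coordinates in km (``crs_mode="planar"``).
    labels
        Optional per-point behavior annotations (simulator truth or expert
        labels).
    source_index
        When this track is a subsample of a parent track, the parent indices
        of the retained points; used by agreement scoring.
    """

    def __init__(
        self,
        times: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        animal_id: str = "track",
        crs_mode: str = "geographic",
        labels: Sequence[str] | None = None,
        source_index: Sequence[int] | None = None,
    ):
        self.times = np.asarray(times, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.animal_id = str(animal_id)
        if crs_mode not in ("geographic", "planar"):
            raise ValueError(f"crs_mode must be 'geographic' or 'planar', got {crs_mode!r}")
        self.crs_mode = crs_mode
        self.labels = None if labels is None else np.asarray(labels, dtype=object)
        self.source_index = None if source_index is None else np.asarray(source_index, dtype=int)
        self._validate()

    def _validate(self) -> None:
        n = self.times.size
        if n < 1:
            raise TrackValidationError("a track needs at least one point")
        if not (self.x.size == n and self.y.size == n):
            raise TrackValidationError("times and coordinates have mismatched lengths")
        if self.labels is not None and self.labels.size != n:
            raise TrackValidationError("labels length does not match point count")
        if self.source_index is not None and self.source_index.size != n:
            raise TrackValidationError("source_index length does not match point count")
        for name, arr in (("timestamp", self.times), ("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TrackValidationError(f"non-finite {name} at row {bad}")
        dt = np.diff(self.times)
        if np.any(dt == 0):
            bad = int(np.flatnonzero(dt == 0)[0])
            raise TrackValidationError(
                f"duplicate timestamp at rows {bad} and {bad + 1}; "
                "duplicate fixes must be resolved before analysis"
            )
        if np.any(dt < 0):
            raise TrackValidationError("timestamps must be strictly increasing")
        if self.crs_mode == "geographic":
            if np.any(np.abs(self.y) > 90.0):
                raise TrackValidationError("latitude out of [-90, 90]")
            if np.any(np.abs(self.x) > 180.0):
                raise TrackValidationError("longitude out of [-180, 180]")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[TrackPoint]:
        return iter(self.points)

    @property
    def points(self) -> list[TrackPoint]:
        labs = self.labels if self.labels is not None else [None] * len(self)
        return [
            TrackPoint(i, float(t), float(px), float(py), lab)
            for i, (t, px, py, lab) in enumerate(zip(self.times, self.x, self.y, labs))
        ]

    @property
    def sampling_interval_min(self) -> tuple[float, float]:
        """(mean, SD) of the fix interval in minutes; (nan, nan) for one point."""
        if len(self) < 2:
            return (float("nan"), float("nan"))
        dt_min = np.diff(self.times) / 60.0
        return (float(np.mean(dt_min)), float(np.std(dt_min)))

    @property
    def metric(self) -> DistanceMetric:
        return metric_for(self.crs_mode)

    def replace(self, **kw) -> "Track":
        """A copy with the given constructor fields replaced."""
        base = dict(
            times=self.times,
            x=self.x,
            y=self.y,
            animal_id=self.animal_id,
            crs_mode=self.crs_mode,
            labels=self.labels,
            source_index=self.source_index,
        )
        base.update(kw)
        return Track(**base)

    def take(self, idx: np.ndarray) -> "Track":
        """Subset by positional indices, recording them as source_index."""
        idx = np.asarray(idx, dtype=int)
        parent = self.source_index[idx] if self.source_index is not None else idx
        return Track(
            self.times[idx],
            self.x[idx],
            self.y[idx],
            animal_id=self.animal_id,
            crs_mode=self.crs_mode,
            labels=None if self.labels is None else self.labels[idx],
            source_index=parent,
        )

    def split_on_gaps(self, max_gap_min: float) -> list["Track"]:
        """Split where the fix interval exceeds ``max_gap_min`` minutes.

        Tracks are not split by default anywhere in the package: under the
        residence analysis a fix isolated by a large gap simply scores zero
        residence and classifies as transit. This helper exists for users
        who prefer explicit segmentation.
        """
        if len(self) < 2:
            return [self]
        cuts = np.flatnonzero(np.diff(self.times) > max_gap_min * 60.0) + 1
        pieces = np.split(np.arange(len(self)), cuts)
        return [self.take(p) for p in pieces if p.size]

    def to_frame(self) -> pd.DataFrame:
        cx, cy = ("lon", "lat") if self.crs_mode == "geographic" else ("x", "y")
        df = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": pd.to_datetime(self.times, unit="s", utc=True),
                cx: self.x,
                cy: self.y,
            }
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def __repr__(self) -> str:
        mean, sd = self.sampling_interval_min
        return (
            f"Track({self.animal_id!r}, n={len(self)}, crs={self.crs_mode}, "
            f"interval={mean:.2f}±{sd:.2f} min)"
        )


_DEFAULT_COLUMNS = {
    "geographic": {"id": "animal_id", "timestamp": "timestamp", "x": "lon", "y": "lat"},
    "planar": {"id": "animal_id", "timestamp": "timestamp", "x": "x", "y": "y"},
}


def _parse_times(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, utc=True, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0])
        raise TrackValidationError(
            f"unparseable timestamp {col.iloc[row]!r} at row {row}; "
            "expected ISO 8601 or epoch seconds"
        )
    return parsed.astype("int64").to_numpy() / 1e9


def _track_from_frame(df: pd.DataFrame, cols: Mapping[str, str], crs_mode: str, animal_id: str) -> Track:
    times = _parse_times(df[cols["timestamp"]].reset_index(drop=True))
    order = np.argsort(times, kind="stable")
    labels = None
    if "label" in cols and cols["label"] in df.columns:
        labels = df[cols["label"]].to_numpy(dtype=object)[order]
    return Track(
        times[order],
        df[cols["x"]].to_numpy(dtype=float)[order],
        df[cols["y"]].to_numpy(dtype=float)[order],
        animal_id=animal_id,
        crs_mode=crs_mode,
        labels=labels,
    )


def read_tracks(
    path,
    column_map: Mapping[str, str] | None = None,
    crs_mode: str = "geographic",
    delimiter: str | None = None,
) -> list[Track]:
    """Read a delimited point table, one :class:`Track` per animal id.

    ``column_map`` maps the logical fields ``id``, ``timestamp``, ``x``,
    ``y`` (and optionally ``label``) to column names in the file; fields
    left out fall back to ``animal_id``/``timestamp``/``lon``/``lat`` (or
    ``x``/``y`` in planar mode). The id column is optional — without it the
    whole file is one track named after the file stem. Rows are sorted by
    time; duplicate timestamps within an animal are an error.
    """
    cols = dict(_DEFAULT_COLUMNS[crs_mode])
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if len(df) < 1:
        raise TrackValidationError(f"{path}: no data rows")
    for field in ("timestamp", "x", "y"):
        if cols[field] not in df.columns:
            raise TrackValidationError(
                f"{path}: missing column {cols[field]!r} for field {field!r} "
                f"(available: {list(df.columns)})"
            )
    if "label" in df.columns and "label" not in cols:
        cols["label"] = "label"
    if cols.get("id") in df.columns:
        return [
            _track_from_frame(sub, cols, crs_mode, str(aid))
            for aid, sub in df.groupby(cols["id"], sort=False)
        ]
    import os

    stem = os.path.splitext(os.path.basename(str(path)))[0]
    return [_track_from_frame(df, cols, crs_mode, stem)]


def read_track(
    path,
    column_map: Mapping[str, str] | None = None,
    crs_mode: str = "geographic",
    delimiter: str | None = None,
) -> Track:
    """Read a point table that holds exactly one track."""
    tracks = read_tracks(path, column_map, crs_mode, delimiter)
    if len(tracks) != 1:
        raise TrackValidationError(
            f"{path}: expected one track, found {len(tracks)} animal ids; use read_tracks"
        )
    return tracks[0]


def filter_near_point(
    track: Track, center: tuple[float, float], radius_km: float
) -> tuple[Track, int]:
    """Drop fixes within ``radius_km`` of a fixed position (e.g. a colony).

    Returns the filtered track and the number of points removed. Points at
    distance exactly ``radius_km`` are kept (only the open disc is removed).
    Order is preserved; the operation is idempotent.
    """
    if radius_km < 0:
        raise ValueError("radius_km must be >= 0")
    d = track.metric.distances_to(track.x, track.y, center[0], center[1])
    keep = np.flatnonzero(d > radius_km)
    removed = len(track) - keep.size
    if keep.size == 0:
        warnings.warn(
            f"filter_near_point removed every fix of {track.animal_id!r}", stacklevel=2
        )
        return _EmptyTrack(track), removed
    return track.take(keep), removed


class _EmptyTrack:
    """Zero-point sentinel returned when a filter removes every fix."""

    def __init__(self, parent: Track):
        self.animal_id = parent.animal_id
        self.crs_mode = parent.crs_mode
        self.times = np.empty(0)
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.labels = None
        self.source_index = np.empty(0, dtype=int)

    def __len__(self) -> int:
        return 0


RST_TABLE_COLUMNS = [
    "index",
    "timestamp",
    "coord_x",
    "coord_y",
    "rt_hr",
    "rd",
    "rt_norm",
    "rd_norm",
    "residual",
    "state",
]


def write_rst_table(result, path) -> None:
    """Write a residence analysis as a CSV, one row per fix.

    Columns: ``index, timestamp, coord_x, coord_y, rt_hr, rd, rt_norm,
    rd_norm, residual, state``. ``coord_x/coord_y`` are lon/lat degrees for
    geographic tracks, planar km otherwise; ``rt_hr`` is residence time in
    hours and ``rd`` residence distance in the metric unit (km). Floats are
    written at full precision so the table round-trips.
    """
    result.to_frame().to_csv(path, index=False, columns=RST_TABLE_COLUMNS)


def read_rst_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_rst_table`."""
    return pd.read_csv(path)
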