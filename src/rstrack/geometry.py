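"""Distance computations between track fixes.

Two coordinate modes are supported:

* ``geographic`` — positions are (longitude, latitude) in decimal degrees;
  distances are great-circle (haversine) kilometres on a sphere of radius
  6371.0088 km (the IUGG mean Earth radius). Sub-half-percent ellipsoidal
  error is negligible at the spatial scales of residence analysis.
* ``planar`` — positions are projected (x, y); distances are Euclidean in
  whatever unit the coordinates carry (kilometres by convention).

The circle radius R and re-entry threshold Th of the residence analysis are
interpreted in the same unit as the metric output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088

_MODES = ("haversine_km", "euclidean")


def haversine_km(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def euclidean(x1, y1, x2, y2):
    """Planar Euclidean distance; accepts scalars or broadcastable arrays."""
    x1, y1, x2, y2 = (np.asarray(v, dtype=float) for v in (x1, y1, x2, y2))
    return np.hypot(x2 - x1, y2 - y1)


@dataclass(frozen=True)
class DistanceMetric:
    """A distance function over positions.

    mode
        ``haversine_km`` for (lon, lat) degrees, output in km;
        ``euclidean`` for planar (x, y) in coordinate units.
    earth_radius_km
        Sphere radius used in haversine mode only.
    """

    mode: str = "euclidean"
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown metric mode {self.mode!r}; expected one of {_MODES}")

    def distance(self, a, b):
        """Distance between two positions (each a (x, y) / (lon, lat) pair)."""
        if self.mode == "haversine_km":
            return float(haversine_km(a[0], a[1], b[0], b[1], self.earth_radius_km))
        return float(euclidean(a[0], a[1], b[0], b[1]))

    def distances_to(self, x, y, x0: float, y0: float) -> np.ndarray:
        """Vectorised distances from coordinate arrays (x, y) to one focal position."""
        if self.mode == "haversine_km":
            return haversine_km(x, y, x0, y0, self.earth_radius_km)
        return euclidean(x, y, x0, y0)

    def pair_steps(self, x, y) -> np.ndarray:
        """Consecutive-pair distances along coordinate arrays (length n-1)."""
        if self.mode == "haversine_km":
            return haversine_km(x[:-1], y[:-1], x[1:], y[1:], self.earth_radius_km)
        return euclidean(x[:-1], y[:-1], x[1:], y[1:])


def metric_for(crs_mode: str) -> DistanceMetric:
    """The natural metric for a track CRS mode (geographic -> haversine km)."""
    if crs_mode == "geographic":
        return DistanceMetric("haversine_km")
    if crs_mode == "planar":
        return DistanceMetric("euclidean")
    raise ValueError(f"unknown crs_mode {crs_mode!r}")


def check_metric(metric: DistanceMetric, crs_mode: str) -> None:
    """Raise if a metric is applied to a track in the wrong CRS mode."""
    want = "haversine_km" if crs_mode == "geographic" else "euclidean"
    if metric.mode != want:
        raise ValueError(
            f"metric mode {metric.mode!r} cannot be applied to a {crs_mode!r} track"
        )


def point_distance(a, b, metric: DistanceMetric) -> float:
    """Distance between two positions under the given metric."""
    return metric.distance(a, b)


def step_lengths(track, metric: DistanceMetric | None = None) -> np.ndarray:
    """Distances between consecutive fixes of a track (length n-1, all >= 0)."""
    if metric is None:
        metric = metric_for(track.crs_mode)
    else:
        check_metric(metric, track.crs_mode)
    if len(track) < 2:
        return np.empty(0, dtype=float)
    return metric.pair_steps(track.x, track.y)
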