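"""Residence in Space and Time (RST): the core per-point computation.

For every fix a circle of radius R is centred on it and two quantities are
accumulated over the maximal contiguous stretch of track connected to the
fix inside that circle:

* residence time (RT) — the sum of time intervals between consecutive
  included fixes, in hours;
* residence distance (RD) — the sum of path lengths between consecutive
  included fixes, in the metric unit (km for geographic tracks).

Boundary "tails" — the partial path segments between the first/last
included fix and the circle perimeter — are never added; a fix alone in its
circle scores RT = RD = 0. If the trajectory exits the circle and re-enters
having travelled no more than a threshold path length Th outside, the whole
excursion (outside stretch included) is kept and the walk continues;
otherwise the walk stops at the last in-circle fix. The default Th = 0
disables excursions entirely.

Each sequence is then normalised by its own track maximum and the per-point
residual is

    residual = RD / max(RD)  -  RT / max(RT),

a unitless value in [-1, 1] whose sign partitions behavior states: zero is
transit, positive is time-&-distance-intensive movement (area-restricted
search), negative is time-intensive movement (rest at fine scales,
concentrated feeding at coarse ones). The sign test is exact — transit is
defined by the exact zeros arising from RT = RD = 0 — and the rare points
whose residual is exactly zero despite nonzero RT/RD are flagged for
inspection rather than silently folded in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DistanceMetric, check_metric, metric_for, step_lengths
from .track import Track

__all__ = [
    "TRANSIT",
    "ARS",
    "REST",
    "STATES",
    "RSTParams",
    "RSTResult",
    "included_runs",
    "residence_values",
    "normalize_and_residuals",
    "classify",
    "run_rst",
]

#: State names. ``ars`` is the time-&-distance-intensive class (positive
#: residual), ``rest`` the time-intensive class (negative residual).
TRANSIT = "transit"
ARS = "ars"
REST = "rest"
STATES = (TRANSIT, ARS, REST)


@dataclass(frozen=True)
class RSTParams:
    """Analysis parameters: circle radius R, re-entry threshold Th, metric.

    ``radius_R`` and ``threshold_Th`` are in the metric's output unit (km
    for haversine). ``metric=None`` selects the track's natural metric at
    run time.
    """

    radius_R: float
    threshold_Th: float = 0.0
    metric: DistanceMetric | None = None

    def __post_init__(self):
        if not self.radius_R > 0:
            raise ValueError("radius_R must be > 0")
        if self.threshold_Th < 0:
            raise ValueError("threshold_Th must be >= 0")

    def resolve_metric(self, track: Track) -> DistanceMetric:
        if self.metric is None:
            return metric_for(track.crs_mode)
        check_metric(self.metric, track.crs_mode)
        return self.metric


def _extend(inside: np.ndarray, steps: np.ndarray, start: int, direction: int, th: float) -> int:
    """Walk from ``start`` in ``direction``; return the last included index.

    ``inside`` marks fixes within R of the focal position. Consecutive
    in-circle fixes extend the run directly. On exit, the path length of the
    full segments from the last in-circle fix to the next in-circle fix is
    the excursion's outside travel; the excursion is kept iff that length
    <= th. steps[j] is the segment length between fixes j and j+1.
    """
    n = inside.size
    pos = start
    j = start + direction
    while 0 <= j < n:
        if inside[j]:
            pos = j
            j += direction
            continue
        # find the next in-circle fix beyond this outside stretch
        k = j
        while 0 <= k < n and not inside[k]:
            k += direction
        if not (0 <= k < n):
            break
        lo, hi = (pos, k) if direction > 0 else (k, pos)
        outside_len = float(np.sum(steps[lo:hi]))
        if outside_len <= th:
            pos = k
            j = k + direction
        else:
            break
    return pos


def included_runs(
    track: Track,
    params: RSTParams,
    _dist_to_focal=None,
) -> tuple[np.ndarray, np.ndarray]:
    """First and last included index of every fix's in-circle run.

    For fix i the included stretch is the contiguous index range
    ``[lo[i], hi[i]]`` found by walking backward and forward from i,
    keeping fixes within R of i's position and any qualifying excursions
    (outside travel <= Th). ``lo[i] == hi[i] == i`` marks a fix alone in
    its circle.

    ``_dist_to_focal`` is an internal hook: a callable ``i -> distances from
    every fix to fix i`` (used by the radius scan to reuse one precomputed
    distance matrix across radii).
    """
    metric = params.resolve_metric(track)
    n = len(track)
    lo = np.arange(n)
    hi = np.arange(n)
    if n < 2:
        return lo, hi
    steps = step_lengths(track, metric)
    x, y = track.x, track.y
    if _dist_to_focal is None:
        _dist_to_focal = lambda i: metric.distances_to(x, y, x[i], y[i])  # noqa: E731
    th = params.threshold_Th
    for i in range(n):
        inside = _dist_to_focal(i) <= params.radius_R  # closed disc
        if th == 0:
            # Th = 0 admits no excursion (an outside stretch always has
            # positive path length), so the run is just the maximal block of
            # consecutive in-circle fixes around i.
            outside = ~inside
            after = outside[i + 1 :]
            k = int(np.argmax(after)) if after.size else 0
            hi[i] = i + k if (after.size and after[k]) else n - 1
            before = outside[:i][::-1]
            k = int(np.argmax(before)) if before.size else 0
            lo[i] = i - k if (before.size and before[k]) else 0
        else:
            lo[i] = _extend(inside, steps, i, -1, th)
            hi[i] = _extend(inside, steps, i, +1, th)
    return lo, hi


def residence_values(
    track: Track,
    params: RSTParams,
    _dist_to_focal=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point residence time (hours) and residence distance (metric unit)."""
    n = len(track)
    rt = np.zeros(n)
    rd = np.zeros(n)
    if n < 2:
        return rt, rd
    lo, hi = included_runs(track, params, _dist_to_focal)
    steps = step_lengths(track, params.resolve_metric(track))
    t = track.times
    for i in range(n):
        if hi[i] > lo[i]:
            rt[i] = (t[hi[i]] - t[lo[i]]) / 3600.0
            rd[i] = float(np.sum(steps[lo[i] : hi[i]]))
    return rt, rd


def normalize_and_residuals(
    rt: np.ndarray, rd: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide each sequence by its track maximum and subtract.

    Returns ``(rt_norm, rd_norm, residuals)`` with
    ``residuals = rd_norm - rt_norm``. A sequence whose maximum is zero
    normalises to all zeros (a degenerate all-transit track).
    """
    rt = np.asarray(rt, dtype=float)
    rd = np.asarray(rd, dtype=float)
    if rt.shape != rd.shape:
        raise ValueError("rt and rd must have equal length")
    if np.any(rt < 0) or np.any(rd < 0):
        raise ValueError("residence values must be >= 0")
    max_rt = float(rt.max()) if rt.size else 0.0
    max_rd = float(rd.max()) if rd.size else 0.0
    rt_norm = rt / max_rt if max_rt > 0 else np.zeros_like(rt)
    rd_norm = rd / max_rd if max_rd > 0 else np.zeros_like(rd)
    return rt_norm, rd_norm, rd_norm - rt_norm


def classify(residuals: np.ndarray) -> np.ndarray:
    """Map residual signs to states: >0 ars, <0 rest, ==0 transit (exact)."""
    residuals = np.asarray(residuals, dtype=float)
    states = np.full(residuals.shape, TRANSIT, dtype=object)
    states[residuals > 0] = ARS
    states[residuals < 0] = REST
    return states


@dataclass
class RSTResult:
    """Per-point residence analysis of one track at one (R, Th).

    ``ambiguous_zero`` flags points whose residual is exactly zero while
    RT and RD are both positive — a coincidental cancellation rather than
    an isolated fix; such collisions are rare but worth inspecting.
    """

    track: Track
    params: RSTParams
    rt: np.ndarray
    rd: np.ndarray
    rt_norm: np.ndarray
    rd_norm: np.ndarray
    residual: np.ndarray
    state: np.ndarray
    max_rt: float
    max_rd: float
    ambiguous_zero: np.ndarray = field(default=None)

    def state_counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.state == s)) for s in STATES}

    def isolated_fraction(self) -> float:
        """Fraction of fixes alone in their circle (RT = RD = 0).

        This is the transit fraction net of coincidental zero residuals;
        unlike the raw transit fraction it is provably non-increasing in R.
        """
        n = self.residual.size
        return float(np.mean((self.rt == 0) & (self.rd == 0))) if n else 0.0

    def state_fractions(self) -> dict[str, float]:
        n = self.residual.size
        return {s: (c / n if n else 0.0) for s, c in self.state_counts().items()}

    def to_frame(self) -> pd.DataFrame:
        tr = self.track
        return pd.DataFrame(
            {
                "index": np.arange(len(tr)),
                "timestamp": pd.to_datetime(tr.times, unit="s", utc=True).strftime(
                    "%Y-%m-%dT%H:%M:%S.%f%z"
                ),
                "coord_x": tr.x,
                "coord_y": tr.y,
                "rt_hr": self.rt,
                "rd": self.rd,
                "rt_norm": self.rt_norm,
                "rd_norm": self.rd_norm,
                "residual": self.residual,
                "state": self.state,
                "ambiguous_zero": self.ambiguous_zero,
            }
        )

    def summary(self) -> dict:
        f = self.state_fractions()
        return {
            "animal_id": self.track.animal_id,
            "n_points": len(self.track),
            "radius_R": self.params.radius_R,
            "threshold_Th": self.params.threshold_Th,
            "pct_transit": 100.0 * f[TRANSIT],
            "pct_ars": 100.0 * f[ARS],
            "pct_rest": 100.0 * f[REST],
            "max_rt_hr": self.max_rt,
            "max_rd": self.max_rd,
        }


def run_rst(track: Track, params: RSTParams, _dist_to_focal=None) -> RSTResult:
    """Full analysis: residence values, normalisation, residuals, states."""
    rt, rd = residence_values(track, params, _dist_to_focal)
    rt_norm, rd_norm, residual = normalize_and_residuals(rt, rd)
    state = classify(residual)
    ambiguous = (residual == 0.0) & (rt > 0) & (rd > 0)
    return RSTResult(
        track=track,
        params=params,
        rt=rt,
        rd=rd,
        rt_norm=rt_norm,
        rd_norm=rd_norm,
        residual=residual,
        state=state,
        max_rt=float(rt.max()) if rt.size else 0.0,
        max_rd=float(rd.max()) if rd.size else 0.0,
        ambiguous_zero=ambiguous,
    )
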