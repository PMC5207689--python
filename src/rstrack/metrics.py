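"""Classical movement metrics on the same spatial window as the residence
analysis: per-point speed, path straightness, and Barraquand–Benhamou-style
residence time/distance that include the boundary "tails".

These exist for side-by-side comparison with the residual classification;
each is computed over the same included run of fixes used by the core
analysis, so the comparison is at a single spatial scale R.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import RSTParams, included_runs, residence_values
from .geometry import step_lengths
from .track import Track

__all__ = [
    "point_speed",
    "straightness_index",
    "residence_time_bb",
    "residence_with_tails",
    "metrics_table",
    "metric_histograms",
]


def point_speed(track: Track, centered: bool = False) -> np.ndarray:
    """Per-point speed in metric units per hour (km/hr for geographic tracks).

    Trailing difference by default: speed(i) = distance(i-1, i) / dt(i-1, i),
    with the first point (or first and last, if ``centered``) NaN. The
    centered option averages over (i-1, i+1).
    """
    n = len(track)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    steps = step_lengths(track)
    dt_hr = np.diff(track.times) / 3600.0
    if centered:
        out[1:-1] = (steps[:-1] + steps[1:]) / (dt_hr[:-1] + dt_hr[1:])
    else:
        out[1:] = steps / dt_hr
    return out


def straightness_index(track: Track, params: RSTParams) -> tuple[np.ndarray, np.ndarray]:
    """Net displacement over cumulative path length, within each fix's run.

    For every fix the run is the Th = 0 in-circle stretch used by the
    residence analysis; straightness is the straight-line distance between
    the run's first and last fix divided by the path length along it, in
    [0, 1]. Fixes whose run has zero path length (isolated or stationary)
    are defined as perfectly straight (1.0) and flagged in the returned
    boolean array.
    """
    metric = params.resolve_metric(track)
    p0 = RSTParams(params.radius_R, 0.0, params.metric)
    lo, hi = included_runs(track, p0)
    steps = step_lengths(track, metric)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    n = len(track)
    straight = np.ones(n)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        path = cum[hi[i]] - cum[lo[i]]
        if path > 0:
            net = metric.distance(
                (track.x[lo[i]], track.y[lo[i]]), (track.x[hi[i]], track.y[hi[i]])
            )
            straight[i] = min(net / path, 1.0)
        else:
            degenerate[i] = True
    return straight, degenerate


def _perimeter_fraction(metric, focal_xy, inner_xy, outer_xy, radius, tol=1e-12):
    """Fraction of the segment inner->outer lying inside the circle.

    The crossing point is located by bisection on the distance to the focal
    position along the linearly parametrised segment (distance at the inner
    end <= R < distance at the outer end).
    """
    a, b = 0.0, 1.0  # parameter from inner (inside) to outer (outside)
    for _ in range(60):
        m = 0.5 * (a + b)
        p = (
            inner_xy[0] + m * (outer_xy[0] - inner_xy[0]),
            inner_xy[1] + m * (outer_xy[1] - inner_xy[1]),
        )
        if metric.distance(focal_xy, p) <= radius:
            a = m
        else:
            b = m
        if b - a < tol:
            break
    return 0.5 * (a + b)


def residence_with_tails(
    track: Track, params: RSTParams
) -> tuple[np.ndarray, np.ndarray]:
    """Residence time (hours) and distance including boundary tails.

    The core residence values are augmented with the estimated time and
    path length from the run's first/last fix out to the circle perimeter,
    by linear space-time interpolation along the first exiting segment
    (constant speed within a segment). Where the run reaches the track end
    no tail exists on that side. This mirrors the classical residence-time
    construction of Barraquand & Benhamou.
    """
    metric = params.resolve_metric(track)
    rt, rd = residence_values(track, params)
    rt_bb = rt.copy()
    rd_bb = rd.copy()
    n = len(track)
    if n < 2:
        return rt_bb, rd_bb
    lo, hi = included_runs(track, params)
    steps = step_lengths(track, metric)
    dt_hr = np.diff(track.times) / 3600.0
    xy = list(zip(track.x, track.y))
    for i in range(n):
        focal = xy[i]
        if lo[i] > 0:
            j = lo[i]
            f = _perimeter_fraction(metric, focal, xy[j], xy[j - 1], params.radius_R)
            rt_bb[i] += f * dt_hr[j - 1]
            rd_bb[i] += f * steps[j - 1]
        if hi[i] < n - 1:
            j = hi[i]
            f = _perimeter_fraction(metric, focal, xy[j], xy[j + 1], params.radius_R)
            rt_bb[i] += f * dt_hr[j]
            rd_bb[i] += f * steps[j]
    return rt_bb, rd_bb


def residence_time_bb(track: Track, params: RSTParams) -> np.ndarray:
    """Residence time in hours including tails; >= the core RT point-wise."""
    return residence_with_tails(track, params)[0]


def metrics_table(track: Track, params: RSTParams) -> pd.DataFrame:
    """All comparison metrics for one track at one radius, one row per fix."""
    straight, degenerate = straightness_index(track, params)
    rt_bb, rd_bb = residence_with_tails(track, params)
    return pd.DataFrame(
        {
            "index": np.arange(len(track)),
            "speed": point_speed(track),
            "straightness": straight,
            "straightness_degenerate": degenerate,
            "rt_bb_hr": rt_bb,
            "rd_bb": rd_bb,
        }
    )


def metric_histograms(
    values: np.ndarray, labels: np.ndarray, bins: int = 20
) -> pd.DataFrame:
    """Per-label frequency table of a metric (histogram comparison input).

    Bin edges are shared across labels so the distributions are directly
    comparable; NaN values are dropped. Returns a tidy frame with columns
    ``bin_left, bin_right, label, count``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "label", "count"])
    edges = np.histogram_bin_edges(values, bins=bins)
    rows = []
    for lab in pd.unique(labels):
        counts, _ = np.histogram(values[labels == lab], bins=edges)
        for k, c in enumerate(counts):
            rows.append((edges[k], edges[k + 1], lab, int(c)))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "label", "count"])
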