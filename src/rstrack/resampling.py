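"""Temporal subsampling experiments and behavior-state agreement scoring.

These tools ask how robust the residual classification is to coarser or
erratic sampling: a track is subsampled (regularly, to mimic longer duty
cycles; or stochastically, to mimic satellite-telemetry dropout), the
analysis is re-run — re-selecting the radius dynamically for the new
interval — and each retained fix's state is compared to its state in the
native-interval reference analysis. Agreement is scored over retained
points only; states are never interpolated back onto dropped fixes.

The mechanism the experiments expose is bout length: behaviors whose bouts
are long relative to the sampling interval (rest, typically) survive
subsampling, while short-bout behaviors (area-restricted search, short
transits) are increasingly misclassified once the interval exceeds the
bout length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import STATES, RSTParams, RSTResult, run_rst
from .scales import dynamic_radius, select_dynamic_radius
from .track import Track

__all__ = [
    "AgreementReport",
    "subsample_regular",
    "subsample_stochastic",
    "state_agreement",
    "run_resolution_experiment",
    "run_stochastic_experiment",
]

DEFAULT_INTERVALS_MIN = (10, 20, 30, 60, 120, 180)


def subsample_regular(track: Track, interval_min: float) -> Track:
    """Thin a track to roughly one fix per ``interval_min`` minutes.

    Greedy nearest-to-grid selection: keep the first fix, then repeatedly
    keep the earliest fix at least ``interval_min`` minus half the native
    interval after the last kept fix. Parent indices are recorded on the
    result (``source_index``). The interval must be at least the native
    mean interval.
    """
    native, _ = track.sampling_interval_min
    if np.isfinite(native) and interval_min < native * (1 - 1e-9):
        raise ValueError(
            f"subsample interval {interval_min} min is below the native interval "
            f"{native:.3g} min"
        )
    threshold_s = (interval_min - native / 2.0) * 60.0
    t = track.times
    kept = [0]
    for j in range(1, len(track)):
        if t[j] >= t[kept[-1]] + threshold_s:
            kept.append(j)
    return track.take(np.asarray(kept))


def subsample_stochastic(
    track: Track, fraction: float, n_reps: int, seed: int
) -> list[Track]:
    """Random retention replicates mimicking erratic satellite sampling.

    Each replicate keeps ``floor(fraction * n)`` fixes drawn uniformly
    without replacement, re-sorted by time. Replicates use independent
    substreams derived deterministically from ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(track)
    k = int(np.floor(fraction * n))
    if k < 2:
        raise ValueError(f"fraction {fraction} of {n} points keeps {k} < 2 fixes")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    reps = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = np.sort(rng.choice(n, size=k, replace=False))
        reps.append(track.take(idx))
    return reps


@dataclass
class AgreementReport:
    """Per-state agreement between a subsampled analysis and its reference.

    For each reference state s, ``per_state[s]`` is the fraction of retained
    fixes whose reference state is s that received state s in the subsampled
    analysis (NaN when no retained fix has reference state s);
    ``n_per_state`` gives the denominators. ``overall`` is the matching
    fraction over all retained fixes.
    """

    per_state: dict[str, float]
    n_per_state: dict[str, int]
    overall: float
    n_retained: int
    interval_min: float | None = None
    fraction: float | None = None
    replicate: int | None = None

    def to_row(self) -> dict:
        row = {
            "interval_min": self.interval_min,
            "fraction": self.fraction,
            "replicate": self.replicate,
            "n_retained": self.n_retained,
            "overall": self.overall,
        }
        for s in STATES:
            row[f"agree_{s}"] = self.per_state[s]
            row[f"n_{s}"] = self.n_per_state[s]
        return row


def state_agreement(
    reference: RSTResult,
    sub_result: RSTResult,
    index_map: np.ndarray | None = None,
    **meta,
) -> AgreementReport:
    """Score state matches of a subsampled analysis against the reference.

    ``index_map`` maps each subsampled fix to its index in the reference
    track; it defaults to the subsampled track's recorded ``source_index``.
    """
    if index_map is None:
        index_map = sub_result.track.source_index
    if index_map is None:
        raise ValueError("no index_map given and the subsampled track records none")
    index_map = np.asarray(index_map, dtype=int)
    if index_map.size != sub_result.residual.size:
        raise ValueError("index_map length does not match the subsampled analysis")
    if index_map.min() < 0 or index_map.max() >= reference.residual.size:
        raise ValueError("index_map points outside the reference track")

    ref_states = reference.state[index_map]
    sub_states = sub_result.state
    match = ref_states == sub_states
    per_state: dict[str, float] = {}
    n_per_state: dict[str, int] = {}
    for s in STATES:
        sel = ref_states == s
        n_per_state[s] = int(sel.sum())
        per_state[s] = float(match[sel].mean()) if n_per_state[s] else float("nan")
    return AgreementReport(
        per_state=per_state,
        n_per_state=n_per_state,
        overall=float(match.mean()),
        n_retained=int(index_map.size),
        **meta,
    )


def _dynamic_params(
    track: Track, radius_grid, threshold_Th: float, cutoff: float
) -> tuple[RSTParams, float]:
    """Dynamically scale R for a track, extending the grid upward if needed."""
    scan = select_dynamic_radius(track, radius_grid, threshold_Th, cutoff)
    return RSTParams(dynamic_radius(scan), threshold_Th), scan.selected_numerator


def run_resolution_experiment(
    track: Track,
    intervals_min=DEFAULT_INTERVALS_MIN,
    radius_grid=None,
    threshold_Th: float = 0.0,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Regular-subsampling agreement profile over a set of intervals.

    The reference analysis uses a dynamically scaled R on the full track;
    each subsample is re-scaled dynamically on its own grid (built from its
    own step lengths when ``radius_grid`` is None, mirroring per-interval
    re-scaling). Returns one row per interval with per-state and overall
    agreement.
    """
    ref_params, _ = _dynamic_params(track, radius_grid, threshold_Th, cutoff)
    reference = run_rst(track, ref_params)
    rows = []
    for interval in intervals_min:
        sub = subsample_regular(track, float(interval))
        sub_params, _ = _dynamic_params(sub, radius_grid, threshold_Th, cutoff)
        sub_result = run_rst(sub, sub_params)
        report = state_agreement(reference, sub_result, interval_min=float(interval))
        row = report.to_row()
        row["radius_R"] = sub_params.radius_R
        rows.append(row)
    return pd.DataFrame(rows).drop(columns=["fraction", "replicate"])


def run_stochastic_experiment(
    track: Track,
    seed: int,
    base_interval_min: float = 60.0,
    fraction: float = 1.0 / 3.0,
    n_reps: int = 100,
    radius_grid=None,
    threshold_Th: float = 0.0,
    cutoff: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stochastic-retention agreement replicates on a coarsened base track.

    The base track is first regularly subsampled to ``base_interval_min``
    (mirroring telemetry duty cycles), then each replicate randomly keeps
    ``fraction`` of its fixes and is analysed with its own dynamically
    scaled R. Agreement is scored against the native-interval reference.
    Returns (per-replicate table, per-state summary with mean, SD, median
    and quartiles — box-plot inputs).
    """
    ref_params, _ = _dynamic_params(track, radius_grid, threshold_Th, cutoff)
    reference = run_rst(track, ref_params)
    base = subsample_regular(track, base_interval_min)
    reps = subsample_stochastic(base, fraction, n_reps, seed)
    rows = []
    for r, sub in enumerate(reps):
        sub_params, _ = _dynamic_params(sub, radius_grid, threshold_Th, cutoff)
        report = state_agreement(
            reference, run_rst(sub, sub_params), fraction=fraction, replicate=r
        )
        rows.append(report.to_row())
    per_rep = pd.DataFrame(rows).drop(columns=["interval_min"])
    cols = [f"agree_{s}" for s in STATES] + ["overall"]
    summary = per_rep[cols].agg(["mean", "std", "median", lambda v: v.quantile(0.25), lambda v: v.quantile(0.75)])
    summary.index = ["mean", "sd", "median", "q1", "q3"]
    return per_rep, summary
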