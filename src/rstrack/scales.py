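"""Choosing the analysis radius R.

Two routes are provided.

Static: when the animal's typical transit speed is known a priori,

    R = (mean transit speed x sampling interval) / 2,

with the interval converted to hours so R comes out in km. The average
spacing of transit fixes is roughly speed x interval; halving uncouples two
consecutive fixes, so that at radius R a transiting fix is alone in its
circle.

Dynamic: scan a user-defined ascending grid of radii, compute the fraction
of transit (zero-residual), positive-residual and negative-residual points
at each, and take as the formula's numerator the smallest radius at which
the transit fraction falls below a cutoff (default 5% — fast movements and
data gaps keep it from ever reaching exactly zero). The selected radius is
that numerator divided by two. Both the qualifying radius and the halved
value are exposed on the scan, since users may reasonably want either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ARS, REST, TRANSIT, RSTParams, run_rst
from .geometry import step_lengths
from .track import Track

__all__ = [
    "ScaleScan",
    "ScaleSelectionError",
    "static_radius",
    "default_radius_grid",
    "scan_radii",
    "select_dynamic_radius",
    "dynamic_radius",
]

# Pairwise distance matrices are precomputed for the whole scan below this
# track size (n^2 doubles; 4000 -> ~128 MB).
_PRECOMPUTE_LIMIT = 4000


class ScaleSelectionError(RuntimeError):
    """No radius on the grid brought the transit fraction under the cutoff."""


def static_radius(mean_transit_speed_kmh: float, sampling_interval_min: float) -> float:
    """R in km from a known transit speed (km/hr) and fix interval (min)."""
    if not mean_transit_speed_kmh > 0:
        raise ValueError("mean transit speed must be > 0")
    if not sampling_interval_min > 0:
        raise ValueError("sampling interval must be > 0")
    return mean_transit_speed_kmh * (sampling_interval_min / 60.0) / 2.0


def default_radius_grid(track: Track, n: int = 40, span: tuple[float, float] = (0.25, 8.0)) -> np.ndarray:
    """Log-spaced candidate radii spanning ``span`` times the median step length."""
    steps = step_lengths(track)
    positive = steps[steps > 0]
    if positive.size == 0:
        raise ScaleSelectionError("track has no positive step lengths; cannot build a grid")
    scale = float(np.median(positive))
    return np.geomspace(span[0] * scale, span[1] * scale, n)


@dataclass
class ScaleScan:
    """State-fraction profile over a radius grid plus the selected radius.

    ``fractions`` has one row per radius with columns ``transit``, ``ars``,
    ``rest`` summing to 1. ``isolated`` is the per-radius fraction of fixes
    alone in their circle (RT = RD = 0): the transit fraction net of rare
    coincidental zero residuals, and the quantity that is provably
    non-increasing in R. ``selected_numerator`` is the smallest radius
    whose transit fraction is strictly below ``cutoff`` (None if no radius
    qualifies); ``dynamic_R`` is half of it.
    """

    radii: np.ndarray
    fractions: pd.DataFrame
    isolated: np.ndarray
    cutoff: float
    threshold_Th: float
    selected_numerator: float | None
    dynamic_R: float | None

    def to_frame(self) -> pd.DataFrame:
        df = self.fractions.copy()
        df.insert(0, "radius", self.radii)
        df["pct_transit"] = 100.0 * df.pop("transit")
        df["pct_ars"] = 100.0 * df.pop("ars")
        df["pct_rest"] = 100.0 * df.pop("rest")
        df["pct_isolated"] = 100.0 * self.isolated
        return df

    def plot(self, ax=None):
        """Scale plot: state fractions vs radius, cutoff and selection marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.radii, self.fractions["transit"], color="black", label="transit (residual = 0)")
        ax.plot(self.radii, self.fractions["ars"], color="tab:blue", label="positive residuals")
        ax.plot(self.radii, self.fractions["rest"], color="tab:red", label="negative residuals")
        ax.axhline(self.cutoff, ls="--", color="grey", lw=1)
        if self.dynamic_R is not None:
            ax.axvline(self.dynamic_R, color="lightgrey", lw=3, zorder=0)
        ax.set_xlabel("radius")
        ax.set_ylabel("fraction of points")
        ax.set_xscale("log")
        ax.legend(frameon=False)
        return ax


def scan_radii(
    track: Track,
    radii,
    threshold_Th: float = 0.0,
    cutoff: float = 0.05,
) -> ScaleScan:
    """Run the residence analysis at every radius and profile state fractions."""
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radius grid is empty")
    if np.any(radii <= 0):
        raise ValueError("all radii must be > 0")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radius grid must be strictly ascending")

    dist_fn = None
    n = len(track)
    if 2 <= n <= _PRECOMPUTE_LIMIT:
        metric = track.metric
        d = np.empty((n, n))
        for i in range(n):
            d[i] = metric.distances_to(track.x, track.y, track.x[i], track.y[i])
        dist_fn = lambda i: d[i]  # noqa: E731

    rows = []
    isolated = []
    for r in radii:
        res = run_rst(track, RSTParams(float(r), threshold_Th), _dist_to_focal=dist_fn)
        f = res.state_fractions()
        rows.append((f[TRANSIT], f[ARS], f[REST]))
        isolated.append(res.isolated_fraction())
    fractions = pd.DataFrame(rows, columns=["transit", "ars", "rest"])

    below = np.flatnonzero(fractions["transit"].to_numpy() < cutoff)
    numerator = float(radii[below[0]]) if below.size else None
    return ScaleScan(
        radii=radii,
        fractions=fractions,
        isolated=np.asarray(isolated),
        cutoff=cutoff,
        threshold_Th=threshold_Th,
        selected_numerator=numerator,
        dynamic_R=None if numerator is None else numerator / 2.0,
    )


def select_dynamic_radius(
    track: Track,
    radii=None,
    threshold_Th: float = 0.0,
    cutoff: float = 0.05,
    max_extensions: int = 3,
) -> ScaleScan:
    """Scan, extending the grid upward until the cutoff is crossed.

    The default grid is anchored on the median step length, which tracks
    dominated by slow behavior pull well below the transit scale; rather
    than fail, the grid is extended toward larger radii (up to
    ``max_extensions`` times) until the transit fraction crosses the
    cutoff. Raises :class:`ScaleSelectionError` if it never does.
    """
    grid = np.asarray(radii, dtype=float) if radii is not None else default_radius_grid(track)
    for _ in range(max_extensions + 1):
        scan = scan_radii(track, grid, threshold_Th, cutoff)
        if scan.dynamic_R is not None:
            return scan
        grid = np.concatenate([grid, np.geomspace(grid[-1] * 1.2, grid[-1] * 8.0, 10)])
    raise ScaleSelectionError(
        f"transit fraction never fell below {cutoff:.0%} for {track.animal_id!r} "
        f"even after extending the grid to {grid[-1]:g}"
    )


def dynamic_radius(scan: ScaleScan) -> float:
    """The dynamically scaled radius of a completed scan.

    Raises :class:`ScaleSelectionError` if the transit fraction never fell
    below the cutoff — extend the grid to larger radii and rescan.
    """
    if scan.dynamic_R is None:
        raise ScaleSelectionError(
            f"transit fraction never fell below {scan.cutoff:.0%} on the grid "
            f"[{scan.radii[0]:g}, {scan.radii[-1]:g}]; rescan with larger radii"
        )
    return scan.dynamic_R
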