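"""Independent brute-force oracles used to validate the implementation.

The residence walker here follows the verbal definition literally, point by
point: walk away from the focal fix, keep consecutive in-circle fixes,
accumulate the path travelled since the last in-circle fix while outside,
and keep an excursion only if the trajectory re-enters the circle with that
accumulated path no greater than Th. It shares no run-finding code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def law_of_cosines_km(lon1, lat1, lon2, lat2, radius=6371.0088):
    """Spherical law of cosines great-circle distance (alternative formula)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, c)))


def _walk(dist_to_focal, steps, i, radius, th, direction, n):
    """Literal walker; returns the last included index in ``direction``."""
    last_in = i
    acc = 0.0  # path travelled since last_in
    j = i
    while True:
        nxt = j + direction
        if not (0 <= nxt < n):
            break
        seg = steps[j] if direction > 0 else steps[nxt]
        acc += seg
        j = nxt
        if dist_to_focal[j] <= radius:
            if j == last_in + direction:
                # never left the circle: consecutive in-circle fix
                last_in = j
                acc = 0.0
            elif acc <= th:
                # excursion re-entered with path <= Th: keep it all
                last_in = j
                acc = 0.0
            else:
                break
        elif acc > th:
            # outside with too much path already travelled: no future
            # re-entry can qualify
            break
    return last_in


def brute_force_residence(track, radius, th=0.0):
    """Per-point (RT hours, RD) by the literal walker; O(n^2)."""
    n = len(track)
    metric = track.metric
    steps = np.array(
        [
            metric.distance((track.x[k], track.y[k]), (track.x[k + 1], track.y[k + 1]))
            for k in range(n - 1)
        ]
    )
    rt = np.zeros(n)
    rd = np.zeros(n)
    for i in range(n):
        d = np.array(
            [metric.distance((track.x[k], track.y[k]), (track.x[i], track.y[i])) for k in range(n)]
        )
        lo = _walk(d, steps, i, radius, th, -1, n)
        hi = _walk(d, steps, i, radius, th, +1, n)
        if hi > lo:
            rt[i] = (track.times[hi] - track.times[lo]) / 3600.0
            rd[i] = float(np.sum(steps[lo:hi]))
    return rt, rd


def nearest_grid_subsample(times, interval_min, native_min):
    """Greedy nearest-to-grid index selection, written as a plain loop."""
    kept = [0]
    need = (interval_min - native_min / 2.0) * 60.0
    for j in range(1, len(times)):
        if times[j] - times[kept[-1]] >= need:
            kept.append(j)
    return kept
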