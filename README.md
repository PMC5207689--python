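# rstrack

Residence in Space and Time (RST): point-by-point behavioral-state
classification of animal trajectories.

Movement ecologists routinely need to split a GPS or satellite-telemetry
track into behaviorally coherent segments — travelling, searching,
resting — before any habitat, energetics or distribution analysis.
`rstrack` does this with a single spatially windowed statistic instead of a
state-space model or HMM: it is meant for fast, objective first-pass
exploration of tracking data, from 5-minute GPS fixes to sparse Argos-style
telemetry, for one animal or a whole population.

## The statistic

A circle of constant radius *R* is centred on every fix. Over the maximal
contiguous stretch of track connected to the fix inside that circle, two
quantities are accumulated between consecutive fixes:

* **residence time** RT — summed time intervals (hours),
* **residence distance** RD — summed path lengths (km),

with no partial "tail" segments at the circle boundary; a fix alone in its
circle scores RT = RD = 0. Optionally, an excursion that leaves the circle
and returns after travelling at most *Th* outside is kept (*Th* = 0 by
default). Each sequence is normalised by its own track maximum and the
per-fix residual is

```
residual = RD / max(RD)  −  RT / max(RT)   ∈ [−1, 1]
```

whose sign partitions three states:

| residual | state | movement |
|---|---|---|
| = 0 | transit | low time, low distance in the window |
| > 0 | `ars` | time- & distance-intensive (area-restricted search) |
| < 0 | `rest` | time-intensive (rest, or concentrated feeding at coarse scales) |

*R* can be set from a known transit speed, `R = speed × interval / 2`
(45 km/hr at 5.16-min fixes gives R = 1.935 km), or chosen dynamically per
track: scan a grid of radii and halve the smallest radius at which fewer
than 5% of fixes are transit.

## Worked example

Simulate a labeled three-regime track, pick *R* dynamically, classify, and
score recovery of the true regimes (`examples/01_classify_synthetic_track.py`):

```
$ python examples/01_classify_synthetic_track.py
track: 2500 fixes at 5-min interval
dynamically selected radius R = 2.170 km

confusion (rows = true regime, columns = classified state):
state    ars  rest  transit
true
ars      179     8        0
rest      49  1501        0
transit   18    19      726

       ars recall: 0.957
      rest recall: 0.968
   transit recall: 0.952
```

The dynamic radius (2.17 km) lands near the static formula's value for the
simulated 45 km/hr transit speed (1.875 km), and the residual sign recovers
about 95% of each regime's fixes; errors sit at bout boundaries, where the
window mixes behaviors. The other examples profile the radius scan
(`02`), the loss of state agreement under temporal subsampling (`03`), and
the comparison with speed, straightness and tailed residence time (`04`).

The same analyses run from the shell:

```sh
rstrack rst track.csv --radius dynamic --exclude-center 169.1,-52.6,5
rstrack scan track.csv --radii 0.5,1,2,4,8
rstrack simulate --n-points 2000 --seed 1
rstrack resolution track.csv --stochastic
```

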