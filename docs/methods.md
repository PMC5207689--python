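# Methods

## The residence model

Each fix *i* of an ordered, strictly time-increasing track is scored over
the set of fixes connected to it within a circle of radius *R* centred on
its position. The included set is found by walking forward and backward
from *i*: consecutive fixes within *R* (closed disc — a fix at distance
exactly *R* is inside) extend the run; when the trajectory exits the
circle, the walk continues and accumulates the path length travelled while
outside, and if the trajectory re-enters before that accumulated length
exceeds a threshold *Th*, the whole excursion — outside stretch included —
is kept and the walk goes on, through any number of qualifying excursions;
otherwise the run ends at the last in-circle fix. Residence time RT(i) is
the summed time and residence distance RD(i) the summed path length between
consecutive included fixes. Three accounting choices matter:

* **No tails.** Partial segments between the first/last included fix and
  the circle perimeter are never added (unlike the classical
  Barraquand–Benhamou residence time, which `rstrack.metrics` provides for
  comparison). Consequently a fix alone in its circle scores exactly
  RT = RD = 0.
* **Excursion length by full segments.** The "distance travelled outside"
  of an excursion is the sum of whole segment lengths from the last
  in-circle fix to the next in-circle fix. This avoids circle–segment
  intersection geometry and is consistent at the data's resolution; it
  slightly overstates the outside travel (it includes the in-circle
  portions of the exit and re-entry segments), so a given *Th* is a hair
  stricter than a perimeter-exact accounting would be.
* **Segments are never truncated.** A segment joining two included fixes is
  counted in full even if its straight line would geometrically leave the
  circle in between (straight-line path assumption between fixes).

RT and RD are each normalised by their own track maximum (a sequence whose
maximum is 0 normalises to all zeros), and the residual

    residual(i) = RD(i)/max RD − RT(i)/max RT ∈ [−1, 1]

is classified by exact sign: zero → transit, positive → time-&-distance-
intensive (`ars`), negative → time-intensive (`rest`). No floating-point
tolerance is applied: the transit class is *defined* by the exact zeros
arising from RT = RD = 0. A residual can also be exactly zero by
coincidental cancellation with nonzero residence; such fixes are still
classified transit by the sign rule but flagged (`ambiguous_zero`) for
inspection. This distinction has a structural consequence: the
alone-in-circle fraction is provably non-increasing in *R* (residence
values are monotone in *R* at *Th* = 0), while the raw transit fraction can
fluctuate by the occasional flagged collision and reaches 1 again at
track-spanning radii where every fix shares the same run. The scan
diagnostic therefore reports both; the two differ by exactly the flagged
fraction.

Distances are great-circle (haversine, sphere radius 6371.0088 km) for
longitude/latitude tracks and Euclidean for planar ones; *R* and *Th* are
in the metric's output unit (km). Sub-half-percent ellipsoidal error is
irrelevant at the scales the window operates on, so no geodesic library is
needed. RT is reported in hours. Timestamps are stored as epoch seconds
(UTC); duplicate timestamps are a validation error rather than being
merged, because RT accumulation assumes strictly positive time steps.
Tracks are not split at data gaps: a fix isolated by a gap simply scores
zero residence and classifies transit (an explicit `split_on_gaps` helper
exists for users who prefer segmentation).

## Choosing the radius

With a known transit speed the static formula `R = speed × interval / 2`
(interval converted to hours) makes a transiting fix just uncoupled from
its neighbours: consecutive transit fixes sit about one `speed × interval`
apart, and halving keeps each outside the other's circle. Without a priori
speed, the dynamic route runs the analysis over an ascending radius grid
and profiles the state fractions. The selected radius is half the smallest
grid radius at which the transit fraction is strictly below a cutoff
(default 5%; the fraction rarely reaches zero because of fast movements and
data gaps). Reading the qualifying radius as the formula's *numerator* —
rather than as the radius itself — keeps the dynamic choice consistent with
the static formula on tracks with a known transit speed, and both the
qualifying radius and its half are exposed on the scan for users who prefer
the other reading. No interpolation is done between grid points: grid
resolution is the user's precision control. The default grid is 40
log-spaced radii spanning 0.25–8 times the median step length; because the
median step is pulled toward the slowest behavior, `select_dynamic_radius`
extends the grid upward (up to three times) when the cutoff is never
crossed, and errors only after that.

## Comparison metrics

`metrics.py` computes, over the same *Th* = 0 window: per-fix speed
(trailing difference, km/hr; a centered option exists), path straightness
(net displacement of the run over its cumulative path, in [0, 1]; runs with
zero path length are defined straight and flagged), and residence
time/distance including tails in the classical style. Tails are estimated
by linear space–time interpolation along the first exiting segment: the
perimeter crossing is located by bisection on the distance to the focal
position (60 iterations, tolerance 1e−12 on the segment parameter), and the
inside fraction of the segment contributes that fraction of its duration
and length. Tailed residence time dominates the tail-free RT point-wise by
construction.

## Subsampling experiments

Regular subsampling keeps the first fix and then greedily the earliest fix
at least `interval − native/2` after the last kept one (nearest-to-grid
selection); stochastic subsampling keeps a uniform random fraction of
fixes without replacement, with per-replicate generator substreams spawned
deterministically from one seed. Each subsampled track is re-scaled
dynamically on its own grid and re-analysed, and agreement with the
native-interval reference is scored per reference state over **retained
fixes only** (the subsample is an index subset of the parent, so the
mapping is exact); states are never interpolated back onto dropped fixes.
At the native interval the subsample is the identity and agreement is 1 by
construction. The stochastic experiment first coarsens the track to a
60-min base interval, mirroring telemetry duty cycles, and reports
per-replicate agreement plus mean/SD/median/quartile summaries.

## The synthetic generator

`simulate.py` produces planar correlated random walks switching among
behavior regimes semi-Markov style: bout durations are drawn explicitly
(exponential with a per-regime mean, floored at one sampling step) so that
bout length — the quantity that governs which behaviors survive
subsampling — is directly controllable, and successor regimes are drawn
from a transition matrix. Within a bout each step draws a speed (normal,
truncated at zero) and a heading increment (von Mises; concentration 0 is
uniform turning) and integrates position at the sampling interval.

Defaults describe a pelagic-seabird-like system at 5-min fixes: transit
45 km/hr nearly straight (κ = 30), search 10 km/hr highly tortuous
(κ = 0.5) in 30-min bouts, rest 0.5 km/hr drift in 6-hr bouts. Two
structural choices deserve note. Rest drift is directionally persistent
(κ = 50): a resting animal is carried by current and wind, not performing
a Brownian scribble, and persistence is what keeps the path length a rest
bout lays down inside any one circle bounded — with uniform turning a long
rest bout would accumulate more in-circle path than any search bout and
own both track maxima, collapsing the residual contrast. And the default
transition matrix gives switching a diurnal-like structure (rest enters
and exits via transit 80% of the time), since rest is a nighttime state
rarely adjacent to mid-search; with uniform switching, half of all bout
boundaries would butt search against rest and inflate boundary
misclassification beyond anything the motivating systems show. Both
defaults are overridable per regime.

What the generator does **not** emulate: positional measurement error
(Argos-class jitter), irregular native sampling, revisitation of known
foraging patches, environmental forcing (wind, current, resources), and
central-place trip structure. Passing recovery tests therefore show that
the residual separates kinematically distinct regimes at realistic speeds
and bout lengths — not that it is robust to location error or will match
expert labels on any particular species.

## Problem sizes and numerical checks

The validation suite runs the exhaustive comparison against an independent
brute-force walker (literal walk/excursion enumeration, shared arithmetic
only in the final sums so agreement is bit-exact) on 500 random planar
tracks up to n = 200 with random *R* and *Th*; regime recovery uses 2500
fixes (~8.7 simulated days) and asserts per-regime recall ≥ 0.8; the
subsampling experiment uses 2000 fixes and asserts exact agreement at the
native interval and rest ≥ search agreement at 60- and 120-min intervals.
The per-focal computation is O(n) after an O(n²) distance precomputation
(used below n = 4000; above that distances are computed per focal row), so
a 40-radius scan of a 2500-fix track takes a few seconds.

## Known limitations

* Exact-zero classification means any rescaling that perturbs floats
  (e.g., writing at reduced precision and re-reading) can move a flagged
  coincidental zero across the boundary; the isolated zeros (RT = RD = 0)
  are unaffected.
* The excursion accounting (full-segment outside lengths) makes *Th*
  slightly conservative, and results with *Th* > 0 are not comparable
  against perimeter-exact implementations at the last decimal.
* Dynamic scaling assumes the track contains genuine transit; a track
  recorded entirely within one aggregation never crosses the cutoff and
  the selection errors by design.
* One radius per track: long multi-phase tracks (migration plus residency)
  mix scales, and should be split into phases before analysis rather than
  analysed with a compromise radius.
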