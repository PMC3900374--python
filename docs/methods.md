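# Methods

This note documents the models, estimators and numerical choices behind
`walkleader`, in the order data flows through the package.

## Track preprocessing

Raw fixes arrive as per-individual GPS positions at 5 Hz (CSV in planar
metres or WGS84 degrees; GPX 1.1 with a JSON sidecar naming each track).
Latitude/longitude are projected to local planar metres with an
equirectangular projection about the walk centroid using the WGS84
equatorial radius; over a ~1 km field the projection error is far below
the 1–2 m GPS noise. All tracks are linearly resampled onto one closed-open
0.2 s grid covering the individuals' common time span (an error is raised
if that span is under half the walk). Gaps are filled linearly; gaps longer
than `max_gap` (default 2 s) are still filled but recorded on the walk and
flagged with a warning, so downstream code can mask them — they are never
passed off silently.

Positions are smoothed with a truncated Gaussian kernel (sd 1 s, support
±3 sd, renormalized at the edges). The kernel family and width are the
package's own choice — the source analyses show smoothing only through its
effect on velocities — and both are configurable. Velocities come from
central differences on the smoothed track (one-sided at the ends); headings
are unit velocity vectors, defined only where speed ≥ `v_min` = 0.5 m/s.
Below that threshold the velocity direction is GPS noise, and the speed
distribution itself shows a separate near-zero "not moving" mode that must
not contaminate heading analyses.

## Path characteristics

Per dog and walk the package computes: path length; distance covered
relative to the owner; time-mean distance to the owner and to the other
dogs (mean over dogs first, then over time); return-loop detection; the
far-from-owner time ratio; and the preferred running speed.

*Preferred running speed* is the mode exp(μ₂ − σ₂²) of the higher-location
component of a two-component lognormal mixture fitted by maximum likelihood
to the positive speeds (Gaussian mixture on log speeds). The lower
component captures time spent not moving; if the components collapse
(location separation under half the larger σ, or a component weight under
2 %) a single-lognormal mode is returned with a warning. At least 500
positive-speed samples are required.

*Return detection* works on the dog–owner distance series, smoothed with
the preprocessing kernel: every local maximum with prominence ≥ `p_min`
(5 m) opens a candidate return that ends at the first subsequent time the
distance drops to `d_near` (5 m). Candidates that hit the next maximum
first, or run into the end of the walk, are discarded. Loop length is the
dog's path length over the return segment (peak to proximity), and the
return period is the mean gap between consecutive event *ends*; both
semantics are configurable switches because magnitude conventions differ
between reports of this kind.

*Far-from-owner ratio* counts grid points with distance above a threshold;
the default threshold is the dog's own walk-mean distance (factor f = 1),
a pluggable policy.

## Directional-correlation delay analysis

For an ordered dog pair (i, j), C_ij(t, τ) is the mean of
u_i(s)·u_j(s + τ) over sample pairs whose midpoint s + τ/2 lies within
t ± t_win/2, computed on a τ grid of step 0.2 s spanning ±5 s, at window
centres spaced 1 s apart. The midpoint convention makes the estimator
exactly mirror-antisymmetric: exchanging the pair negates every τ* and
preserves the correlation value bit-for-bit, which the test suite asserts.
A window-lag combination is valid when at least 80 % of its sample-pair
slots have both headings defined; the owner is excluded from pairing by
role, since her direction changes live on a far longer timescale than the
6 s window resolves.

An interaction event is a window whose maximal correlation exceeds
C_min = 0.95 (headings within 18.2° on average). Two guards apply to the
arg-max: plateau ties resolve to the value nearest zero, then to the
negative side (deterministic and conservative against false directed
edges); and windows whose maximiser sits on the ±τ_max boundary are
discarded — there the true optimum likely lies outside the scanned range
(slowly drifting, route-following correlation), and keeping such windows
was observed to pile an artifactual spike onto the edge bins sharp enough
to mimic a stable peak.

Events pooled over walks are binned (bin width = τ grid step), normalized
by the number of walks, and smoothed with a σ = 0.3 s Gaussian evaluated
on a 0.05 s grid. The histogram mode τ*, its full width at half maximum
(outermost half-maximum crossings, so multi-lobed histograms report the
full span), and a bootstrap stability sd are recorded. The bootstrap
resamples events with replacement and records the smoothed-histogram
arg-max; because events enter only through their bin, this is implemented
exactly as multinomial resampling of the bin counts (an explicit
event-resampling implementation cross-checks it in the tests). Reported
pair sds use 1000 resamples.

### Randomization null and pair classification

The null asks how stable a peak looks when walks' event sets are shuffled
across pairs: each of 4000 composite histograms picks, independently for
every walk, a uniformly random *ordered* pair's event set — both
orientations of each pair enter with equal probability, since which member
is listed first is arbitrary labelling and the (j, i) histogram is the
mirror of (i, j) — and sums them. Omitting the orientation draw would tie
the null to the labelling convention, which is unphysical. Each composite
gets a bootstrap peak sd (250 resamples; the null enters only through a
quantile over 4000 sds, so per-composite resolution matters little — the
cutoff moves by ~2 % relative to 1000 resamples).

A pair is *connected* when its own bootstrap sd is at or below the
`null_quantile` quantile of the null sds. The default quantile is the
lower quartile (0.25). The extreme lower tail of this null is not "pure
noise": composites are built from the very event sets under test, and
whenever the random orientations of genuinely coupled pairs happen to line
up, the composite re-creates a stable one-sided peak. In simulations the
pair sds separate into two clusters an order of magnitude apart (~0.03 s
for coupled pairs, 0.5–3.6 s for uncoupled ones) while the null's 5 %
point sits *inside* the lower cluster; the lower quartile falls in the gap
and classifies robustly, and `randomization_null_sds` exposes the full
null so the quantile can be swept — the inferred hierarchy is unchanged
across a wide bracket (the test suite checks quantiles 0.10–0.40).

A connected pair is *directed* when ≥ 97.5 % of its bootstrap arg-maxes
share the sign of the mode (a two-sided 5 % bootstrap sign test), with the
leader on the positive side; otherwise it is *undirected* (evenly
matched). Pairs with fewer than 10 events are unconnected outright. The
*leading ratio* is the probability mass on the leader's side of τ = 0
under a Gaussian least-squares fitted to the smoothed curve within ±1 s of
the mode, clipped to [0.5, 1]; if the fit fails the empirical event-side
fraction is used with a warning. Note that even a point mass at +0.6 s
yields 0.977, not 1: the σ = 0.3 s kernel bleeds mass across zero, a
deliberate property of estimating the ratio from the smoothed curve.

## Leadership network and vicinity cross-check

Directed and undirected edges assemble into a mixed graph. *Leading
tendency* is the number of individuals reachable from a node along
directed edges only (undirected edges are not traversed); *active
connections* counts incident edges of either kind. The vicinity network
connects pairs whose pooled fraction of time within 5 m exceeds the 95 %
quantile of a null obtained by circularly time-shifting one track per walk
by at least 60 s — a shift preserves each track's marginal statistics,
which is the standard null for co-location. Network agreement between
per-pair scores uses the Pearson correlation with the t-transform p-value.

## Small-sample association statistics

Pearson r with the two-tailed p from t = r√((n−2)/(1−r²)) on n−2 degrees
of freedom; Spearman's ρ by mid-ranks with the same transform (documented
as an approximation at n = 5–6 — exact enumeration of the 120 rank
permutations can differ by a few hundredths there, and published values of
this kind are reproduced by the t approximation, not the exact test). The
method gate applies Spearman when a Shapiro–Wilk test rejects normality of
either variable at α = 0.05.

The exhaustive permutation check enumerates all n! pairings (n ≤ 8) of one
variable against the other and reports the fraction of pairings whose
Pearson r is ≥ the observed one; the identity pairing is included, so the
ratio is at least 1/n!. A ratio < 0.025 flags a positive association,
> 0.975 a negative one. With n = 5 the flag can only fire when at most 2
of 120 pairings reach the observed r, so the exact null flag rate is
2/120 ≈ 1.7 %, slightly conservative relative to the nominal 2.5 % — an
unavoidable discreteness of exhaustive tests at this n, which the
calibration test asserts exactly. The all-pairs screen reports raw
p-values alongside Bonferroni and Benjamini–Hochberg adjusted
significance; nothing is silently filtered, and with 25 usable variables
the screen has 300 rows.

## Synthetic walk generator

The generator is first-class, tested code and defines the study conditions
for every simulation-based check. Per walk: the owner traverses smoothed
random waypoints on a 1000 × 500 m field at a constant 1.1 m/s (turn rate
capped at 0.25 rad/s); each dog is a correlated random walk steered
outward from the owner until an excursion radius derived from its loop
period is reached, then back until within 4 m, producing out-and-back
loops; per-step speeds are lognormal about the dog's preferred running
speed (defaults span 1.4–4.0 m/s) with Poisson-scheduled near-stationary
pauses supplying the slow speed mode. Coupling episodes are Poisson per
ordered pair (default 1.5/min, 10 s long), thinned so no individual is in
two episodes at once — a follower's heading would otherwise be
over-determined and the ground truth ill-defined. During an episode the
leader runs a loop at a per-episode constant turn rate and the follower's
heading equals the leader's lagged by the realized delay plus heading
noise (0.15 rad per step by default). With all noise and jitter disabled
the copy is exact sample-by-sample, which a test asserts.

Two episode-level parameters emulate the dynamics of real leader–follower
pairs: `lead_share` (default 0.7) reverses the roles in 30 % of a pair's
episodes, matching the observation that pair leaders lead roughly 57–85 %
of interactions, and `delay_jitter_sd` (default 0.2 s) perturbs each
episode's realized delay, giving delay histograms event-level width rather
than needle peaks. Positions are finally perturbed by isotropic Gaussian
GPS noise (default 1.5 m).

What the generator does **not** emulate: terrain and visibility, scent
and play behaviour, GPS dropouts and autocorrelated (multipath) noise,
position-level attraction between dogs, or drifting individual preferences
across walks. Passing tests therefore demonstrate that the inference chain
recovers heading-copy couplings under realistic sampling, noise, role
reversal and delay scatter — not that it would survive every artefact of
field data.

## Problem sizes and reference conditions

The reference simulated study used by the tests and the acceptance script
is 4 dogs (3 coupled pairs at delays 0.4, 0.8 and 0.4 s; one uncoupled
dog), 14 walks of 600 s at 5 Hz. Fourteen walks matches the field design
and matters for the randomization null — with too few walks the composites
mix poorly — while the 600 s walk length is a deliberate scale-down of the
30–40 min sessions that leaves every pair with well over a thousand
events. Under these conditions the full pipeline recovers all and only the
imposed directed edges with delay-mode errors ≤ 0.2 s in ≥ 90 % of seeded
runs, and the delay mode moves by at most one bin when the window length
is varied between 4 and 8 s.

## Known limitations

* Delays are resolved on the 0.2 s sampling grid; sub-sample delays bias
  the mode toward the nearest grid value.
* Episode-level role reversal pulls the histogram mode slightly toward
  zero (a mixture of two opposite-signed lobes); with the default 70/30
  share and 0.2 s jitter the bias stays within one bin, but stronger
  reversal shifts modes noticeably — the mode then estimates the *net*
  delay asymmetry, not the per-episode delay.
* The Spearman p-value uses the t approximation everywhere, for
  comparability; exact enumeration is available via the permutation ratio.
* The randomization null inherits true structure from coupled pairs by
  construction; its extreme lower tail is therefore not a clean
  false-positive rate, which is why the acceptance cutoff defaults to the
  lower quartile rather than a conventional 5 % point (see above).
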