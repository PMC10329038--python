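# Methods

This note documents the models and procedures implemented in
`hiveburst`, the choices made where the problem left the design open, and
what the synthetic-data tests do and do not establish.

## Input model

The pipeline consumes long-format per-second tracking tables
(`bee_id, t, x, y, nx, ny`): integer seconds since trial start, pixel
coordinates inside a rectangular arena (default 6576 × 4384 px), and a
unit head-direction vector.  Headings are stored as vectors rather than
angles because every behavioral criterion is a dot or cross product.
Rows with out-of-arena positions or heading norms outside [0.99, 1.01]
are rejected and counted; norms inside the band are renormalized.
Missing seconds are treated as absences — the substrate for trip
detection — and are never interpolated.  Duplicate `(bee_id, t)` rows are
an integrity error rather than something to resolve silently: sub-second
dedup belongs upstream in the tracking software.

Trial metadata carries the wall-clock anchor of `t = 0` (needed by the
before-noon orientation-flight rule), the entrance-opening second, glass
cleaning times, and the arena bounds.  No assumption is made about
whether y grows upward or downward; only distances and sign-consistent
angle tests are used.

## Kinetics

Per-bee activity is the squared per-second displacement
`K_i(t) = Δx² + Δy²` (px²/s²), defined only when the bee is detected at
both `t` and `t+1`; hive activity `K_G(t)` is the unweighted mean over
bees with a defined `K_i(t)`.  Averaging over the *detected* set rather
than a fixed roster avoids spurious dips when tags are lost or bees die;
this is the one place where a fixed-denominator reading of the mean would
change results, and the choice is deliberate.

The diurnal cycle is removed by subtracting a centered 12-h (43 200 s)
moving average, truncated at the series edges so the output keeps full
length.  Detrended values can be negative; before burst detection the
series is floored at `1e-6` times its positive mean, because the
inverse-rate conversion below requires strictly positive rates.  The
floor is far below any activity scale of interest and its exact value is
immaterial (it only caps the implied quiet-phase gap length).

## Burst detection

Kleinberg's burst automaton expects a sequence of event gaps; hive
activity is a rate series.  The conversion reads `K_G(t)` as an event
rate — `K = 1` is one event per second, `K = 10` one every 0.1 s — and
attaches one pseudo-event gap `x_t = 1/K(t)` per second.  Attaching gaps
per second (rather than concatenating a realized event train) keeps the
level sequence aligned with the time axis, so burst periods can be read
off directly.  The base rate is `λ̄ = N/T` with `N = Σ K(t)` kept as an
exact (fractional) sum.

The automaton's state `i` emits gaps as Exp(`λ̄ sⁱ`); raising the level
by `d` costs `γ·d·ln n` and lowering is free.  We solve the full
cost-minimizing dynamic program (defaults `s = 2`, `γ = 1`) rather than
the threshold-crossing shortcut sometimes used to describe the algorithm,
because γ has meaning only in the DP.  The level cap defaults to
`ceil(log_s(max λ_t/λ̄)) + 1`, one above the highest emission-optimal
state, so it never binds.  Tests verify DP optimality against full
enumeration (small instances) and an independently coded shortest-path
solution of the same trellis (up to 30 gaps), plus scale invariance and
monotonicity of burst time in γ.

Bursts are maximal runs with level ≥ 1; the burst peak is the maximum of
the series within the period (earliest on ties).  Bursts intersecting
±300 s (configurable) of a recorded glass-cleaning time are flagged
artificial and excluded from downstream statistics.  Inter-burst
intervals are peak-to-peak differences of spontaneous bursts: peaks are
the anchors the pioneer analysis uses, so using them here keeps the two
consistent.

Inter-burst intervals are fitted with the continuous power-law MLE
(`α̂ = 1 + n·[Σ ln(x_i/x_min)]⁻¹`), scanning `x_min` over the unique data
values (capped at 200 quantile-spaced candidates for large samples —
beyond that the KS objective changes negligibly between neighboring
candidates) and minimizing the Kolmogorov–Smirnov distance.  The
goodness-of-fit p-value is a semi-parametric bootstrap (default 1000
replicates): tail values are redrawn from the fitted Pareto, body values
resampled from the data, and each replicate is refitted in full.

## Behavioral event detection

**Waggle dance.**  At 1 Hz, five consecutive samples yield exactly four
heading steps, so "at least four >90° reversals in 5 s" means all four
dot products `n_τ·n_{τ+1}` are negative; turn direction must strictly
alternate, judged by the sign of the scalar cross product.  A zero cross
product (collinear headings) breaks the alternation and rejects the
window — with continuous tracking data this is measure-zero, and
rejecting is the conservative reading.  Overlapping or adjacent dance
windows of one bee merge into a single event; windows containing a
tracking gap are skipped.

**Dance follower.**  Over the seconds of a dance where a candidate is
detected, it must be within 600 px of the dancer (about one bee length in
this imaging geometry) and its heading must be within 90° of the
direction to the dancer.  Detection dropouts do not break a follow
episode but do not count toward its length; episodes of at least 3
tracked seconds become events.  The detector is invariant under rigid
motions of the arena, which the tests check explicitly.

**Trips.**  A trip is a detection gap of at least 60 s whose gap starts
at or after the entrance opened; gaps before that are tracking loss.
The 60-s minimum is the package's own inference threshold (the original
instrumentation could observe the exit tunnel directly; a pure tracking
table cannot distinguish a short dropout from a short exit).  This is the
largest single inference gap in the pipeline and is configurable.

**Orientation flights.**  A bee's first *foraging* day is the first
calendar day with ≥ 6 trips of which > 25 % leave before 12:00 local
time; all trips before that day are orientation flights and never count
as foraging.  An alternative rule — discard the bee's first six trips —
is exposed as an option (`rule="skip-n"`), since both rules circulate in
the literature on automatic forager identification; the day rule is the
default.

**Per-burst roles.**  For each burst with peak `p`: foragers `F_b` are
bees with a non-orientation trip entry in `[p−1000, p−600]`; dancers
`W_b` and followers `DF_b` are bees with a dance/follow event overlapping
`[p−1000, p]`.  The forager window reflects the ~10-min lead of dancing
(and hence of dance-driven returns) over bursts seen in the
information-flow analysis; the dancer/follower window mirrors the
pre-peak half of the NMF analysis window.

## Information flow

Transfer entropy from source Y to target X (history lengths `k = l = 1`
by default) is the plug-in estimate of
`Σ p(x_{t+1}, x_t, y_t) · log₂ [p(x_{t+1}|x_t, y_t) / p(x_{t+1}|x_t)]`.
Real-valued series are first discretized into `q = 3` equiprobable bins
by empirical quantiles, with ties assigned to the lower bin so that
zero-inflated count series keep all zeros in one symbol.  The estimator
is validated against an exact direct-summation oracle on small alphabets
and against analytically solvable processes (a copy process gives 1 bit;
independent series give 0).

The plug-in estimate is biased upward in small samples.  Effective
transfer entropy subtracts the mean TE over 300 full random permutations
of the source series; the permutation distribution also yields an
empirical p-value with the add-one convention (so p is never exactly 0,
and its floor at 300 shuffles is 1/301).  Units are bits throughout;
net-flow *signs*, which carry the scientific conclusions, do not depend
on the log base.  The K/D/O scan computes all six directed flows at bin
widths of 2, 5, 10, 30 and 60 min, skipping widths that leave fewer than
50 bins; group-level flows (e.g. foraged-pioneer vs non-pioneer bees) use
per-group mean kinetic energy binned the same way.

## Pioneer extraction

For each burst, the window matrix `A` (rows: seconds in peak ± 1000 s;
columns: bees; entries: raw `K_i`, 0 where undefined) is factorized as
`A ≅ G·B` with generalized KL divergence and Lee–Seung multiplicative
updates: `G` holds nonnegative basis time courses, `B` bee memberships.
The 1000-s half-width is about half the smallest plausible inter-peak
spacing in week-long trials, so consecutive windows do not swallow each
other's flanks.  Defaults follow standard practice for this estimator:
500 iterations, best of 50 uniform-random restarts, denominators floored
at 1e-12 so empty rows or columns are harmless.  The update rule's
guarantee — the loss never increases — is asserted per iteration in the
test suite, and the final loss is cross-checked against scikit-learn's
independent `mu`-solver implementation.

The rank is selected by Brunet's consensus procedure over r = 2…10:
multiple factorizations per rank, connectivity matrices (bees co-assigned
by dominant membership) averaged into a consensus matrix, cophenetic
correlation between consensus distances and their average-linkage
dendrogram, and the chosen rank is the one preceding the first drop of
the coefficient (argmax if it never drops).  We use 20 runs per rank by
default; the selection is validated by planted-structure recovery, not by
agreement with any external implementation.

Pioneer classification: (1) each bee's dominant basis is the argmax of
its membership column; (2) pioneer bases are those whose time course
peaks strictly *before the burst-period onset* — "before the burst" is
read as before the detected level-≥1 period, not before the peak;
(3) candidate pioneers are bees dominated by a pioneer basis, and when
several bases peak pre-onset their bees are pooled (a flag restricts to
the earliest-peaking basis); (4) a bee is dropped if the maximum of its
reconstructed activity over the window is below the mean of all entries
of `A`.  The amplitude threshold has a second reading (per-bee column
mean), exposed as an option; the matrix-mean default is the stricter,
scale-anchored one.  An empty pioneer set is a valid outcome, recorded
rather than raised.

The per-burst pioneer sets become a binary bees × bursts *pioneer
matrix*, and each burst's roster is partitioned into foraged pioneers
(FP = F_b ∩ P_b), non-foraged pioneers (NFP) and non-pioneers (NP) for
the group information-flow analysis.

## Burst similarity

Bursts are compared by the Jaccard distance between their pioneer sets
(bursts with empty sets are excluded — their distance is undefined) and
embedded in 2-D by non-metric MDS (SMACOF with monotone regression,
Kruskal stress-1), restarting from random initializations until stress
< 0.2 or a restart budget is exhausted; non-converged embeddings are
flagged and excluded from dispersion statistics.  Dispersion of a burst
subset is the mean squared distance to its centroid (the sum of
per-coordinate population variances) — the natural reading of "variance
within the embedding space".

The null model redraws each burst's pioneer set uniformly without
replacement from the roster, preserving its cardinality, and recomputes
distances, a fresh embedding, and the subset dispersion per draw (500
draws by default).  Recomputing the full embedding per draw, rather than
projecting into the observed space, is deliberate: the observed space is
itself a function of the pioneer sets under test.  Early/late burst
subsets split by wall-clock day of the burst peak (first five days vs
last two by default).

Group comparisons use the Brunner–Munzel rank test (statistic,
Satterthwaite degrees of freedom, two-sided t-approximation p, and the
stochastic-superiority estimate `p̂ = P(A<B) + ½P(A=B)`), implemented
directly and cross-checked against both scipy and an exact
full-permutation oracle of the studentized statistic.  The t
approximation is known to be rough below ~10 observations per group; the
implementation refuses samples below 5.

## Synthetic hive generator

The generator exists to give every detector a ground truth.  Agents move
as correlated random walks with half-normal step lengths: quiet agents at
σ = 3 px/s with 0.25 rad/s turning noise, active agents at σ = 40 px/s
and 0.9 rad/s — a ~180-fold kinetic-energy contrast, the driver of
detectable bursts.  A quiet agent activates when at least
`activation_threshold` active agents are within `contact_radius`
(120 px), with probability `p_contact_activation` per second, or
spontaneously at `p_spontaneous`; active agents revert after an
exponential duration.  Positions reflect at the walls; recorded headings
get 0.05 rad of jitter.  Scripted dancers turn by ±(180° − 20° ± 8°)
with alternating sign, in place, which satisfies both dance criteria with
margin even after heading jitter; scripted followers are pinned 150–450
px from their dancer facing it within ±35°; trips are literal removals
from the table with re-insertion at the entrance.  An optional sinusoidal
diurnal modulation of step scales exercises the detrending stage.

Fixture presets use a 1600 × 1100 px arena with 50–100 bees over two
simulated hours: real hives are dense, and contact cascades need
neighbors within reach (≈ 2–3 within 120 px here).  The
`contact_cascade` preset sits in the bistable threshold-2 regime —
ignition needs two coincident spontaneous activations, after which the
cascade saturates and collapses when durations expire — tuned to produce
3–8 bursts per two hours.  `forager_driven` uses the same regime but with
ignition supplied by clusters of scripted forager returns, so
non-forager activity is driven by forager activity with a cascade lag of
tens of seconds; this is the ground truth for the information-flow
direction test.  `pioneer_recovery` plants 20 mass-activation events with
known 20-bee pioneer groups pre-activated 60 s ahead at an intermediate
step scale (σ = 15 px/s: conspicuous against quiet, but below the
burst-detection threshold so the burst onset stays at the mass event).
For these two-hour fixtures the pioneer analysis uses a ±150 s window and
a fixed rank of 4 (background, pioneer lead-in, cascade rise, decay) —
the paper-scale defaults (±1000 s, cophenetic rank selection) are
impractical and meaningless at 340-s event spacing, and rank selection is
validated separately on planted-structure matrices.

What the generator does *not* emulate: comb geometry and crowding,
trophallaxis, thermoregulation, pheromone fields, realistic circadian
structure, tracking noise and identity switches, or any calibrated
correspondence to real hive parameters.  Passing tests therefore show
that the pipeline recovers the structures it claims to recover when they
are present — not that those structures take the same quantitative form
in real colonies.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; every public
  stochastic function takes a seed or generator.  The pipeline spawns
  per-stage substreams from one global seed and writes a manifest with
  input hashes, parameters, and the package version.
* Ties: burst peaks break earliest; discretization assigns
  quantile-boundary values to the lower bin; a zero cross product rejects
  a dance window.
* Degenerate inputs: constant series discretize to a flagged single
  symbol and yield TE = 0; empty pioneer sets propagate as exclusions,
  not errors; singleton subsets have dispersion 0.
* The pipeline skips diurnal detrending when the series is shorter than
  the detrend window (there is no cycle to remove), and clamps
  regardless.

## Known limitations

* Trip inference from absence cannot separate short exits from tracking
  dropouts; the 60-s threshold trades one error for the other.
* The amplitude-filter threshold and the dancer/follower attachment
  window each have plausible alternative readings (options are provided,
  defaults documented above); pioneer sets can shift slightly under the
  alternatives.
* The discretization (q = 3 equiprobable bins) and log base of the
  transfer-entropy stage are conventions; absolute ETE magnitudes depend
  on them, though directions and significance calls are stable in our
  tests.
* Non-metric MDS below stress 0.2 requires genuinely low-dimensional
  pioneer structure; fully random membership matrices are near-simplex in
  Jaccard distance and do not embed — the similarity stage reports
  non-convergence rather than forcing a layout.
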