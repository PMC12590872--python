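# Methods

This note documents what each stage of `locopop` computes, the modeling
assumptions behind the synthetic-data generator, the parameter defaults
and why they were chosen, and the numerical conventions that matter for
reproducing numbers exactly.

## Movement-bout segmentation (`locopop.behavior`)

Velocity is treated as unsigned speed in cm/s, one sample per imaging
frame (signed encoder output is rectified at load time). An **onset** is a
timepoint preceded by a 2 s window in which every sample stays below
0.09 cm/s and followed by a 2 s window in which velocity exceeds
0.35 cm/s at least once; an **offset** is preceded by a 2 s window with an
excursion above 0.30 cm/s and followed by 2 s entirely below 0.09 cm/s.

Many consecutive timepoints can satisfy these window criteria, so
candidates are restricted to threshold transitions: an onset candidate is
the first frame of a run at/above 0.09 cm/s, an offset candidate the
first frame of a run below it. Windows are half-open — pre-window
[t−2 s, t), post-window [t, t+2 s) — with 0-based frames and t =
frame/rate. Candidates whose window would cross a trace end are excluded
(the criteria cannot be evaluated there), and among same-type events
closer than 2 s only the earlier is kept, applied greedily in time order.
Onsets and offsets are detected independently: a bout may contribute one
without the other.

**Motion timepoints** run from each onset up to (exclusive) the earliest
later frame whose centered moving-average velocity over 0.7 s falls below
0.09 cm/s. The window length is forced odd as 2·⌊0.7·rate/2⌋+1 — 17
frames at 25 Hz — and shrinks symmetrically at trace edges. Every emitted
event is additionally covered in the test suite by a slow frame-by-frame
verifier of the printed criteria.

The bout-kinematics statistic resamples each bout's paw X-Y trajectory to
the median bout length (linear interpolation on normalized time),
computes the Pearson correlation per dimension for every bout pair, and
averages over pairs and dimensions; pairs with a constant dimension are
skipped with a warning.

## Ca²⁺ event detection (`locopop.events`)

Traces are standardized per neuron per session to zero mean and unit
population SD (ddof = 0; a constant trace raises and the neuron is
excluded downstream), then smoothed with a centered moving average whose
span is 0.5 s rounded to the nearest odd frame count (13 at 25 Hz), edge
windows shrinking.

The default detector (`mode="gated_peak"`) takes local maxima of the
smoothed trace that (i) exceed the 3 SD activity threshold, (ii) are
separated by at least 0.5 s with prominence ≥ 1.5 SD (one event per
transient), and (iii) have a rise rate above 0.4 SD/s anywhere in the
preceding smoothing span (the derivative is the centered gradient of the
smoothed trace, in SD per second). Event times are then sharpened by two
passes of event-triggered-average re-timing: the ETA of the raw trace
(±1.5 s) is recomputed from the current alignment and each event shifts
(±0.5 s) to maximize correlation with it. The re-timing recovers the
timing information the 0.5 s smoothing removes — the smoothed derivative
alone localizes a transient no better than ±2 frames at realistic SNR,
while the raw GCaMP rise (τ ≈ 0.2 s) is much sharper.

A pure derivative reading (`mode="deriv_peak"`: strict local maxima of
the smoothed derivative above 0.4 SD/s, no amplitude gate) is available.
It is not the default because a derivative estimated over a 0.5 s span of
a unit-SD baseline has σ ≈ 1.9 SD/s, so a 0.4 SD/s threshold alone is
noise-dominated for any realistic noise spectrum at that marginal SD;
against planted transients its precision is below 1%. The amplitude gate
reuses the 3 SD activity threshold rather than introducing a new
parameter.

Detected event times follow a trace-peak convention and therefore trail
the transient start by a fixed, kernel-dependent latency (~0.4 s for
GCaMP6f-like kinetics). Recovery scoring against ground truth
(`locopop.validate`) removes the median per-neuron lag before matching
within the frame tolerance, the usual convention in event-detection
benchmarking.

**Activation typing**: a neuron is onset-active (offset-active) when its
dF/F averaged across all onset (offset) windows of ±2 s — inclusive, 101
lags at 25 Hz, edge events dropped — crosses 3 SD anywhere in the window,
in session-standardized units (the window average is not re-standardized).
The label is the 2×2 combination: *both*, *onset_only*, *offset_only*,
*neither*. Ties at exactly a threshold are inactive: strict `>`
everywhere.

**Positively modulated cells**: the per-neuron instantaneous event rate
is the event delta train smoothed with the same 0.5 s moving average and
z-scored; frames above 2 SD are active timepoints, and a neuron is
positively modulated when active timepoints make up a strictly larger
share of motion than of non-motion frames (an event-free neuron is never
flagged). The rate signal is not further specified by the definition of
the statistic; the boxcar-rate choice is recorded here and exposed in the
parameters.

## Ensemble statistics (`locopop.ensembles`)

Per-bout **activation vectors** mark neurons whose standardized dF/F
exceeds 3 SD at any frame of a 2 s window *centered* on the bout event
(±1 s). This window is deliberately narrower than the ±2 s typing window;
the two are independent parameters. Bout-to-bout activation curves take
the first 8 onsets (or offsets) of a session.

**Similarity** of two ensembles is the Jaccard index divided by its mean
over 1000 shuffles, each shuffle independently permuting each vector's
entries (active counts preserved). A uniform permutation of a binary
vector is exactly a uniform random subset of its active count, which is
how the shuffles are sampled; the resulting overlap is hypergeometric, and
the test suite checks the Monte-Carlo normalization against the exact
hypergeometric expectation by enumeration. Pairs whose union is empty are
skipped; if one vector is empty the normalization is undefined (NaN) and
the pair is excluded from day averages. Within-day summaries average all
unordered same-day pairs of one action type; across-day summaries average
all pairs spanning adjacent days. Similarity analyses assume a neuron set
detected on all 8 days.

**Fate overlap**: a neuron is early-active if active (typing criterion)
on both of days 1 and 2, late-active likewise for days 7 and 8; the
statistic is 100·|late ∩ early|/|late|. The null independently permutes
neuron identities of each daily vector; 1000 shuffles (matching the
similarity statistic; the fate shuffle count is not otherwise pinned
down), one-sided p = fraction of shuffles ≥ observed.

**Action bias**: for the late ensemble (bout-averaged activity over all
bouts of days 7+8 crossing 3 SD), each member is scored +1 if active at
onsets only, −1 at offsets only, 0 at both — activity here averaged over
the first two bouts of each of days 1–3, reusing the typing criterion —
and members inactive at both are omitted. The bias is the mean score;
it is antisymmetric under swapping the onset/offset roles.

**Action separability**: per day, the matrix of onset and offset bouts ×
(neurons × 101-frame 4 s windows, horizontally concatenated) is z-scored
per column, reduced by PCA to 8 components, embedded in 2-D by t-SNE with
the Chebyshev metric (perplexity min(30, (rows−1)/3), PCA initialization,
fixed seed), and scored by the silhouette of the onset/offset labels on
the embedding (Euclidean on the 2-D points). Early/late scores average
days 1+2 and 7+8; per-day-then-average is the default (a pooled mode is a
straightforward variant). Days with fewer than two bouts of either label
are skipped.

## Decoding and efficiency (`locopop.encoding`)

The peri-event design concatenates 4 s windows (centered, inclusive: 101
frames at 25 Hz) around all onsets (or offsets) of a day: rows are
frames in event order, columns are neurons, the target is the velocity at
those frames. Fitting is OLS with intercept, leave-one-bout-out (k =
number of bouts); held-out predictions are pooled into a single R² (more
stable than averaging per-fold R² over 101-frame folds), and adjusted as
1 − (1−R²)(n−1)/(n−p−1) with n the pooled row count and p the predictor
count. When p ≥ n−1 the OLS fold is degenerate and a fixed-penalty ridge
fit is substituted with a flag; the adjusted R² is then undefined and
reported as NaN. Cross-validation folds are computed by downdating the
full normal equations per bout, which is exact OLS.

**N-neuron curves**: the support of size N comes from LASSO on
standardized predictors, tuning the penalty (coarse 60-point path, then
bisection) until exactly N coefficients are nonzero; if the support size
jumps past N along the path, the nearest achievable support is trimmed by
coefficient magnitude or padded by marginal correlation, with a warning.
The selected neurons are then refit by unpenalized OLS on the raw
predictors under the same cross-validation.

**Efficiency**: the N-curve is made monotone by isotonic regression,
linearly interpolated in N, evaluated at the day's active-neuron count
(the number of typing-criterion action-active neurons that day;
plateau-extrapolated beyond the largest N, flagged), and divided by that
count — decodable information per neuron activated. The monotone-fit
choice resolves an otherwise unspecified curve family.

## Synthetic studies (`locopop.synthgen`)

The generator emulates the statistical structure the analysis assumes and
plants complete ground truth. Behavior: ~20 min sessions at 25 Hz;
bouts are velocity trapezoids (0.4 s linear ramps) whose count
(19→22/day) and peak speed (2→6 cm/s across days, constant CV 0.15)
increase with training, durations 5 ± 0.8 s (min 3 s), ≥ 5 s of
quiescence between bouts so every planted bout satisfies the detector's
pre/post windows by construction, plus clipped Gaussian speed noise
(SD 0.02 cm/s).

Population: 160 neurons per animal; fixed onset-only (15%) and
offset-only (15%) memberships; a "both" pool that starts at 40% and,
under `refine=True`, deactivates to 10% by day 8 in a random but
persistent order (deactivated neurons become "neither"); bout-to-bout
reliability rises 0.87→0.93. Transients are difference-of-exponentials
kernels (rise 0.2 s, decay 0.7 s — GCaMP6f kinetics, which the
experimental line expressed; both taus are parameters), amplitude 8 SD of
the unit white-noise baseline — a bright somatic transient — jittered
N(0, 0.15 s), clipped at ±0.5 s so planted membership remains visible to
the ±1 s activation window. Start-related transient amplitudes scale
linearly with the bout's relative peak speed, giving the population a
graded speed code; stop-related amplitudes are speed-independent, since a
stop response fires after velocity has returned to zero and any speed
scaling there would be undecodable bout-to-bout variance rather than
signal. All randomness flows through `SeedSequence(master_seed, animal,
day)` (roles from `SeedSequence(master_seed, animal)`), so identical
configurations are bit-identical.

These defaults are chosen so the generator's documented premise holds:
the planted velocity information is approximately constant across days
while the active population shrinks — which is exactly the configuration
the efficiency score is designed to detect. Under them the analysis
recovers: "both" fraction falling with single-action fractions flat,
within-day similarity rising (both through reliability and because
chance-level Jaccard falls as ensembles shrink), all-neuron decoding
stable (early-vs-late |Δ adjusted R²| ≈ 0.001 onsets / 0.08 offsets over
six animals), and efficiency roughly doubling.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: correlated or non-Gaussian noise
(neuropil, motion artifacts, photobleaching residue), spontaneous
activity unrelated to locomotion (background transient rate defaults to
0 Hz, parameter available), speed-tuned *sustained* activity during
running, cell-type differences (direct vs indirect pathway), imperfect
cross-day identity matching, and any within-bout kinematic structure
beyond the trapezoid. The positively-modulated fraction of the synthetic
population *falls* across days (the deactivating "both" pool outweighs
everything else), which is a property of this planted schedule, not a
claim about real populations.

## Pipeline and inference (`locopop.pipeline`)

`run_pipeline` analyzes every animal-day (generating synthetic sessions
on demand unless recordings are supplied), then summarizes each metric as
an early (days 1+2) vs late (days 7+8) paired contrast across animals:
per-animal means over the named days, a two-sided paired t statistic, and
an exact sign-flip permutation p (exhaustive up to 12 animals, 10 000
random flips beyond). Inference is deliberately limited to these paired
descriptive tests. The materialized configuration and its SHA-256 hash are
embedded in the report; identical (config, seed) reproduce identical
numbers. Per-stage failures (no bouts, empty ensembles, constant targets)
are logged and recorded as NaN/flags without aborting the run.

## Problem sizes

The test suite and `scripts/acceptance.py` run at the study's native
scale — 1200 s sessions, 25 Hz, 160 neurons — with a six-animal,
eight-day study for the directional checks; component benchmarks use 50
velocity traces, 20 event-recovery sessions, 10 typing sessions, ~485
similarity configurations, and 20 decoding seeds. The full suite runs in
about seven minutes on one CPU, the acceptance script in about eight.
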