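# Methods

## The analysis model

Accuracy in a two-alternative response-deadline task is treated as a
function of raw processing time, rPT = RT − gap (integer milliseconds,
derived from the stored RT and gap on every read — never trusted from a
file). The analysis window is the inclusive range [−200, 1000] ms;
practice trials and trials without a response are removed first, and each
removal is counted in a `FilterReport`. Removal order matters only for the
report's bookkeeping (each trial is counted against the first rule that
removes it); the retained set is order-preserving and the filter is
idempotent. Late (post-deadline) responses are retained by default — the
analysis window is defined by rPT, not deadline compliance — with a
`drop_late` switch for stricter conventions.

### Tachometric curves

Trials are pooled across participants: for every integer rPT value with at
least one trial, the binwise accuracy is the fraction correct (so
accuracy × n is always an integer count). A `bin_width` option pools wider
center-labeled bins; it exists for large simulation studies and defaults
to 1 ms. Grid values without data are not imputed — curves are functions
on the observed-bin support.

The binwise accuracies are smoothed by local polynomial regression
(LOESS): at each grid point the ceil(span · n) nearest bins (contiguous in
sorted rPT; distance ties resolved toward smaller rPT) are fit by a
weighted polynomial with tricube weights (1 − (d/d_max)³)³, and the local
prediction is the fitted value at that point. Defaults are span 0.2 and
degree 2, the conventional settings for conditional-accuracy curves; the
span counts bins with data, not milliseconds of range. The fit is
unweighted by bin counts (binwise means enter as equal observations),
with `count_weighted` as an option. The solver builds the normal
equations of all points at once from weighted moments of the centered,
rescaled abscissa; a numba-compiled kernel computes the same moments when
numba is importable (identical results to ~1e-14, an order of magnitude
faster). Rank-deficient windows — possible when the window barely exceeds
the degree and the boundary weight vanishes — fall back to a minimum-norm
least squares solve. Exactness is enforced in the tests by a brute-force
per-point weighted-least-squares oracle and by exact reproduction of
quadratics.

A curve's minimum is the global minimum of the fitted values over grid
points in a search range (default: the full analyzed window, since the
guess regime is part of the curve; the range is configurable because edge
bins with few trials can produce noise dips). Ties break toward the
smallest rPT. Sampling variability of the minimum value is estimated by a
trial-level bootstrap within condition (resample n trials with
replacement, re-pool, re-smooth, re-minimize; SE = SD of replicate minima,
ddof = 1, 1000 replicates by default). Participant-level resampling was
considered and rejected as the default because the headline analysis
pools trials across participants; the trade-off is that the SE reflects
trial noise, not participant heterogeneity.

### Permutation test and d_z

The test statistic is min(congruent curve) − min(incongruent curve), so a
deeper incongruent dip gives positive values. Each of B (default 1000)
replicates permutes the congruency labels uniformly over the pooled trial
set — every trial keeps its rPT and correctness — and recomputes both
curves and minima; a within-participant stratified permutation is
available. The p value uses the add-one convention
p = (1 + #{null ≥ observed}) / (B + 1), one-sided by default because the
prediction (deeper incongruent dip) is directional; two-sided uses
absolute values. The floor is 1/(B+1), reported as "p < .001" at B = 1000.
The effect size d_z is the observed difference divided by the SD (ddof = 1)
of the permutation null. Replicates whose smoothing degenerates are
reshuffled and counted.

The permutation engine precomputes per-bin totals once; a replicate needs
only the congruent-side bincounts, the incongruent side being the
complement. This, plus the moment-based smoother, keeps a B = 1000 test on
~29,000 trials under five seconds.

### Binned repeated-measures analysis

rPT in [0, 1000) is divided into half-open 100-ms bins [a, a + 100)
labeled by centers 50, 150, … (the half-open convention is a choice; only
the center labels are conventional). Per participant × congruency × bin
the mean accuracy is computed, and bins missing any participant ×
condition cell are dropped entirely (complete-bin rule), so the design is
balanced by construction. On the balanced cell-mean array the two-factor
within-subject ANOVA uses the classical sums-of-squares decomposition
(verified to conserve the total SS to 1e−10). Per multi-level effect,
sphericity is tested with Mauchly's W on the orthonormal-contrast
covariance (interaction contrasts are the Kronecker product of the factor
contrasts), using the chi-square approximation with the second-order
correction term — the convention of R's ezANOVA, matched against pingouin
in the tests. Greenhouse–Geisser epsilon multiplies both F degrees of
freedom; the reported p uses the GG correction when Mauchly's p < .05
("conditional" policy), with both uncorrected and corrected p always
available. Generalized eta-squared puts the effect SS over the effect SS
plus every error stratum including subject variance — the standard
definition for fully within-subject designs.

Post-hoc paired t tests (scipy) cover all level pairs; Bonferroni
adjustment is min(1, m·p) with m defaulting to the number of pairs;
Cohen's d for paired designs is t/√n. Published post-hoc tables for the
three tasks serve as arithmetic oracles: recomputed d and adjusted-p
cells agree with the printed ones to one unit in the last printed digit
(the printed inputs are themselves rounded). Display rounding (2 decimals
for t, adjusted p, d) happens only in the CSV export; full precision is
kept internally. The congruency effect is congruent − incongruent
accuracy per participant and bin (positive = conflict cost).

## The synthetic generator

The generator emulates the three task designs at their published scale:
5 sessions × 1188 trials per participant (9 × 132 blocks for the word and
Simon tasks, 3 × 396 for the numerical task), gaps 0, 100, …, 900, 950 ms,
fixation 350/400/500 ms, a 1000-ms deadline, and 132 practice trials.
Within every block the factorial of balancing units × gap × fixation is
crossed exactly and shuffled. For the numerical Stroop task the balancing
unit is the digit pair (12 pairs at numerical distances 1, 2, 5); the four
side/size variants of a pair rotate cyclically across blocks with a
per-cell phase, which makes congruency and larger-digit side exactly
50/50 in every session and every variant exactly 5940/4 per participant —
exact four-way balance within a session is arithmetically impossible at
these trial counts. The Simon color→button mapping defaults to
green→left (a counterbalancing choice, configurable). One master seed
drives everything; each participant's design shuffle and the response
sampling use independent spawned substreams, so adding participants never
perturbs existing ones.

Responses come from a three-source mixture indexed by rPT t:

- w_s(t) = A_s · exp(−(t − μ_s)² / 2σ_s²) — stimulus capture, correct on
  congruent and wrong on incongruent trials;
- w_g(t) = A_g / (1 + exp(−(t − μ_g)/τ_g)) — goal-driven responding with
  accuracy a_goal;
- the remainder guesses at 1/2.

Where w_s + w_g would exceed 1, w_s is clipped to 1 − w_g (the engaged
goal process is not displaced). Defaults — A_s = 0.8, μ_s = 250 ms,
σ_s = 50 ms, A_g = 1, μ_g = 350 ms, τ_g = 40 ms, a_goal = 0.97 — place a
deep below-chance incongruent dip near 250 ms and recovery to ~0.97,
the canonical qualitative pattern; the Gaussian/logistic forms are smooth
parametric stand-ins chosen to make the model likelihood-fittable, since
only the qualitative time course is established. RTs are
deadline-targeting: Normal(900, 90) ms truncated to [1, 1400] and rounded
half-up, independent of the gap — the simplest process consistent with
instructions to respond before the deadline even by guessing. rPT
variation therefore comes from the gap manipulation, as in the task.

What the generator does **not** emulate: participant heterogeneity (all
simulated participants share one parameter set, so between-subject
variance is pure sampling noise and simulated ANOVA F values are far
larger than real ones), feedback-driven RT adaptation across sessions,
lapses, and any RT–accuracy dependence beyond the mixture. Passing tests
therefore demonstrate correctness of the estimators and calibration of
the inference under a known generative process — not that real data will
show effects of any particular size.

Parameter recovery (`fit_behavior_model`) maximizes the binned Bernoulli
likelihood over (rPT, congruency) cells with multi-start L-BFGS-B
(bounded; deterministic given a seed); RT mean and SD are estimated
separately from the sample moments (the default truncation clips
negligible mass, so no truncation correction is applied). At the study
scale (~29,000 trials) μ_s is recovered within a few ms and A_s within a
few hundredths; under a null simulation (A_s = 0) the recovered amplitude
pins to ~0.

## Numerical and design choices

- Inclusive rPT window bounds on both ends; stated ranges without
  inclusivity default to inclusive here.
- Times are integer milliseconds; sub-ms values are rounded half-up at
  ingest.
- The permutation test and bootstrap are bit-reproducible given their
  seeds (`numpy` `SeedSequence`-derived generators throughout).
- Problem sizes in the test suite: the permutation calibration study uses
  one participant × one session with 5-ms pooling and B = 199 over 200
  simulated datasets; the power/dip study uses the full 5 × 5940 scale
  with B = 1000 over 20 seeds. These sizes make the Monte-Carlo studies
  precise enough for their acceptance bands while keeping the suite fast.
- Degenerate inputs fail loudly: empty tables, missing conditions (named
  in the error), windows smaller than the polynomial degree, singular
  contrast covariances, and constant-difference post-hoc pairs (flagged
  `undefined` rather than silently dropped).

## Known limitations

- The rm-ANOVA assumes the complete-bin table is balanced (guaranteed by
  the binning stage); it does not handle missing cells by imputation.
- Only Bonferroni adjustment is built in; Holm/FDR are out of scope.
- The bootstrap SE describes trial-resampling variability of the minimum
  value, not uncertainty in its rPT location.
- Published adjusted-p columns for two of the congruency-effect tables are
  inconsistent with min(1, m·p) (they match the raw p rounded to two
  decimals); this implementation follows min(1, m·p).
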