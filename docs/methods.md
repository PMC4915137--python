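# Methods

`checkdyn` re-implements, as a tested pipeline, the analysis chain of a
primate dual-task "checking" experiment: on every trial an agent either
*Works* (a cued left/right categorization with three difficulty levels) or
*Checks* a seven-step gauge that fills with correct Work trials and pays a
large bonus (7x the per-trial reward) when checked full.  The neural
questions are which single units in midcingulate (MCC) and lateral
prefrontal (LPFC) cortex encode feedback valence, the Check/Work decision,
and the cued side; how those signals look at the population level; and
whether the decision to check is visible in population activity trials in
advance.  The original recordings are not publicly available, so every
stage is exercised end-to-end on a synthetic generator with known ground
truth; what the tests establish is therefore the *correctness and
calibration of the machinery*, not a re-estimate of the biological effect
sizes.

## Task and agent generator (`synth`)

The generator reproduces the task's structure: blocks requiring 14, 21, 29
or 36 correct cued decisions (drawn uniformly), a gauge level
`min(7, 1 + floor(7*k/required))` for `k` gauge-advancing correct trials, a
bonus that persists until collected (a block ends only when the full gauge
is checked), per-difficulty accuracies of 0.70/0.80/0.90, and event
timings following the faster animal's schedule (600 ms cue, 400 ms delay,
800 ms gauge view, 800 ms end-of-trial signal).  The agent's checking
policy is logistic in gauge level, previous-trial outcome and gauge speed;
its defaults (`beta0 = -5.0`, `beta_gauge = 0.55`,
`beta_prev_incorrect = -1.0`, speed offsets 0/0.1/0.2/0.3) were calibrated
once so the agent checks on ~12.5% of trials with checking odds rising
with the gauge and dropping after errors — the behavioral regime the
analyses assume.  Reaction times are log-normal with a difficulty-graded
location and an additive post-error slowing term on the log scale.

Spike trains are gamma-Poisson: each unit has a baseline rate, a
negative-binomial dispersion `theta` (a per-trial gamma multiplier with
shape `theta`; `theta = inf` is Poisson), and additive rate bumps (boxcar
or half-Gaussian) tied to task factors — feedback valence, Check-vs-Work,
cued side, gauge level, and distance to the next check (a ramp over the
last three pre-check trials).  Rates are piecewise constant, so spikes are
drawn exactly (per-segment Poisson counts with uniform placement) rather
than by 1 ms stepping; the count marginals are identical and generation is
two orders of magnitude faster.  Latency defaults differ by area (MCC
earlier for feedback and checking, LPFC earlier for the cued side); these
are *emulation targets*, constants chosen to make the expected asymmetries
present in synthetic sessions, not estimates of anything.  What the
generator deliberately omits: no biophysics, no spike history or
refractoriness, no noise correlations between units (each unit's
multiplier is independent), no eye-movement dynamics beyond fixation
bouts, and no within-session drift.  Passing tests therefore say nothing
about how the methods behave under correlated noise or nonstationarity.

Gaze is generated at 186 Hz: the agent always fixates the lever it is
about to touch; with logistic probability (in gauge and upcoming choice)
it first scans the other lever.  Fixation bouts last 180-400 ms with
0.15 deg isotropic noise.

## Single-unit sliding GLMs (`encoding`)

Spike counts in 200 ms bins stepped by 50 ms are fit per bin with a
Poisson GLM; when residual deviance per degree of freedom exceeds 1.2 a
negative-binomial model (MLE shape) is fit and retained if the
likelihood-ratio test on the shape parameter is significant at 0.05.  Both
thresholds are parameters; 1.2 operationalizes "dispersion close to 1".
Two formulas are used: feedback valence + next decision + gauge (on the
feedback, end-of-trial and next-lever-touch alignments) and cued side +
difficulty + gauge (cue alignment).  Difficulty and gauge enter as linear
covariates; sign conventions are positive = Correct / Check / Right.  The
`next_lever_touch` pseudo-event (the following trial's lever touch) lets
the peri-decision epoch of the next-decision term use the same design rows
as the feedback model.

A unit encodes a factor when the factor's Wald p stays below 0.05 for at
least four consecutive bins (350 ms on the stepped grid) inside a
predefined epoch; preference is the sign of Z at the maximal |Z| within
the significant runs (run-restricted by choice — the whole-epoch
alternative is ambiguous when a unit has significant runs of both signs).
Bins that fail to converge break runs rather than being interpolated.
Epochs default to [0, 1.5] s after feedback onset, [-1.0, 0.5] s around
the (next) lever touch, and [0, 1.5] s after cue onset; all are arguments.
Area proportions are compared with Pearson chi-square without continuity
correction — the variant that reproduces all four published contingency
statistics from their printed counts (49.6, 22.37, 3.65, 3.7), which is
the only exact numerical anchor available without the recordings.

## Group GLMM with OLRE (`glmm`)

The group model is a Poisson mixed model per bin: fixed effects
(Check/Work, gauge, previous performance, optionally scanning), a random
intercept per unit, and an observation-level random effect (OLRE, one
Gaussian intercept per count) absorbing extra-Poisson variance.  No
maintained Python package fits crossed Poisson GLMMs with an
observation-level term and reports a marginal AIC, so the fit is
implemented here with the same strategy as lme4's `glmer`: for candidate
variance components, a sparse Newton solver maximizes the joint penalized
likelihood over fixed and random effects; the Laplace formula integrates
out the random effects; Nelder-Mead maximizes the resulting marginal
likelihood over the (log) variances.  Wald intervals come from the joint
Hessian; `AIC = -2*loglik + 2*(p + #variance terms)` supports the
with/without-OLRE comparison.  The implementation is validated against an
independent `glmer` fit on a fixture (slopes within 5%, both AICs within
1%) and against a pooled Poisson GLM in the degenerate no-heterogeneity
limit (within 1%).  Variance components collapsing below 1e-4 are pinned
and flagged singular, not raised.  Random slopes are available behind a
flag but default off — at desk scale they are rarely identifiable.  Bins
are fit independently (no autocorrelation modeling), and per-bin
significance markers are uncorrected, matching the display convention of
the analyses this mirrors.  For long sessions `group_long_table` can
subsample Work trials (keeping every Check, the rare class) to bound the
problem size.

## Ward clustering (`clustering`)

Units are clustered on three signed features: max |Z| x preference sign
for feedback, Check/Work and cued side, zeros where not significant.
Ward linkage on Euclidean distances; the default cut is the largest gap
between successive merge heights, with a fixed-k override.  Features are
not standardized by default (signed Z values share a scale); a flag
enables z-scoring.  Areas are clustered separately.  Cluster means over
the input features characterize each class, flagging clusters jointly
loaded on negative feedback and Check (mean feedback feature <= -1 and
mean check feature >= +1, i.e. |Z| ~ 1 sided loading) — the phenotype
linking performance monitoring to the decision to check.

## Population decoding (`decoding`)

Pseudotrials: per repetition each neuron contributes counts from its own
randomly sampled trials (without replacement, n = 20 per condition;
Check/Work decoding only uses trials preceded by a correct cued decision).
This is the standard construction for non-simultaneous recordings; it
destroys cross-neuron noise correlations by design.  The readout is ridge
regression on classes coded +/-1 with sign readout: per repetition a
stratified 60/40 split, 5-fold CV on the training partition minimizing
summed squared error over a 20-point log-spaced grid (1e-3..1e3), refit at
the winner, scored on the held-out 40%.  The ridge path is computed in
closed form from one SVD per fold (validated to 1e-8 against the normal
equations and sklearn).  Cross-temporal decoding trains at bin t and
tests at every t' using the same repetition's pseudotrials and split, so
the matrix diagonal matches the plain timecourse up to Monte-Carlo error.

Significance: labels are shuffled within each neuron's trial set before
assembly, the full pipeline re-runs, and
`p = (1 + #{null >= observed}) / (1 + n_perm)` per bin.  The stated
two-tailed counting rule is internally inconsistent for a statistic with a
one-sided alternative; the one-sided add-one rule is used and labeled.
Calibration measured over 300 replicate null experiments at the test's
configuration (10 units, 15 pseudotrials per class, 5 repetitions,
n_perm = 200): rejection rate 0.050 at nominal 0.05.  Area comparisons use
Kruskal-Wallis over the repetition accuracies, Bonferroni-corrected by the
number of bins where at least one area decodes significantly.

Distance-to-check decoding uses inter-trial counts (end-of-trial to +2 s)
of correct-preceded correct trials, decoding distance n, n-1, n-2, n-3
against a reference at distances 5-10, with a Lasso under the same
split/CV protocol (15 trials per class).  Features are standardized on
the training partition so one penalty treats high- and low-rate neurons
alike; the default penalty grid is log-spaced 0.16..3.2 because on
standardized features with +/-1 targets penalties much below ~0.15
saturate the active set at these sample sizes (18 training pseudotrials),
which would make the non-zero census uninterpretable.  A fit that hits
the coordinate-descent iteration cap counts as 50% accuracy, per the
stated convention.  The census marks neurons with non-zero coefficients
in at least 10% of repetitions; pairwise Venn counts compare the
contributing sets across distances.  An RBF-kernel SVM (hyperparameters
by CV accuracy) runs under the identical resampling protocol as a
nonlinearity control.

## Oculomotor stage (`oculomotor`)

Gaze is resampled to 186 Hz; samples that are missing or off-range are
interpolated by a smoothing spline with GCV-selected penalty
(`scipy.interpolate.make_smoothing_spline`; the spline support is thinned
to 400 points — the GCV solve is the only expensive step and the
interpolant is insensitive to this).  Periods with >20% bad samples
exclude the trial.  Fixations are dwell episodes of >=150 ms inside a
window of 2.5 lever sizes around each lever (box window; geometry is
configurable), with episodes on the same lever separated by <=150 ms
merged before thresholding.  Three measures per pre-decision period
(1 s before the end-of-trial signal to the lever touch): scanning (both
levers fixated), the latency of the last fixation *end* relative to the
touch (the stated anchor is ambiguous between start and end; end is used
as "last ... and the lever touch"), and the number of fixations on scan
trials.  The three GLMs are binomial (scan), identity-link Gaussian
(latency) and Poisson (count), each on gauge, distance to check, previous
performance and the upcoming choice.

## Behavioral stage (`behavior`)

The checking model is a binomial GLM on gauge (linear), previous
performance as a three-level factor (COR reference, INC and CHECK
contrasts), speed (categorical, speed-1 reference) and block number.  The
RT model is OLS on log RT with difficulty (categorical), previous
performance and block, reported with type-II ANOVA.  Reward-rate profiles
split each completed block's elapsed time into ten equal deciles; the
no-checking counterfactual divides the same per-decile reward by the
decile duration minus the time consumed by Check trials (a Check trial's
time cost runs from its lever onset to the next trial's lever onset),
which makes the counterfactual exactly equal to the observed rate in
deciles without checks and never smaller elsewhere.  Re-check distance
pairs consecutive checks within a block (gauge seen at the first check vs
trials until the next), stratified into tertiles of trials-performed (the
exact stratification is not pinned down; tertiles are the documented
choice), with both Pearson and Spearman correlations reported because the
original statistic is unspecified.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own reproducibility envelope: sessions of 10-40
blocks, populations of 10-200 units, 20-200 decoder repetitions,
n_perm = 200 and 100 replicate experiments for the permutation
calibration, 30 replicates for the GLMM comparisons.  Random seeds fix
every stochastic path; the same seed reproduces a session bit-exactly.
Degenerate inputs are contracts, not crashes: zero-margin contingency
tables, all-zero spike counts, complete separation in logistic fits,
never-checking policies (a trial cap raises), and singular variance
components all have defined, tested behavior.

## Known limitations

Laplace marginal likelihoods are approximations; with very low counts the
AIC comparison inherits that approximation (the lme4 cross-check bounds
the error at the scales tested).  The NB-vs-Poisson likelihood-ratio test
sits on the boundary of the parameter space and is conservative as used.
Pseudotrial decoding cannot see noise-correlation structure, and the
synthetic generator does not produce any, so decoding results here bound
only the correlation-free regime.  The winner's-curse bias of max-|Z|
summaries is real (selecting the peak bin overstates amplitudes by ~25%
at these scales); the amplitude-recovery checks therefore average
coefficients over the known bump support instead.
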