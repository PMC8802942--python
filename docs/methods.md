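# Methods

## The task and its data model

The package analyzes a four-cycle object search task for nonhuman
primates.  A session is a series of *problems*; in each problem one or
two of four familiar objects are covertly designated targets.  On every
trial all four objects appear at four display locations (a fresh uniform
arrangement per trial) and the animal touches one.  Touching a target
not yet selected in the current cycle is rewarded; a cycle ends once
every target has been selected.  Cycle 1 is the *explore* cycle — the
animal discovers the targets by sampling — and cycles 2–4 are *exploit*
cycles in which the known targets are reselected.  1- and 2-target
problems are blocked; the two 4-object sets alternate between problems.

Trials are classified against the within-cycle history as `T` (correct
target selection), `T_revisit` (target already selected this cycle,
unrewarded; only possible with two targets), `NT_novel` / `NT_revisit`
(nontargets, split by whether the object was already sampled this
cycle), or `no_response`.  Problems in which the animal failed to
respond on six or more trials within a single cycle are excluded as
disengaged; aborted trials (fixation break, early release) count toward
this threshold alongside explicit no-response trials, since both signal
poor task focus.

Analytic chance expectations follow from the permutation structure of a
revisit-free random search: the expected number of trials to find all
targets is the expected maximum target position in a random permutation,
`n_targets * (n_objects + 1) / (n_targets + 1)` — 2.50 trials for one
target among four, 10/3 ≈ 3.33 for two.  A memoryless chooser revisits
with probability `k/4` after `k` distinct objects have been sampled
(0/25/50/75%), and the first sample of a cycle is a target with
probability `n_targets/4`.

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream analysis is validated.

**Behavior.**  The agent plays the task with a small set of
interpretable lapse parameters:

| parameter | default | meaning |
|---|---|---|
| `p_learn_one_shot` | 0.9 | probability the Cycle-1 reward produces learning; otherwise Cycle 2 opens with at least one error before the targets are acquired |
| `p_revisit_lapse` | 0.35 | per-opportunity probability that a sampled object re-enters the Cycle-1 choice pool (imperfect memory); 0 = revisit-free, 1 = memoryless chance behavior |
| `p_exploit_error_by_cycle` | 0.12/0.05/0.03 | probability of a lapse (non-target choice) per exploit cycle, non-increasing |
| `favored_location_bias` | 0.6 | extra mass on one location for the first Cycle-1 choice |
| `p_no_response`, `p_abort` | 0.01 each | failed-trial rates feeding the exclusion rule |

The forgetting-style revisit model makes the revisit rate grow faster
than linearly with the number of objects sampled, which is what real
animals show; the defaults reproduce observed revisit curves only
approximately, by design — the analyses are tested against the
generator's own ground truth, not against any specific animal's
percentages.  Event timestamps are drawn uniformly from the task's
timing ranges (0.8–1.2 s wait before the choice array, 1.2–2.0 s delay
to GO, 0.15–0.8 s reaction time, 0.35–0.45 s touch hold, 0.3 s
feedback), so trial-aligned windows behave as they would on real event
logs.

**Spiking.**  Each cell draws a log-normal baseline rate (median ≈ 6
spikes/s, a typical prefrontal range) and multiplicative log-normal
object and location tuning (SD 0.15) applied while the choice is on
screen.  A configurable fraction of cells carries an explore or exploit
preference *conjunctive with one trial phase*: the state gain (default
×1.8) multiplies the rate only within that cell's phase gate, from
200 ms before choice-array (CH) or feedback (FB) onset to 500 ms after,
matching the sustained pre-onset preferences seen in cross-validated
PSTHs.  Default fractions are 7%/10% explore/exploit at CH and 6%/15%
at FB.  Optional outcome cells multiply their FB rate on correct (or
error) trials.  Spiking is an inhomogeneous Poisson process with
piecewise-constant rate per epoch; an optional log-normal per-trial
rate jitter (off by default) allows super-Poisson variability.

The latent state is **binary**: explore on every Cycle-1 trial, exploit
otherwise — except on failed-learning problems, where the explore state
persists through Cycle-2 error trials and, with probability
`failed_state_persistence` (default 0.5), through the first correct
Cycle-2 trial that follows.  The 0.5 default encodes partial
maintenance: at the moment of the delayed first success the population
is, on average, halfway between states, so failed-learning projections
fall between Cycle 1 and regular Cycle 2 rather than collapsing onto
either.  Graded reward-expectancy signals are deliberately absent by
default, making "no effect of sampling order / prediction error /
discovery type" the true null for the expectancy analyses; a
`graded_expectancy` knob ramps the state gain across Cycle-1 sampling
positions for power analyses of those same tests.  A
`cross_phase_leakage` knob (default 0 = absolute phase conjunction)
lets the state gain act in the non-preferred phase, producing the
phase-general population used as the contrast case for
cross-generalization.

**What the generator does not emulate:** inter-neuron noise
correlations beyond shared condition rates, firing-rate drift and
recording instabilities, spike-sorting artifacts, graded learning
within Cycle 1, and autocorrelated spike-train structure (bursting,
refractoriness).  Passing tests therefore demonstrate that the
analysis machinery is correct and calibrated under Poisson-like,
condition-driven variability — not that any particular biological
result must replicate.

## Analysis pipeline

**Windows.**  All windows are half-open `[start, start + width)` in
seconds relative to CH or FB onset, so adjacent windows partition time.
Selection and statistical tests use the 400 ms window from event onset.
PSTHs use 28 overlapping 100 ms windows with centers from −200 ms to
+475 ms in 25 ms steps.

**Cross-validated selection.**  Each cell's trials are split 50/50 into
selection and validation halves, stratified within cycle × number of
targets × object set × touched location cells (so per-condition counts
differ by at most one trial); the split seed is a required, logged
input.  On the selection half — correct trials of cycles 1 and 4 only —
a factorial ANOVA of the windowed rate on cycle(2) × n_targets(2) ×
object_set(2) × location(4) is run per phase.  Sums of squares are
Type II on a main-effects model: with 32 design cells and realistic
trial counts the full factorial is sparse and unbalanced, interactions
are not of interest, and Type II keeps main effects interpretable under
imbalance.  Cells with a significant cycle main effect (α = 0.05, no
multiple-testing correction — the validation half is the guard against
selection bias) are labeled explore (Cycle 1 > Cycle 4) or exploit
(reverse).  Validation-half PSTHs and across-cell t-tests confirm the
preference on unseen trials; both two-tailed and direction-consistent
one-tailed p-values are reported since the original convention is
ambiguous.  Degenerate fits (zero-variance response, saturated design,
single-level factors) return p = 1 for the affected terms rather than
raising, so silent cells can never be selected.

**Normalization.**  Each cell's normalization constant is the
unweighted mean over the selection-ANOVA condition cells of both 400 ms
windows (CH and FB combined).  Cells below 0.1 spikes/s are excluded
from normalized group averages: the ratio estimate is unstable and a
near-silent cell would otherwise dominate a group PSTH.  Unweighted
condition means skip empty cells and average the available ones, with
per-cell coverage retained.

**One-shot and expectancy analyses.**  Conducted on 1-target problems
within each labeled group, in the group's own phase window, using
normalized activity; cell is the unit of analysis throughout
(across-cell paired t and repeated-measures F).  Cycles 1 and 4 use
validation-half trials only; cycles 2–3 use all trials; cycles 2–4 are
restricted to *regular* cycles (first response correct).
Failed-learning trials are correct Cycle-2 trials preceded by at least
one Cycle-2 error.  The sampling-order, correct/error and
discovery-type analyses follow the same conditioning (favored-location
selections where location would otherwise confound; revisits excluded;
correct/error means averaged unweighted over serial positions 1–3,
position 4 having no possible error).  Repeated-measures F falls back
to the uncorrected within-subject F when the sphericity estimate
degenerates at very small cell counts.

**Temporal cross-generalization.**  A fresh random halving (independent
of the selection split) yields per-cell cycle-preference vectors
(Cycle 4 − Cycle 1 mean rate, unweighted over location × n_targets) in
four 100 ms windows per phase; the 8×8 matrix of Pearson correlations
between half-A and half-B vectors (pairwise-complete over cells) tests
stability of the code within and across phases.  Spearman is available
as an option.  The summary statistic is the mean within-phase minus
mean cross-phase correlation.

**Population discriminant.**  Per phase, cycle-1/4 trials are freshly
split into train and test halves.  Per cell: center = unweighted mean
of the two train cycle means; scale = unweighted mean of the two
across-trial SDs; the discriminant is the scaled Cycle-4 vector minus
the scaled Cycle-1 vector in the full cell-dimensional space.  Cells
with zero or undefined scale get scale 1 and weight 0 (they carry no
information about the axis).  Conditions — C1/C4 test halves, regular
C2 and C3 (all such trials), and failed-learning C2 — are projected as
the dot product of their standardized per-cell mean vector with the
discriminant; cells missing from a condition contribute 0, with
coverage reported.  Permutation inference pools each cell's trials from
the two compared conditions, reshuffles labels, recomputes means and
re-projects on the frozen transform (center, scale and weights are
never refitted); p = (k + 1)/(N + 1) with N = 1000 by default, so the
attainable floor is 1/(N + 1) and p is never zero.

## Problem sizes and calibration design

The bundled experiments validate the stack at sizes chosen to give
clear statistical answers quickly on a single core:

- Search-expectation checks use 20,000 (1-target) and 12,000 (2-target)
  optimal-agent problems; revisit and first-choice checks use
  1,500–3,000 problems — Monte-Carlo standard errors well below the
  effects being measured.
- Selection calibration uses 1,000 null cells (2,000 cell × phase
  tests) over a 30-problem session, simulated in chunks of 125 cells to
  bound memory.  The validation-side calibration uses per-cell
  two-sample t-tests on the validation half of the (falsely) selected
  cells: with honest cross-validation this rejects at the nominal rate,
  whereas reusing selection data would inflate it several-fold.
- Recovery uses two 100-problem sessions and 120 cells at the default
  gain — comfortably above 40 correct cycle-1/4 trials per cell in the
  selection half.
- The one-shot experiment uses the *binary-switch* agent (one-shot
  failures at rate 0.25, zero exploit lapses) so that every behavioral
  failed-learning trial reflects a genuine explore-state carry-over;
  with lapses enabled, lapse-induced "failed" trials dilute the
  carry-over signal toward regular Cycle 2 (the realistic default).
- Null-hypothesis checks on families of four tests (Cycles 2–4
  flatness; C2/C3 vs C4 projections) assert at most one incidental
  rejection at α = 0.05 rather than demanding every p exceed 0.05: the
  individual p-values are uniform by construction, so the strict form
  would fail one run in five by design.
- Permutation calibration re-splits one dataset's Cycle-4 test trials
  into exchangeable pseudo-conditions 500 times (199 permutations per
  run), rather than regenerating 500 datasets.

## Known limitations

- The OLS F-test is applied to Poisson-distributed window rates; the
  mild mean-variance coupling leaves the cycle test within ~1% of the
  nominal 5% level at these rates and trial counts (measured by the
  null calibration), but very low-rate cells in short windows would be
  better served by a GLM.
- Unweighted condition means become noisy when many condition cells are
  empty (few trials per cell); coverage is reported but no shrinkage is
  applied.
- The behavioral agent's lapse structure is deliberately simple
  (stationary probabilities, no fatigue or within-session learning
  trends).
- Repeated-measures tests use complete cases across conditions; cells
  missing a condition drop out of the F rather than being imputed.
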