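# Methods

`sackcog` re-implements, as a tested pipeline, the computational core of a
placebo-controlled crossover study of stimulant "smart drugs" on human
knapsack-problem solving: instance-difficulty algorithms, behavioral
trajectory scoring, a synthetic cohort generator, and the statistical
analyses (mixed-effects model selection, ECDF dominance, random-effect
shrinkage tests). This note records the models, the defaults and why, the
numerical choices, and the limits of what the synthetic cohorts can show.

## The task and its difficulty metrics

A 0-1 knapsack instance is a set of `n` items with integer values `v_i` and
weights `w_i` plus a capacity `c`; the task is to select a subset maximizing
total value subject to total weight ≤ `c`. Values and weights are integers
throughout so optimality checks are exact.

**Greedy.** Items are scanned in decreasing value/weight ratio and added
whenever they still fit; scanning continues past items that do not fit (the
*skip* variant). This reading matters: under the stop-at-first-misfit
variant Sahni-k values change. Ratio ties are broken toward higher value,
then lower weight, then lower index, so the algorithm is deterministic.

**Sahni-k.** The smallest `k` such that some feasible set of exactly `k`
items, fixed in the knapsack and completed by greedy, attains the optimal
*value* (not necessarily the optimal set — instances may have several
optima). `k = 0` means pure greedy is optimal. Prefix sizes are tried in
increasing order with lexicographic enumeration inside each size, so the
returned `k` is minimal; success at size `j < k` would already have
returned. Because adding any item to an optimal set would exceed the
optimum, the full optimal set is always a succeeding prefix, giving the
invariant `sahni_k ≤ |optimal set|`.

**DP complexity.** The published difficulty index derived from the dynamic
program is defined in external work we do not reproduce; the variant
implemented here counts the non-dominated reachable (weight, value) states
summed across item stages of the DP, with dominance pruning (a state is
dropped when a lighter-or-equal state has at least its value). It is
deterministic, merges duplicate items (so duplication lowers the count),
and is monotone under item addition. It is **not** claimed to equal the
published per-instance values (109, 100, …), which depend on the original
formula and instances; those published values ship as a metadata fixture
and are never recomputed. MiniZinc propagation counts are likewise external
metadata only.

**Exact solvers.** `solve_bruteforce` (n ≤ 20) enumerates all subsets and
is the oracle; `solve_dp` is the classic value-table recursion with an
earliest-index backtrace that reproduces the oracle's deterministic
tie-break (the lexicographically smallest optimal index set — with strictly
positive values no optimal set can contain another, so greedy
earliest-inclusion is equivalent), plus a counting recursion for the number
of distinct optima.

## Behavioral scoring

An attempt log is a capacity-respecting sequence of timestamped add/remove
events plus a submission time (censored at the 4-minute task limit; the
interface blocks selections that would exceed capacity, so a violating log
is rejected as corrupt rather than scored). Outcomes per attempt:
correctness (submitted value equals the optimum, exact in integers), value
fraction, time to submission, number of moves, seconds per move,
productivity, the overlap of the first *full* knapsack with the optimal
set, and the greedy–optimal overlap.

Two definitional choices are worth flagging:

* **Productivity** is the *net* value gained per move — value fraction
  divided by the number of moves — not the mean of signed per-move
  increments. Attempts start from an empty selection, so the two readings
  differ only by path cancellations; the net reading is used consistently.
  The stored productivity is bit-exact `value_fraction / n_moves`;
  per-move fields are absent (not zero) for zero-move attempts.
* **Full** is objective: a state is full when no unselected item fits the
  remaining capacity. The first-full overlap is undefined (absent) when an
  attempt is submitted before any full state is reached.

## The synthetic cohort generator

No raw trial data are packaged, so every downstream stage is exercised on
simulated cohorts from an explicitly assumption-bearing agent model. The
agent is a softmax-on-ratio local searcher: while some item fits it adds
item `i` with probability ∝ `exp((v_i/w_i)/T)`; at a full knapsack it
starts another improvement episode (removing an item with probability ∝
`exp(−(v_i/w_i)/T)`) with probability `1 − 1/persistence`, else submits.
As `T → 0` with persistence 1 the agent reproduces the greedy trajectory
exactly — pinned to the observation that human first knapsacks resemble the
greedy solution. Inter-event gaps are exponential with rate `move_rate`;
attempts are censored at 240 s.

Participant ability enters as a log-scale offset: it lowers the effective
temperature (`T·e^{−a}`) and the number of wasted improvement episodes
(`1 + (persistence−1)·e^{−a}`). Condition effects are multipliers on
temperature, persistence, and move rate, with placebo fixed at 1. The
temperature multiplier additionally *damps the ability offset by the same
factor*: injected randomness dilutes the influence of individual strategy
quality. This is the mechanism by which participant-level productivity
heterogeneity shrinks under the active conditions, as the trial reported.

Defaults (chosen once to emulate the trial's reported conditions, then
frozen): base temperature 0.10 (ratio units), persistence 4 episodes, move
rate 0.3 moves/s, ability SD 1.0; multipliers for MPH/DEX/MOD of 1.8/1.8/1.4
(temperature), 2.0/1.9/1.35 (persistence), 1.10/1.10/1.05 (move rate).
Under these defaults a 40-participant placebo arm solves ≈50% of attempts,
spends ≈54 s and ≈15 moves per attempt at ≈3.7 s/move with ≈2% of attempts
hitting the time limit, and the active conditions add tens of seconds and
several moves while productivity and first-full-knapsack quality drop —
the magnitudes the trial reported. Cohorts follow a balanced 4×4 Latin
square (Williams design) with participants randomized to rows; each
attempt draws from an independent named random sub-stream, so generation
is reproducible and order-independent. Session/period effects are omitted
(the trial reported none).

What the generator does *not* emulate: learning or fatigue across sessions
or repeated attempts, within-attempt strategy switches, memory for
previously tried solutions, item-position/interface effects, and any
pharmacokinetics. Its difficulty gradient is also much steeper than the
human one: it solves Sahni-k = 0 instances almost always and Sahni-k ≥ 3
instances almost never, so on a bank matched to the published battery's
difficulty profile (`generate_matched_bank`) its placebo solve rate
(~20%) sits well below the trial's ~50%, whereas on the default
mixed-difficulty banks it is near 50%. It likewise overstates the drug
effect on the probability of an exactly correct solution relative to the
trial (which found no significant correctness effect). Passing recovery
tests therefore show that the pipeline detects the injected signature, not
that the agent is a faithful model of human solvers.

## Statistical machinery

**Mixed models.** `MixedModel(spec, table).fit()` returns a results object
with ML estimates, Wald z-tests, ML log-likelihood, and AIC/BIC that are
recomputable as `−2ℓ + 2k` and `−2ℓ + k·log(nobs)` with `k` counting fixed
effects, random-effect (co)variances, and (for Gaussian models) the
residual variance. Binary correctness uses logistic models; all other
outcomes Gaussian. Gaussian mixed models are fitted by statsmodels MixedLM
with ML (REML is never used where models are compared). Frequentist ML
logistic mixed models are implemented in-package: scalar random intercepts
by adaptive Gauss–Hermite quadrature (21 nodes, recentred and rescaled at
each group's conditional mode), vector-valued per-condition intercepts with
unstructured covariance (Cholesky-parameterised, log diagonal) by Laplace
approximation — the standard choice when tensor-product quadrature is
impractical. The test-suite cross-checks both against lme4's `glmer`.
Random-effect predictions are empirical-Bayes conditional modes.
Random-effect correlations carry Fisher-transform z-tests with
`n = number of participants`; fixed effects carry Wald z-tests, with no
multiple-testing correction (mirroring the original analysis; a Bonferroni
adjustment can be applied downstream).

**Model selection** fits a ladder of candidates — nested difficulty fixed
effects × pooled-drug vs per-drug coding × random structure (none /
participant intercept / per-condition intercepts with unstructured
correlation) — on a single harmonised row set (listwise deletion over the
union of required columns), returns the minimal-AIC or -BIC fit, breaks
ties toward fewer parameters, marks failed or non-finite fits and selects
over the survivors.

**ECDF bands** use Greenwood's variance estimator, which with fully
observed attempt-level outcomes reduces to the binomial form `F(1−F)/n`;
bounds are normal-approximation, clipped to [0, 1]. The dominance check
evaluates two bands on their merged grid and reports the fraction of grid
points where one band's upper bound lies strictly below the other's lower
bound, and the majority direction.

**Squared-effect exchangeability.** The Wilcoxon signed-rank test is
applied to differences of *squared* per-participant random effects; the
exact null distribution is used up to 25 non-zero untied pairs, the normal
approximation with continuity correction beyond. Identically zero
differences are a degeneracy error, not a p-value of 1.

**Difficulty correlations** are Pearson over instances with Fisher-scale
standard error `1/sqrt(n−3)`. On the packaged eight-instance metadata this
reproduces the published correlation matrix (0.08 / 0.20 / 0.52) exactly at
two decimals; note the published table quotes SE = 0.20 while `1/sqrt(8−3)
≈ 0.45`, so only the correlations — not the SE — are pinned.

## Numerical and design notes

* Capacity of generated instances is `round-half-up(fraction × total
  weight)` for bit-reproducibility; generation retries a bounded number of
  times when no item fits, then errors.
* Generated value/weight distributions (uniform integers 1–100, capacity
  fraction 0.5) are the package's own choice; the trial does not state its
  instance distributions, and its actual eight instances are represented
  only by their difficulty metadata.
* The softmax uses a max-subtracted exponent; the zero-temperature limit is
  made deterministic by infinitesimal value/weight/index tie-break terms
  matching the greedy order.
* `productivity × n_moves` re-multiplies a division, so it can differ from
  `value_fraction` by one IEEE ulp; the stored field satisfies the defining
  division bit-exactly.
* Whether both attempts per instance, or only first attempts, enter the
  models is exposed as a pipeline flag (`attempts: both|first`); the
  default is both.
* Pipeline stages communicate only via CSV/JSON files; the run manifest
  (config echo, seeds, output hashes, library versions, no timestamps)
  makes a re-run byte-identical under the same seed.

## Scaled-down replication sizes

The statistical calibration and recovery checks run at deliberately modest
sizes chosen as this package's standard desk-scale configuration: null
calibration on 200 cohorts of 12 participants × 4 instances; effect
recovery on 100 cohorts of 20 participants × 8 instances. At these sizes
the pooled-drug Wald test attains its nominal 5% size within binomial
bounds and the injected drug signature (time ↑, moves ↑, productivity ↓,
first-full quality ↓, shrunken per-condition random-effect ranges) is
recovered with correct signs in ≥90% of replicates.

## Known limitations

* The headline participant-level numbers of the original study (e.g. the
  50.3% solve rate's model slopes, the −0.43/−0.55/−0.21 cross-condition
  correlations) depend on the unreleased raw trial data and are not
  reproduced here; only the instance-metadata correlations are exact
  targets.
* The DP-complexity variant is a documented reinterpretation (see above).
* The reversal phenomenon (negative PLC–drug random-effect correlation) is
  *measurable* by `effect_reversal_analysis` and recovered from data
  simulated with injected cross-condition correlations, but the default
  agent mechanism produces shrinkage without systematic reversal.
* Laplace-approximate likelihoods for vector-valued logistic random
  effects are slightly biased at small cluster sizes, as is standard.
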