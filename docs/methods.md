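# Methods

## Data-generating model

Each replicate simulates a platform trial as 100 recruitment blocks (days).
Within a block of size 80 (two-arm) or 120 (four-arm), each patient's
respiratory-support subgroup is an independent categorical draw with
probabilities (0.24, 0.60, 0.16); block composition is therefore stochastic
(the expected composition, 24/60/16% of 80, is not integral, so fixed
counts would be ill-defined). Arm assignment within a block realizes the
current allocation probability vector as a binomial (two arms) or
multinomial (four arms) draw, which reproduces the aggregate behaviour of
per-patient randomisation while avoiding rounding artifacts. The 28-day
death indicator for subgroup `k` on arm `l` is Bernoulli with the
RECOVERY-observed probability `P[k, l]`; the engine draws the binomial
death count per (subgroup, arm) cell, which is distributionally identical
to per-patient draws. Outcomes are generated at allocation time but only
*revealed* to the adaptation machinery with the outcome lag; since nothing
observes an outcome between those two times, the distinction is
unobservable.

Within-block patient order is reconstructed on demand by a deterministic
seeded shuffle. It matters only for metrics taken at a cut strictly inside
a block; all standard cuts (80% of the trial, block-end trajectories) fall
on block boundaries.

## Adaptation timing

The first 34 blocks (2720 patients, 42.5% of the 6400-patient
RECOVERY-scale axis) are a burn-in at the fixed ratio (1:1 in the two-arm
trial; 0.4/0.2/0.2/0.2 in the four-arm trial, keeping the protected 40%
control share that the four-arm design states unconditionally). From block
35 the allocation vector is refreshed every 7 blocks using only outcomes
from blocks `1..j − 28`, and held piecewise-constant in between. The
schedule is validated so the first adaptation always has a non-empty
observed window. Subgroup-scope policies run one independent adaptive
allocation per subgroup, each burning in at 1:1 and adapting on its own
subgroup's window.

## Posterior probability of best

Arms get independent Beta(1, 1) priors on mortality, updated to
Beta(deaths + 1, survivors + 1) by the lagged window's counts; "best" is
the lowest true mortality. With two arms,
`θ(1) = P(rate₁ < rate₀)` is computed by adaptive quadrature of
`F₁(F₀⁻¹(t))` on [0, 1] (absolute accuracy ~1e-10; the substitution keeps
the integrand smooth even for near-degenerate posteriors), so two-arm θ is
deterministic given the data. With four arms θ is a 10,000-draw Monte-Carlo
estimate (SE ≤ 0.005) from a dedicated RNG stream; θ compares all four
arms, control included, even though the control allocation is fixed —
"optimal" is defined against every treatment, and the allocation formulas
then consume only the experimental entries. A uniform prior is the
conventional non-informative choice for this construction; a different
prior (e.g. Jeffreys) would shift absolute adaptive trajectories slightly
but not the qualitative comparisons.

## Allocation rules and clipping

The tuning rule sharpens θ by the completed-trial fraction `s = j/J`
(flat at s = 0, fully greedy at s = 1); the REMAP-CAP rule weights
`√(θ_l/(n_l + 1))` with `n_l` the arm's patient count in the same lagged
window the posterior uses, so a well-sampled arm's allocation is
self-limiting. Two-arm probabilities are clipped to [0.1, 0.9]. Four-arm
experimental vectors are normalized to the 0.6 budget, then floored at
0.05 with the total deficit taken from the single largest arm (ties broken
toward the lowest index — deterministic and testable); the sum is preserved
exactly, and with these constants the maximum arm can never itself be
pushed below the floor (the degenerate case raises an error). The budget,
control share, clip bounds and floor are policy parameters defaulting to
the study's constants.

## Metrics

All metrics are computed post hoc from the recorded history, over the first
`n_cut` patients (default the 80% cut: 6400 / 9600 patients, matching the
sample size at which RECOVERY's dexamethasone arm reported). Every
generated outcome counts: the outcome lag constrains adaptation, not metric
computation, so deaths are full-cohort fractions.

Hypothesis tests fit a binomial log-odds model of death on an indicator of
the tested arm vs standard care (other arms excluded). With a single binary
covariate the ML fit is closed-form — coefficient = sample log odds ratio,
Wald variance = Σ 1/cell — and this is what is implemented (cross-checked
against an iteratively-fitted GLM in the tests). Under separation (a zero
cell) the Wald statistic degenerates and the pooled two-proportion score
test is used instead, flagged in the result. Two-arm tests run at 5%
two-sided; four-arm tests at 0.05/3 (Bonferroni over the three
experimental comparisons), with the familywise error being any rejection
under the null scenario. Subgroup-level power is reported for subgroups ii
and iii only (in subgroup i the treatment is truly worse than control, so
"power" is not meaningful there).

Bias and MSE use raw cell proportions (deaths/patients among the first
`n_cut`), not model coefficients, as the risk-difference estimate
`P̂[k,0] − P̂[k,l]`; relative bias divides by the true difference and is
therefore undefined (and omitted) in the null scenario. Neyman's
power-optimal split `√(p₀q₀)/(√(p₀q₀)+√(p₁q₁))` on the mix-weighted cohort
rates evaluates to 0.5097 — the 51/49 split that makes 1:1 allocation
near-optimal for power.

## Randomness and reproducibility

Each replicate derives four named RNG streams (subgroups, allocation,
outcomes, posterior) from its seed via hashed SeedSequence entropy, so
components are independently reproducible and changing posterior draw
counts does not perturb outcomes. Replicate seeds are hashed from
(base seed, index): replicate *i* is invariant to batch size and execution
order. Experiment suites reuse one base seed across policies, making
between-policy death differences paired (common random numbers), which is
how "deaths prevented vs FuR" is reported.

## Problem sizes

Replicate batches default to 1000, the study's replication level; at that
size the Monte-Carlo SE on mean deaths is ~1 and on a rejection rate ~0.7
percentage points. A full two-arm six-policy suite plus null runs completes
in a few minutes on one CPU; the test suite shares batches across checks
through a memoizing fixture.

## What the generator does and does not emulate

It reproduces the trial's block structure, subgroup mix, mortality rates,
burn-in/lag/cadence timing and allocation rules. It does **not** model
patient drift (time-varying case mix or care quality), arm dropping or
addition, time-varying recruitment, censoring or partial follow-up — all
deliberate simplifications, so conclusions about RAR's benefit transfer to
a real platform trial only insofar as those forces are secondary. In
particular, under RAR with real patient drift, arm comparisons would be
partially confounded in ways this simulator cannot exhibit.

## Known limitations

- The posterior construction is the standard beta-binomial
  probability-of-best model; absolute adaptive trajectories depend mildly
  on that choice, which is why allocation-share checks carry wider
  tolerances than mortality checks.
- Reported fixed-randomisation power at the 80% cut (~73% for two-arm FeR)
  sits at the asymptotic two-proportion value; some published figures for
  the same design are lower (67.7%), consistent with a power analysis
  restricted to lag-matured outcomes. Mortality *differences* between
  policies are the robust quantities and are what the acceptance script
  reports for the four-arm trial.
- The four-arm burn-in split (0.4/0.2/0.2/0.2 rather than 0.25 each)
  follows the unconditional 40% control protection; the alternative only
  affects the first 34 blocks under fixed-equal comparators.
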