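# rartrial

Simulation of **response-adaptive randomisation (RAR)** in multi-arm
mortality trials, calibrated to the RECOVERY COVID-19 trial (standard care,
dexamethasone, hydroxychloroquine, lopinavir-ritonavir, March-June 2020).
The package asks the design question: *had RECOVERY allocated patients
adaptively instead of with fixed 2:1 randomisation, how many trial deaths
would have been avoided, and at what cost in statistical power, bias and
error control?*

It is aimed at trial statisticians and methodologists who want a tested,
configurable engine for comparing allocation rules on realistic operating
characteristics, rather than a one-off analysis script.

## The model

Patients arrive in `J = 100` daily blocks of 80 (two-arm) or 120 (four-arm)
patients; each belongs to a respiratory-support subgroup `k ∈ {i, ii, iii}`
(no oxygen / oxygen only / invasive ventilation) with probabilities
24/60/16%. The 28-day death indicator of a patient in subgroup `k` on arm
`l` is

```
Y ~ Bernoulli(P[k, l])
```

with `P` the mortality matrix observed in RECOVERY (e.g. 41.4% for
ventilated patients on standard care vs 29.3% on dexamethasone).

Allocation strategies (two-arm probability of dexamethasone `α`, clipped to
[0.1, 0.9]):

| name | rule |
|---|---|
| FeR | fixed 1:1 (`α = 1/2`) |
| FuR | fixed 2:1 standard care : dexamethasone (`α = 1/3`) |
| T_f / T_s | tuning rule `θ^s / (θ^s + (1−θ)^s)`, cohort / per-subgroup |
| RMC_f / RMC_s | REMAP-CAP rule with weights `√(θ / (n + 1))` |

where `θ` is the posterior probability (independent Beta(1,1)-prior
beta-binomial model) that the arm has the lowest true mortality, `s = j/J`
is the fraction of the trial completed, and `n` is the arm's accrued sample
size in the observed window. In the four-arm trial the control arm is fixed
at 40% and the adaptive rules split a 0.6 budget over the three experimental
arms with a 0.05 floor.

Adaptation honours the trial's timing: a 34-block burn-in at the fixed
ratio (2720 patients), updates every 7 blocks, and a 28-block outcome lag —
only patients whose 28-day endpoint has matured inform `θ`.

Operating characteristics over 1000 replicates, evaluated at the first 6400
(or 9600) patients: expected deaths, allocation proportions, power and
type-I/familywise error from a Wald test on a binomial log-odds model
(Bonferroni 0.05/3 in the four-arm trial), and relative bias / MSE of the
risk-difference estimate.

## Worked example

```python
from rartrial import TrialSimulation, recovery_two_arm

res = TrialSimulation(recovery_two_arm(), "T_f", n_reps=100).run(seed=42)
print(res.summary())
```

```
Trial simulation: T_f (2-arm, 100 replicates, seed 42)
Metrics at the first 6400 of 8000 patients
------------------------------------------------------------------------
Deaths: 1531.2 +/- 3.5 (23.9%)
Allocation to standard care: 35.8% +/- 0.7
Allocation to dexamethasone: 64.2% +/- 0.7
Rejection rate (dexamethasone vs standard care): 76.0% +/- 4.3
Relative bias (dexamethasone, cohort): 1.31 x 10^-2 +/- 3.60
...
```

Read: cohort-level tuning RAR steers 64% of the first 6400 patients to
dexamethasone and averages ~1531 deaths, against ~1585 under the fixed 2:1
scheme actually used — roughly 54 trial deaths avoided — while the
rejection rate (power) drops relative to 1:1 allocation and the estimate
picks up a small, statistically negligible bias. `res.trajectory()` returns
the same metrics at every block for figure-style ramp-up curves, and
`res.oc.table` is a tidy DataFrame of every metric with Monte-Carlo
standard errors.

The full study (all policies, null-scenario error rates, report tables) runs
from the shell:

```sh
rartrial --scenario two-arm --reps 1000 --seed 1 --out results/two_arm
rartrial --scenario four-arm --reps 1000 --seed 1 --out results/four_arm
```

Custom scenarios (rates, mix, block structure, schedule) can be supplied as
a YAML file; see `rartrial.scenario.load_scenario`.

## Layout

- `rartrial.scenario` — trial scenarios, RECOVERY defaults, null variants
- `rartrial.outcomes` — seeded patient/outcome generation
- `rartrial.posterior` — probability-of-best (quadrature and Monte Carlo)
- `rartrial.allocation` — the ten allocation strategies and clip rules
- `rartrial.engine` — block-wise replicate simulation with lagged adaptation
- `rartrial.metrics` — operating characteristics and aggregation
- `rartrial.simulation` / `rartrial.experiments` / `rartrial.cli` — facade,
  suites, command line

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
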