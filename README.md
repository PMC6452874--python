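# phasefit

Quantitative analysis of the fitness costs and benefits of protein phase
separation, built around a yeast model system: two otherwise isogenic
strains express a Ura3p–GFP fusion, one soluble (`SOL`) and one carrying
an aggregation-prone tag that drives the protein into stable
intracellular deposits (`AGG`).  Growing the pair in media where Ura3p
activity is dispensable (+uracil), essential (−uracil) or toxic (+5FOA,
where Ura3p converts 5-fluoroorotic acid into toxic 5-fluorouracil)
turns protein aggregation into a measurable selective force.

The package is for experimentalists and modellers who run strain
competitions, image foci-forming cells, and want the full chain from raw
measurements to interpretable fitness parameters — plus seeded synthetic
data generators so every stage can be exercised and validated without
wet-lab data.

## What it computes

**Selection coefficients from competition assays.**  Two strains mixed
1:1 diverge exponentially; the log2 abundance ratio is linear in time
with slope ω_agg − ω_sol (doublings/h).  `SelectionModel` fits that
slope by OLS and reports

S = ln2 · (ω_agg − ω_sol)  [per hour]

with its standard error and R².  qPCR calibration (`fit_standard_curve`,
`quantify_copies`) maps Ct values to gene copies per strain, and
`doubling_time_from_growth_curve` extracts τ = ln2/μ_max from OD600
curves via a smoothing spline on ln(OD).

**Cost/benefit decomposition.**  With f_foci the mean deposited-protein
fraction of `AGG` cells and f_free their apparent free-protein fraction
(mean F_CYTO(agg) / mean F_TOTAL(sol)), the per-medium selection
coefficients decompose as

S = α·f_foci + β·f_free·[essential] + γ·f_free·[toxic]

where α is the cost of forming the deposit itself, β the cost of lost
essential activity and γ the benefit of sequestering the toxic activity.
`FitnessDecomposition.fit()` solves for (α, β, γ) per environment.

**Invasion simulation.**  A single deposit-forming mutant among 10⁶
wild-type cells, integrated deterministically in log space
(`ln N(t) = ln N(t−Δt) + Δt·ln2/τ`, Δt = 60 min), with the mutant's τ
derived from S.  Under alternating environments (default 12-h switches)
the outcome is governed by the time-weighted mean selection coefficient
S_h (`history_selection_coefficient`, `pairwise_history_grid`).

**Foci imaging.**  Re-implementation of the particle-analysis recipe:
cells are 20–255 a.u. components of 8–50 µm² and circularity 0.25–1;
foci are 40–255 a.u. components of 0.2–10 µm² assigned to the cell
containing their centroid; per cell, F_CYTO = F_TOTAL − F_FOCI exactly,
with ≥70 % deposited fluorescence classified as a "big focus".

**Noise statistics.**  Expression noise as CV = 100·σ/μ per strain,
medium and compartment, with exact (enumerated) Wilcoxon rank-sum
comparisons for small samples.

## Worked example

```python
import numpy as np
from phasefit import (EnvironmentCondition, EnvironmentSchedule,
                      GeneratorParams, SelectionModel, FitnessDecomposition,
                      simulate_competition_series, simulate_population,
                      time_to_dominance)
from phasefit.decomposition import PopulationFractions

env = EnvironmentCondition("30C", "FOA", tau_sol=2.7)
params = GeneratorParams(omega_agg=0.4793, omega_sol=0.4, noise_sd_log2=0.0)
series = simulate_competition_series(params, env)
res = SelectionModel.from_series(series).fit()
print(res.summary())

fr = PopulationFractions(f_foci=0.8, f_free=0.3, n_agg=200, n_sol=200)
dec = FitnessDecomposition({"PLUS_URA": -0.02, "MINUS_URA": -0.103,
                            "FOA": 0.055}, fr, env_label="30C").fit()
print(dec.summary())

inv = EnvironmentCondition("FOA-30C", "FOA", tau_sol=2.7, S=0.055)
traj = simulate_population(EnvironmentSchedule.constant(inv, 400.0))
print(f"dominance after {time_to_dominance(traj):.1f} WT generations")
```

prints

```
Selection coefficient (log2-ratio OLS)
--------------------------------------
n points                   7
slope (log2/h)       0.07930
S (1/h)              0.05497
se(S) (1/h)          0.00000
R^2                   1.0000
Fitness decomposition  [30C]
---------------------------------------------
f_foci (deposited fraction)          0.8000
f_free (apparent free fraction)      0.3000
alpha  (deposit cost, 1/h)          -0.0250
beta   (loss-of-function, 1/h)      -0.2767
gamma  (gain-of-protection, 1/h)     0.2500
S[PLUS_URA ] observed  -0.0200  predicted  -0.0200
S[MINUS_URA] observed  -0.1030  predicted  -0.1030
S[FOA      ] observed   0.0550  predicted   0.0550
dominance after 93.3 WT generations
```

The fitted S = 0.055/h is ln2 times the 0.0793 doublings/h growth-rate
gap put into the generator; the decomposition says deposit formation
itself costs little (α = −0.025/h weighting 80 % deposited protein),
while the fate of the remaining free protein dominates fitness — a cost
when the enzyme is essential (β < 0), a benefit when it is toxic
(γ > 0).  At S = 0.055/h a single such mutant overtakes half of a
10⁶-cell population in ≈ 93 wild-type generations (2.7 h each).

A `phasefit` command exposes the same chain from the shell
(`generate`, `estimate-s`, `decompose`, `simulate`, `grid`, `segment`,
`stats`, `run-all`, `validate-config`); `phasefit run-all --out report/`
runs the full synthetic pipeline and writes CSV/JSON reports.

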