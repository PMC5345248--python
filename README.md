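# penselect

Penalized linear regression methods for variable selection with
correlated covariates, built around a motivating problem from child-health
epidemiology: identifying which of 33 environmental-enteropathy biomarkers
and clinical risk factors measured in a Bangladeshi birth cohort are
informative for the height-for-age z-score (HAZ) at one year of age, when
eight of the covariates are strongly correlated and only a handful carry
signal.

The package is for biostatisticians who want a tested, self-contained
implementation of the full comparison workflow: five penalized estimators,
a stepwise baseline, BIC tuning, a simulation study against an oracle, and
a bootstrap stability analysis — plus a synthetic cohort generator so the
whole pipeline runs with no access to the original trial data.

## The model

All methods estimate the linear model Y = Xβ + ε by minimizing the
penalized least-squares objective

    (1/2n) ‖Y − Xβ‖² + Σⱼ p_λ(|βⱼ|)

with a penalty p_λ chosen from:

| family | p_λ(|β|) | notes |
|---|---|---|
| LASSO | λ\|β\| | convex, biased for large signals |
| Elastic Net | λ[α\|β\| + (1−α)β²] | α grid-searched over {0.1, …, 0.9} |
| SCAD | p′_λ(θ)=λ{I(θ≤λ) + (aλ−θ)₊/((a−1)λ)·I(θ>λ)}, a=3.7 | unbiased for \|β\|≥aλ |
| MCP | p′_λ(θ)=(aλ−θ)₊/a, a=3.0 | derivative decays from the origin |
| Adaptive LASSO | Σⱼ wⱼλ\|βⱼ\|, wⱼ=\|β̃ⱼ\|^−γ | OLS pilot β̃, γ=1 |

Fitting is by cyclic coordinate descent on internally standardized
covariates, where each coordinate update is the exact closed-form
minimizer of ½(z−β)² + p_λ(|β|). The tuning parameter λ is selected by
minimizing BIC(λ) = n log(RSS/n) + df(λ) log(n) along a 100-point
log-spaced λ path with warm starts; df(λ) is by default the generalized
degrees of freedom of the penalized smoother (see `docs/methods.md`).

The simulation study draws X ~ N(0, Σ) with Σ an AR(1) block (ρ^|i−j|)
among the first eight covariates and identity elsewhere, sets the noise
variance from the signal-to-noise ratio SNR = β′Σβ/σ², and scores every
method by TP/FP selection counts and by the median relative model error

    MRME = 100 × median[ ME(β̂) / ME(β̂_OLS) ],   ME(β̂) = (β̂−β)′Σ(β̂−β),

against the oracle (OLS on the true support) and the full-model OLS fit.

## Worked example

Generate a synthetic cohort shaped like the motivating study (n = 512,
SNR 2.6, AR(1) ρ = 0.5 among the correlated eight) and run the bootstrap
stability analysis for the three oracle-property methods:

```python
from penselect import generate_cohort, bootstrap_selection, render_selection_table

data = generate_cohort(n=512, seed=11)
reports = [bootstrap_selection(data, m, n_boot=100, seed=7)
           for m in ("scad", "mcp", "adaptive_lasso")]
print(render_selection_table(reports))
```

prints (abridged):

```
variable             scad      mcp       adaptive_lasso
-------------------  --------  --------  --------------
mother_weight        + (1.00)  + (1.00)  + (1.00)
HAZ_wk18             + (1.00)  + (1.00)  + (1.00)
MPO_wk12             - (0.95)  - (0.91)  - (0.89)
mannitol_wk12        - (0.73)  - (0.62)  - (0.56)
ferritin_wk6         - (0.80)  - (0.70)  - (0.66)
sCD14_wk18           - (0.99)  - (0.96)  - (0.98)
breast_feeding_wk18  - (0.97)  - (0.95)  - (0.94)
```

Each cell is the coefficient sign from the full-data fit with the fraction
of 100 bootstrap resamples (full refit, fresh λ selection per resample) in
which the variable was selected. All seven generating effects of the
synthetic cohort — the two anthropometric/maternal signals inside the
correlated block and the five independent biomarker signals — are
recovered with the correct sign and high stability, while null covariates
show low frequencies and no full-data selection.

The same stages are available from the shell:

```bash
penselect simulate --rho 0.2 --rho 0.5 --rho 0.8 --snr 1 --snr 3 --snr 5 \
    --reps 100 --seed 0 --out table_cells.csv
penselect cohort-synth --n 512 --seed 11 --out cohort.csv
penselect fit --data cohort.csv --outcome haz_1y --methods scad,mcp --out coef.csv
penselect stability --data cohort.csv --outcome haz_1y \
    --methods scad,mcp,adaptive_lasso --nboot 100 --seed 7 --out table3.txt
```

Every output starts with a provenance header (version, config, seed);
identical invocations produce byte-identical files.

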