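# copulareg

Bivariate copula regression for correlated questionnaire outcomes, built
around the joint analysis of internet addiction (Young's Internet Addiction
Test, Y-IAT, range 20–100) and smartphone addiction (Smartphone Addiction
Scale, SAS, range 33–198) in adolescents. The two scores are strongly
positively correlated, so regressing them separately — as ordinary linear or
generalized linear models do — discards information and misstates uncertainty.
This package is for biostatisticians and psychiatric-epidemiology researchers
who want to model two non-normal, dependent outcomes jointly.

## Model

By Sklar's theorem, any continuous joint distribution factors into its
margins and a unique copula:

    F(y1, y2 | x) = C[ F1(y1 | x; β1), F2(y2 | x; β2); θ ]

Each margin is a regression — here a log-normal margin for the IAT
(`log y1 ~ N(x'β1, σ)`) and a gamma margin with log link for the SAS
(`mean exp(x'β2)`, constant shape α) — and the copula C is Gaussian
(`C(u1, u2; ρ) = Φ2(Φ⁻¹(u1), Φ⁻¹(u2); ρ)`) or Student-t with correlation ρ
and degrees of freedom ν > 2. All parameters (β1, β2, σ, α, ρ[, ν]) are
estimated jointly by maximizing

    Σ_i [ log c(F1(y_i1), F2(y_i2); θ) + log f1(y_i1) + log f2(y_i2) ],

with standard errors from the inverse observed information and Wald
p-values. The workflow mirrors the practice of the field: fit candidate
iid margins and rank them by AIC/BIC; select the copula family on rank
pseudo-observations (with a parametric-bootstrap Cramér–von Mises
goodness-of-fit check); compare the copula regressions with
independence-assuming LM/GLM fits by total AIC; and select covariates by
backward elimination on the joint AIC.

The study's raw data are not deposited, so `copulareg.simulate` generates
study-like datasets from the published summary tables (covariate moments and
correlations, final-model coefficients, t-copula with ρ = 0.364 and ν = 3)
with known generative truth; every stage is validated by parameter-recovery
tests against that truth.

## Worked example

The numbered scripts under `analysis/` run the whole study pipeline on a
simulated dataset and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py
python analysis/02_fit_marginals.py
python analysis/03_select_copula.py
python analysis/04_compare_models.py
python analysis/05_fit_final_model.py
```

Script 01 simulates 714 recruited subjects, deletes outcome pairs completely
at random at the observed rate and keeps the 555 complete cases. Script 02
then prints

```
IAT: lognormal (AIC 4304.9) < gamma (AIC 4344.4) < weibull (AIC 4469.5)
SAS: gamma (AIC 5310.6) < lognormal (AIC 5313.4) < weibull (AIC 5381.6)
```

— the log-normal wins for the IAT and the gamma for the SAS, reproducing the
published margin choice. Script 03 selects the t copula
(`student_t, rho 0.481, df 3.48`) with a goodness-of-fit p of 0.259 (no
evidence against the fit), and script 04 ranks all twelve models:

```
             model  dependence  total_aic
Copula Log./Gam. t   student_t     9204.7
...
     GLM Log./Gam.  independent-GLM 9366.0
```

— every copula row beats every independence-assuming row, and the best model
couples a log-normal IAT margin with a gamma SAS margin through a t copula.
Script 05 runs backward elimination and refits the final model, ending with

```
copula correlation 0.458 (95% CI 0.373, 0.534); AIC 9195.5; n = 555
```

a strong, precisely estimated residual dependence between the two addictions
after adjusting for the psychosocial and usage covariates. (Numbers vary
with the simulation seed set in script 01.)

The same pipeline runs as a single call from a YAML config via
`copulareg.run_pipeline` / `copulareg.PipelineConfig`, or on your own CSV
(columns `y1`, `y2`, `GENDER`, `BDI`, `BAI`, `BIS`, `CASS`, `AQ`, usage-hour
columns, `YEAR`, `ALC`, `SMK`; binaries coded 0/1) via
`copulareg.io.read_dataset`.

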