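# formuopt

A quality-by-design toolkit for pharmaceutical formulation development:
experimental-design generation, response-surface modelling, desirability
optimization, Gaussian-process Bayesian optimization against a synthetic
experiment oracle, and closed-form in-vitro / in-vivo evaluation metrics.

## What it does

- **`formuopt.design`** — 12-run Plackett-Burman screening designs (up to 11
  factors, dummy columns retained for error estimation) and 3-factor,
  two-block central composite designs (8 cube + 4 cube-center runs in
  block 1, 6 axial runs at ±α plus 2 center runs in block 2, α = 1.633 by
  default), with exact coded↔actual affine transforms.
- **`formuopt.rsm`** — full 10-term quadratic response-surface fitting with
  optional fixed block effects, partial (Type-III) ANOVA with lack-of-fit /
  pure-error decomposition, and Plackett-Burman main-effect screening with
  dummy-column error estimates.
- **`formuopt.desirability`** — one-sided Derringer–Suich ramps, geometric-
  mean composite, deterministic grid scan + Nelder-Mead refinement.
- **`formuopt.gp` / `formuopt.bo`** — ARD Matérn 3/2 Gaussian-process
  regression (unit-cube inputs, standardized outputs, marginal-likelihood
  hyperparameter fitting with seeded multistarts) and a closed-loop BO
  driver proposing two points per iteration via Expected Improvement and an
  upper Confidence Bound, evaluated on the same posterior.
- **`formuopt.oracle`** — the synthetic-experiment stage: ground-truth
  quadratic surfaces for the two dissolution responses, Gaussian replicate
  noise with counter-based reproducible streams, DoE dataset simulation for
  parameter-recovery tests, a one-compartment oral PK profile simulator,
  and the study's printed data tables packaged verbatim as CSV fixtures.
- **`formuopt.biometrics`** — MTT viability %, apparent permeability
  (Papp), withdrawal-corrected intrinsic dissolution rate, fold-change
  reporting at printed precision, and non-compartmental PK analysis
  (linear trapezoid AUC, log-linear terminal slope, MRT) with relative
  bioavailability.
- **`formuopt.io` / `formuopt.cli`** — CSV dialects, validated run
  configuration, a pipeline driver, and the `formuopt` command line.

## CLI examples

```bash
formuopt design ccd --alpha 1.633 --centers-cube 4 --centers-axial 2 --out design.csv
formuopt design pb --factors 6 --out pb.csv
formuopt fit --design design.csv --responses resp.csv --response Y1 --scale actual --blocks fixed
formuopt optimize desirability --spec spec.yaml --bounds "0.5:1.5,0:0.2,0.5:1.5"
formuopt bo run --oracle eq4 --iterations 6 --seed 7 --out trace.csv
formuopt nca --profiles pk.csv --terminal-points 3
formuopt idr --profile diss.csv --window 0:15
formuopt fixtures --all --dir fixtures/
formuopt report --config pipeline.yaml
```

`bo run` uses the packaged 8 historical starting runs by default and the
noise-free dissolved-amount surface as the experiment oracle; pass
`--noise-sd` for noisy replicates and `--init` for your own starting CSV.

## Notes on the packaged data

Fixture tables are historical records kept verbatim, including their known
internal inconsistencies (e.g. one run is listed with response 42.70 in the
BO starting table but 42.3 in the CCD run table; one center-point response
of 90 is inconsistent with the published pure-error sum of squares).
Refitting the run table therefore does not reproduce the published
coefficient sets; the fitting code is instead validated by exact parameter
recovery on synthetic data with known coefficients.
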