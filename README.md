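# nlcopt

Design, surrogate modeling and multi-response optimization of
**nanostructured lipid carrier (NLC)** formulations.

Formulating an extract-loaded NLC means choosing four composition variables —
solid lipid content (X₁, wt%), liquid lipid content (X₂, % of total lipid),
emulsifier content (X₃, wt%) and extract content (X₄, wt%) — to obtain a
small particle size (Y₁, nm), a narrow size distribution (PDI, Y₂), a
suitable zeta potential (Y₃, mV) and a high entrapment efficiency of the
marker phenolic 5-O-caffeoylquinic acid (%EE, Y₄). `nlcopt` implements the
complete computational chain used for this kind of study, for formulation
scientists who want it reusable and tested:

- **Design space** — four-factor central composite rotatable design
  (2⁴ factorial + 8 axial points at α = (2⁴)^{1/4} = 2 + center replicates),
  with the coded transform xᵢ = (Xᵢ − X₀)/ΔXᵢ, and a packaged 30-run
  study dataset (mean ± SD, n = 3).
- **ANN surrogate** — a 4-9-9-4 feed-forward network, hidden activation
  tanh(z/2), linear output, trained jointly for the four responses by
  multi-restart quasi-Newton least squares with K-fold (K = 5, 24/6)
  cross-validation, plus the published network transcribed coefficient by
  coefficient. Fit indicators per partition: R², RMSE = √(SSE/n), mean
  absolute deviation, Gaussian-MLE −log-likelihood (n/2)(ln(2π·SSE/n) + 1),
  SSE and n.
- **Variable importance** — Garson's connection-weight algorithm chained
  across both hidden layers (normalized |w| path products, sums to 100% per
  response) and permutation importance as a model-agnostic cross-check.
- **Desirability optimization** — Derringer–Suich transforms d(y) ∈ [0, 1]
  per response, overall desirability D = (d₁d₂d₃d₄)^{1/4}, maximized by an
  exhaustive coded-space grid plus Nelder–Mead refinement over the
  [−2, 2]⁴ design box.
- **Release kinetics** — zero-order, first-order, Higuchi (Q = k√t),
  Hixson–Crowell and Korsmeyer–Peppas (Q/100 = k·tⁿ) fitted by nonlinear
  least squares on the % scale and ranked by adjusted R².
- **Assay arithmetic** — %EE = 100(C₁ − C₂)/C₁ and HET-CAM irritation
  scoring 5(301−t_H)/300 + 7(301−t_L)/300 + 9(301−t_C)/300 with the
  nonirritant / mild / moderate / strong classification scale.
- **Synthetic data** — generators with known ground truth for every stage
  (study datasets with replicate noise, release curves, HET-CAM tables).

## Worked example

Evaluate the published surrogate at the study's reported optimal
composition (4.80 wt% solid lipid, 30.00% liquid lipid, 3.50 wt%
emulsifier, 1.65 wt% extract):

```sh
nlcopt evaluate 4.80 30.00 3.50 1.65
```

```
Y1: 33.2337
Y2: 0.1929
Y3: -10.6039
Y4: 85.3528
```

The PDI (0.19), zeta potential (−10.6 mV) and %EE (85.4%) match the
study's published predictions (0.19, −10.85 mV, 85.49%) to within the
error introduced by the 2-decimal rounding of the published coefficients;
the particle-size output is the one response sensitive enough to that
rounding that its absolute value drifts (the published value is 61.87 nm).

The same chain from Python, training a fresh surrogate instead of using the
published one:

```python
import nlcopt

data = nlcopt.load_packaged_dataset()          # 30-run CCRD study
net, report = nlcopt.train(data, seed=0)        # 4-9-9-4, best of 20 restarts
print(report.stat("Y1", "training", "r_squared"))   # 0.9996

spec = nlcopt.spec_from_dataset(data)           # min Y1, Y2, Y3; max Y4
result = nlcopt.optimize(net, spec)
print(result.x_star_actual, result.desirability)
```

An end-to-end run (`nlcopt run --seed 0 --out report/`) writes
`fit_report.csv`, `importance.csv`, `optimization.json`, `network.json` and
a `run.log` with the seed and configuration hash.

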