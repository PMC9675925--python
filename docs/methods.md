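# Methods

## Design space

The design is a four-factor central composite rotatable design: 16
factorial corners at coded ±1, 8 axial points at ±α with α = (2⁴)^{1/4} = 2
(rotatability: α⁴ equals the number of factorial points), and 6 center
replicates — 30 runs. Coded units are canonical internally; every module
converts through xᵢ = (Xᵢ − X₀)/ΔXᵢ with the factor centers and steps

| factor | meaning | units | center X₀ | step ΔX |
|---|---|---|---|---|
| X1 | solid lipid content | wt% | 6.75 | 3.25 |
| X2 | liquid lipid content | % of total lipid | 30.0 | 15.0 |
| X3 | emulsifier content | wt% | 3.50 | 1.50 |
| X4 | plant extract content | wt% | 1.375 | 0.625 |

The extract factor's five printed levels are 2-decimal roundings
(0.13, 0.75, 1.38, 2.00, 2.63); the exact center and step are stored so the
coded transform round-trips exactly, and the packaged dataset's coded values
consequently carry up to 0.01 of display rounding on that axis. Zeta
potential is stored signed (negative mV), never as a magnitude. The
canonical run order is deterministic (factorial corners in binary order,
then axial, then center); an optional shuffle seed emulates randomized
execution.

## Surrogate network

A single fully connected 4-9-9-4 network predicts all four responses
jointly (shared hidden layers). Hidden units apply the half-gain hyperbolic
tangent tanh(z/2) to their affine pre-activation; the output layer is
linear. The published network is shipped as a checksummed JSON fixture and
**takes inputs in actual units**: its hidden biases (up to +18.45) would
pin several units at saturation everywhere on the coded [−2, 2]⁴ box,
whereas over the actual-unit design box every hidden pre-activation changes
sign — and the actual-unit convention reproduces the published predictions
at the reported optimum. A sensitivity caveat: the size response's output
weights reach 180 in magnitude, so the 2-decimal rounding of the published
coefficients moves its prediction by tens of nm; the other three responses'
output weights are of order 0.1–30 and their predictions are stable to the
rounding.

### Training

The original study fitted the network with commercial software that does
not document its algorithm, so the trainer here is specified from scratch:
full-batch squared-error minimization with analytic backpropagation
gradients under L-BFGS-B, on standardized inputs and per-response
standardized outputs (the responses span nm, dimensionless, mV and percent
scales); the standardization is folded back into the returned weights so a
trained network always maps actual units to response units. Multiple
seeded restarts are drawn from uniform initializations cycled through
scales (0.2, 0.5, 1.0); the kept restart minimizes the held-out RMSE summed
over standardized responses (training loss when no held-out rows exist),
with ties broken by training −log-likelihood and then restart index. No
penalty term is applied by default — ridge penalties from 1e-4 to 1e-1
were evaluated during development and consistently *worsened* held-out
recovery of a known truth surface. Optional flags: per-response training
(four independent 4-9-9-1 networks merged block-diagonally), 1/SD²
replicate weighting, and early stopping on the held-out fold (keeping the
L-BFGS iterate with the lowest validation loss).

Cross-validation is the K = 5 scheme on the 30 runs: seeded random
assignment to folds of 6, each fold held out once (24/6 partitions). The
default `train` call holds out fold 0; `cross_validate` runs all five.

### Fit indicators

Per response and partition: SSE = Σ(obs − pred)²; RMSE = √(SSE/n); mean
absolute deviation; R² = 1 − SSE/SST; and the Gaussian negative
log-likelihood at the maximum-likelihood variance σ̂² = SSE/n,
−logL = (n/2)(ln(2π·SSE/n) + 1). This −logL convention is pinned by the
published training-set indicators (SSE 9980.6204 with n = 24 gives RMSE
20.3926 and −logL 106.4187 exactly). A perfect fit reports −logL = −∞
(degenerate MLE variance); zero observed variance with nonzero error
reports R² = −∞.

## Variable importance

`garson_importance` generalizes Garson's connection-weight algorithm to two
hidden layers: each hidden unit's absolute incoming weights are normalized
to shares, shares are chained along every input→hidden→hidden→output path
(a matrix product of normalized |W| matrices times the absolute output
weights), and input totals are scaled to 100% per response. Biases and
activation saturation are ignored by construction — on the published
network, whose units are strongly saturated over the design box, the
weight-based ranking differs from the permutation ranking, which is why
`permutation_importance` (mean squared prediction disturbance when one
input column is shuffled, normalized to 100%) ships alongside as the
semantic cross-check. The published per-response importance percentages sum
to well over 100% per response and their normalization could not be
reconstructed; they are treated as qualitative only.

## Desirability optimization

Linear Derringer–Suich transforms (shape s = 1) with anchors at the
observed minimum and maximum of each response in the dataset, equal
weights, overall desirability the geometric mean (zero vetoes). Goals
follow the study: minimize size, PDI and zeta potential, maximize %EE.
"Minimize" is ambiguous for a negative-valued zeta potential; the default
reads it literally (most negative preferred), and a magnitude mode (|y|
minimized, i.e. closest to neutral preferred) is available. The search is
deterministic: an exhaustive grid over the coded [−2, 2]⁴ box (default
spacing 0.05, evaluated in memory-bounded chunks) followed by Nelder–Mead
refinement from the best grid point, accepted only if it improves the
incumbent, and never leaving the box (no extrapolation beyond the region
the design supports). Because the published study's desirability form,
anchors and weights are unstated, its reported desirability (85.77%) and
exact optimum are not reproduction targets; the implemented search is
instead required never to return a point worse than the reported optimum
under its own spec.

## Release kinetics

Five laws are fitted to cumulative-release profiles Q(t) (% of dose vs
hours) by bounded nonlinear least squares on the untransformed Q scale:
Q = kt; Q = 100(1 − e^{−kt}); Q = k√t; Q = 100(1 − (1 − kt)³) (cube-root
law, clamped at dose exhaustion); Q = 100·k·tⁿ. R² is computed on the Q
scale for every model so one list is comparable. Ranking uses the
**adjusted** R² (parameter-count penalized): the power law nests both the
square-root law (n = 0.5) and the zero-order law (n = 1), so its raw
least-squares R² is never below theirs on noisy data and raw-R² ranking
could never return the one-parameter truth. Even so, the nested extra
parameter wins a fixed fraction of noisy draws (an F-distribution property
independent of noise scale, roughly a third under the adjusted penalty);
the one-parameter truth beats every *non-nested* competitor essentially
always. The power law's conventional restriction to the first 60% of
release is available behind a flag and off by default. First-order and
cube-root forms assume a 100% releasable dose.

## Bioassay arithmetic

%EE = 100(C₁ − C₂)/C₁ from total (C₁) and free (C₂) marker concentrations;
inputs with C₂ > C₁ are rejected as assay inconsistencies. The HET-CAM
score weights the onset times (seconds, within a 300 s window, earliest
accepted onset 1 s) of hemorrhage (5), vessel lysis (7) and coagulation
(9): score = Σ wᵢ(301 − tᵢ)/300, so all-immediate onsets give 21.0 and an
endpoint that never occurs contributes 0 — which makes a fully
non-reactive membrane score exactly 0.00, matching the negative control.
Classification uses half-open bins [0,1) nonirritant, [1,5) mild, [5,9)
moderate, [9,∞) strong, so scores falling in the printed scale's gaps
(e.g. 0.95) still classify.

## Synthetic-data generators

`simulate_dataset` draws replicate observations around a truth network's
predictions over a design (default: the published network over the 30-run
CCRD) with Gaussian noise whose per-response SD defaults to the median
replicate SD of the packaged dataset (≈2.2 nm, 0.025, 1.7 mV, 3.5%; n = 3
replicates), records means and sample SDs, and clips PDI to [0, 1] and %EE
to [0, 100] with a warning counting clipped values. Noise is homoscedastic
per response by default; a heteroscedastic mode scales each run's SD by its
predicted mean. `simulate_release` evaluates any kinetic law plus Gaussian
noise; `simulate_hetcam` samples onset times from per-category windows
chosen so the expected score sits inside the category's bin (mild:
hemorrhage only, t ~ U[110, 160]; moderate: + lysis, U[100, 150]; strong:
all three, U[20, 70]). All generators are pure functions of configuration
and seed. What the generators do *not* emulate: run-to-run SD variation
(the packaged study's replicate SDs vary several-fold between runs),
non-Gaussian assay error, and any mechanistic emulsification physics — so
passing recovery tests demonstrate statistical behavior under the stated
noise model, not robustness to real laboratory error structure.

## Known limitations

- The held-out R² of a surrogate retrained on simulated study-scale data
  meets 0.8 (median over seeds, pooled over folds) only for the
  particle-size response. The zeta-potential response cannot meet it in
  principle: its truth-surface spread (2.3 mV SD) is close to the noise on
  a 3-replicate mean (≈1.0 mV), capping even the true model's achievable
  held-out R². PDI and %EE fall short for every trainer variant examined
  (restart counts to 150, init scales to 6, ridge penalties, early
  stopping, per-response training, restart committees); 24 noisy runs are
  not enough to re-learn those surfaces to that accuracy.
- The published testing-set statistics depend on an unrecoverable random
  split and are not reproduction targets.
- The published particle-size prediction at the optimum (61.87 nm) is not
  reproducible from the printed coefficients (rounding amplification, see
  above); it is verified against an independent transcription instead.
- Garson importance is not invariant to the sign/scale ambiguity of tanh
  hidden units (rescaling a unit's incoming weights while compensating
  downstream changes the result); only positive rescaling of outgoing
  weights leaves it unchanged.
- Problem sizes used by the test suite and acceptance script (restart
  counts, seed counts, grid spacings) are the package's defaults scaled to
  keep a full run in minutes on one CPU; all are configurable upward.
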