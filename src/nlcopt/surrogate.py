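"""Feed-forward TanH surrogate: representation, evaluation, training, CV.

The surrogate is a fully connected 4-9-9-4 network.  Hidden units apply
``tanh(0.5 z)`` to their affine pre-activation (the half-gain hyperbolic
tangent used by the original study's modeling software); the output layer is
linear.  One network predicts all four responses jointly through shared
hidden layers.

Training minimizes full-batch squared error with analytic gradients under
L-BFGS-B, with inputs and responses standardized internally (the responses
span nm, dimensionless, mV and percent scales); the standardization is folded
back into the returned weights so the public network always maps actual
formulation units to response units.
"""

from __future__ import annotations

import hashlib
import importlib.resources as _resources
import json
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import RESPONSE_NAMES, StudyDataset
from .errors import (
    CorruptedFixtureError,
    InfeasibleSplitError,
    TrainingFailureError,
    ValidationError,
)

__all__ = [
    "NeuralSurrogate",
    "FitStats",
    "FitReport",
    "FoldAssignment",
    "TrainConfig",
    "tanh_half",
    "printed_network",
    "kfold_split",
    "fit_statistics",
    "train",
    "cross_validate",
]


def tanh_half(z):
    """Half-gain hyperbolic tangent, (e^{z/2} - e^{-z/2})/(e^{z/2} + e^{-z/2}).

    Odd, strictly increasing, range (-1, 1); saturates for large |z|.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("tanh_half requires finite input")
    out = np.tanh(0.5 * z)
    return float(out) if out.ndim == 0 else out


_ACTIVATIONS = {"tanh_half": lambda z: np.tanh(0.5 * z), "identity": lambda z: z}


@dataclass(frozen=True)
class NeuralSurrogate:
    """A layered feed-forward network with explicit weights and biases.

    ``weights[l]`` maps layer-l outputs to layer-(l+1) pre-activations
    (shape: size[l+1] x size[l]); ``activations[l]`` tags the nonlinearity
    applied after that map.  ``input_space`` records whether the network
    expects actual formulation units or coded design units.
    """

    layer_sizes: tuple[int, ...]
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    activations: tuple[str, ...]
    input_space: str = "actual"
    input_names: tuple[str, ...] = ("X1", "X2", "X3", "X4")
    response_names: tuple[str, ...] = RESPONSE_NAMES
    provenance: str = ""

    def __post_init__(self) -> None:
        ls = self.layer_sizes
        if len(self.weights) != len(ls) - 1 or len(self.biases) != len(ls) - 1:
            raise ValidationError("one weight matrix and bias per layer transition")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (ls[l + 1], ls[l]) or b.shape != (ls[l + 1],):
                raise ValidationError(
                    f"layer {l}: weight shape {W.shape} or bias shape {b.shape} "
                    f"inconsistent with layer sizes {ls}"
                )
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValidationError(f"layer {l}: non-finite parameters")
        if self.activations[-1] != "identity":
            raise ValidationError("output layer must be linear")
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise ValidationError(f"unknown activation tag {a!r}")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    def forward(self, x) -> np.ndarray:
        """Evaluate the network at one point (shape (d,)) or a batch ((n, d))."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.n_inputs:
            raise ValidationError(
                f"expected {self.n_inputs} inputs, got shape {x.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValidationError("forward requires finite inputs")
        h = X
        for W, b, act in zip(self.weights, self.biases, self.activations):
            h = _ACTIVATIONS[act](h @ W.T + b)
        return h[0] if single else h

    __call__ = forward

    def predict_response(self, x, response: str) -> np.ndarray:
        j = self.response_names.index(response)
        out = self.forward(x)
        return out[..., j]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "activations": list(self.activations),
            "input_space": self.input_space,
            "input_names": list(self.input_names),
            "response_names": list(self.response_names),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralSurrogate":
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=tuple(np.asarray(W, dtype=float) for W in d["weights"]),
            biases=tuple(np.asarray(b, dtype=float) for b in d["biases"]),
            activations=tuple(d["activations"]),
            input_space=d.get("input_space", "actual"),
            input_names=tuple(d.get("input_names", ("X1", "X2", "X3", "X4"))),
            response_names=tuple(d.get("response_names", RESPONSE_NAMES)),
            provenance=d.get("provenance", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NeuralSurrogate":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def printed_network() -> NeuralSurrogate:
    """The published 4-9-9-4 surrogate, transcribed coefficient by coefficient.

    Inputs are in actual units (wt%, % of total lipid); the packaged JSON
    fixture carries a checksum over the coefficients, verified on load.
    """
    ref = _resources.files("nlcopt.data") / "printed_network.json"
    with _resources.as_file(ref) as p, open(p) as fh:
        d = json.load(fh)
    payload = json.dumps(
        {k: d[k] for k in ("layer_sizes", "weights", "biases")},
        sort_keys=True,
        separators=(",", ":"),
    )
    digest = hashlib.sha256(payload.encode()).hexdigest()
    if digest != d.get("sha256"):
        raise CorruptedFixtureError(
            "printed-network fixture failed its checksum; the packaged file "
            "appears to have been modified"
        )
    return NeuralSurrogate.from_dict(d)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------

class FitStats(NamedTuple):
    r_squared: float
    rmse: float
    mad: float
    neg_log_lik: float
    sse: float
    n: int


def fit_statistics(observed, predicted) -> FitStats:
    """Goodness-of-fit indicators for one response on one partition.

    sse = sum of squared errors; rmse = sqrt(sse/n); mad = mean absolute
    deviation; r^2 = 1 - sse/sst; the negative log-likelihood uses the
    Gaussian model with its maximum-likelihood variance sse/n,
    -logL = (n/2) (ln(2 pi sse / n) + 1).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have equal length")
    n = obs.size
    if n < 2:
        raise ValidationError("fit statistics require n >= 2")
    resid = obs - pred
    sse = float(resid @ resid)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        r2 = 1.0 if sse == 0.0 else -np.inf
    else:
        r2 = 1.0 - sse / sst
    rmse = np.sqrt(sse / n)
    mad = float(np.mean(np.abs(resid)))
    if sse == 0.0:
        nll = -np.inf  # degenerate perfect fit: MLE variance is zero
    else:
        nll = 0.5 * n * (np.log(2.0 * np.pi * sse / n) + 1.0)
    return FitStats(float(r2), float(rmse), mad, float(nll), sse, n)


@dataclass
class FitReport:
    """Per-response, per-partition fit indicators plus training metadata."""

    rows: pd.DataFrame
    converged: bool = True
    seed: int | None = None
    n_restarts: int = 1
    best_restart: int = 0

    COLUMNS = ("response", "partition", "r_squared", "rmse", "mad",
               "neg_log_lik", "sse", "n")

    def stat(self, response: str, partition: str, indicator: str) -> float:
        r = self.rows
        sel = r[(r.response == response) & (r.partition == partition)]
        if sel.empty:
            raise KeyError(f"no row for ({response}, {partition})")
        return float(sel.iloc[0][indicator])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_partitions(
        cls,
        observed: dict[str, np.ndarray],
        predicted: dict[str, np.ndarray],
        response_names: Sequence[str] = RESPONSE_NAMES,
        **meta,
    ) -> "FitReport":
        recs = []
        for part in observed:
            for j, resp in enumerate(response_names):
                st = fit_statistics(observed[part][:, j], predicted[part][:, j])
                recs.append((resp, part, *st))
        return cls(rows=pd.DataFrame(recs, columns=cls.COLUMNS), **meta)


# ---------------------------------------------------------------------------
# K-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """A seeded partition of run indices into k disjoint folds."""

    k: int
    fold_of_run: np.ndarray  # length n, values in 0..k-1
    seed: int

    @property
    def n_runs(self) -> int:
        return self.fold_of_run.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_run == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_run != fold)


def kfold_split(n_runs: int, k: int, seed: int) -> FoldAssignment:
    """Randomly assign ``n_runs`` runs to ``k`` folds of near-equal size."""
    if k < 2:
        raise InfeasibleSplitError("k must be >= 2")
    if k > n_runs:
        raise InfeasibleSplitError(f"cannot split {n_runs} runs into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_runs)
    fold_of_run = np.empty(n_runs, dtype=int)
    fold_of_run[order] = np.arange(n_runs) % k
    return FoldAssignment(k=k, fold_of_run=fold_of_run, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for surrogate training.

    n_restarts seeded random initializations are run and the restart with the
    lowest held-out RMSE (summed over standardized responses) is kept; ties
    break on training -logLik, then restart index.  With no held-out rows the
    training loss selects.  ``weight_by_sd`` enables 1/SD^2 replicate
    weighting of the loss; ``early_stopping`` keeps the L-BFGS iterate with
    the lowest validation loss instead of the final one.
    """

    n_restarts: int = 20
    max_iter: int = 500
    init_scales: tuple[float, ...] = (0.2, 0.5, 1.0)
    k: int = 5
    weight_by_sd: bool = False
    early_stopping: bool = False
    per_response: bool = False
    gtol: float = 1e-8


def _pack(weights, biases):
    return np.concatenate([W.ravel() for W in weights] + [b for b in biases])


def _unpack(theta, layer_sizes):
    ws, bs, off = [], [], 0
    for l in range(len(layer_sizes) - 1):
        n_out, n_in = layer_sizes[l + 1], layer_sizes[l]
        ws.append(theta[off:off + n_out * n_in].reshape(n_out, n_in))
        off += n_out * n_in
    for l in range(len(layer_sizes) - 1):
        n_out = layer_sizes[l + 1]
        bs.append(theta[off:off + n_out])
        off += n_out
    return ws, bs


def _loss_grad(theta, X, Y, layer_sizes, sample_w):
    """Weighted mean squared error and its gradient by backpropagation.

    Hidden layers are tanh(z/2); d/dz tanh(z/2) = (1 - h^2)/2.
    """
    ws, bs = _unpack(theta, layer_sizes)
    n_layers = len(ws)
    hs = [X]
    h = X
    for l in range(n_layers):
        z = h @ ws[l].T + bs[l]
        h = z if l == n_layers - 1 else np.tanh(0.5 * z)
        hs.append(h)
    resid = hs[-1] - Y
    n = X.shape[0]
    loss = 0.5 * np.sum(sample_w[:, None] * resid**2) / n
    delta = sample_w[:, None] * resid / n
    gw = [None] * n_layers
    gb = [None] * n_layers
    for l in range(n_layers - 1, -1, -1):
        gw[l] = delta.T @ hs[l]
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ ws[l]) * 0.5 * (1.0 - hs[l] ** 2)
    return loss, _pack(gw, gb)


def _fold_standardization(net_std, x_mean, x_scale, y_mean, y_scale):
    """Rewrite a network trained on standardized data to raw units."""
    ws = [W.copy() for W in net_std[0]]
    bs = [b.copy() for b in net_std[1]]
    ws[0] = ws[0] / x_scale[None, :]
    bs[0] = bs[0] - ws[0] @ x_mean
    ws[-1] = ws[-1] * y_scale[:, None]
    bs[-1] = y_mean + y_scale * bs[-1]
    return ws, bs


def _train_single(X, Y, layer_sizes, config, seed, X_val, Y_val):
    """Best-of-restarts L-BFGS fit on standardized arrays.

    Returns (weights, biases, best_restart, converged, train_loss) in
    standardized units.
    """
    rng = np.random.default_rng(seed)
    sample_w = np.ones(X.shape[0])
    best = None
    n_params = sum(
        layer_sizes[l + 1] * (layer_sizes[l] + 1) for l in range(len(layer_sizes) - 1)
    )
    for r in range(config.n_restarts):
        scale = config.init_scales[r % len(config.init_scales)]
        theta0 = rng.uniform(-scale, scale, size=n_params)
        trace: list[np.ndarray] = []
        cb = (lambda xk: trace.append(xk.copy())) if config.early_stopping else None
        res = minimize(
            _loss_grad,
            theta0,
            args=(X, Y, layer_sizes, sample_w),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": config.max_iter, "gtol": config.gtol},
        )
        if not np.isfinite(res.fun):
            raise TrainingFailureError(f"training diverged on restart {r}")
        theta = res.x
        if config.early_stopping and X_val is not None and trace:
            val_losses = [
                _loss_grad(t, X_val, Y_val, layer_sizes,
                           np.ones(X_val.shape[0]))[0]
                for t in trace
            ]
            theta = trace[int(np.argmin(val_losses))]
        train_loss = _loss_grad(theta, X, Y, layer_sizes, sample_w)[0]
        if X_val is not None:
            pred = _forward_arrays(theta, X_val, layer_sizes)
            sel = np.sqrt(np.mean((pred - Y_val) ** 2, axis=0)).sum()
        else:
            sel = train_loss
        key = (sel, train_loss, r)
        if best is None or key < best[0]:
            best = (key, theta, r, bool(res.success))
    _, theta, r, ok = best
    ws, bs = _unpack(theta, layer_sizes)
    return ws, bs, r, ok


def _forward_arrays(theta, X, layer_sizes):
    ws, bs = _unpack(theta, layer_sizes)
    h = X
    for l, (W, b) in enumerate(zip(ws, bs)):
        z = h @ W.T + b
        h = z if l == len(ws) - 1 else np.tanh(0.5 * z)
    return h


def train(
    data: StudyDataset,
    layer_sizes: Sequence[int] = (4, 9, 9, 4),
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    test_indices: Sequence[int] | None = None,
) -> tuple[NeuralSurrogate, FitReport]:
    """Fit the surrogate to a study dataset.

    By default the held-out partition is fold 0 of a seeded ``config.k``-fold
    split (24/6 for the 30-run study with k=5); pass ``test_indices``
    explicitly to control it, or an empty sequence to train on every run.
    The returned network maps actual units to response units.
    """
    X_all = data.actual
    Y_all = data.response_means
    n, n_resp = X_all.shape[0], Y_all.shape[1]
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if layer_sizes[0] != X_all.shape[1] or layer_sizes[-1] != n_resp:
        raise ValidationError(
            f"layer sizes {layer_sizes} do not match {X_all.shape[1]} inputs "
            f"and {n_resp} responses"
        )
    if test_indices is None:
        folds = kfold_split(n, config.k, seed)
        test_idx = folds.test_indices(0)
    else:
        test_idx = np.asarray(test_indices, dtype=int)
    train_mask = np.ones(n, dtype=bool)
    train_mask[test_idx] = False
    tr = np.flatnonzero(train_mask)
    if tr.size < n_resp + 2:
        raise ValidationError("too few training rows for the number of responses")

    x_mean, x_scale = X_all[tr].mean(axis=0), X_all[tr].std(axis=0)
    y_mean, y_scale = Y_all[tr].mean(axis=0), Y_all[tr].std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_scale[y_scale == 0] = 1.0
    Xs = (X_all - x_mean) / x_scale
    Ys = (Y_all - y_mean) / y_scale
    if config.weight_by_sd:
        # replicate-weighted loss folds 1/SD^2 into per-run sample weights,
        # rescaled to mean 1 per response then averaged across responses
        sd = data.response_sds / y_scale
        w = 1.0 / np.clip(sd, 1e-3, None) ** 2
        sample_w = (w / w.mean(axis=0)).mean(axis=1)
    else:
        sample_w = np.ones(n)

    X_val = Xs[test_idx] if test_idx.size else None
    Y_val = Ys[test_idx] if test_idx.size else None

    if config.per_response:
        parts = []
        for j in range(n_resp):
            sizes_j = (layer_sizes[0], *layer_sizes[1:-1], 1)
            parts.append(
                _train_single(Xs[tr], Ys[tr][:, [j]], sizes_j, config,
                              seed + 1000 * j, X_val,
                              None if Y_val is None else Y_val[:, [j]])
            )
        ws, bs = _merge_block_diagonal([p[:2] for p in parts], layer_sizes)
        layer_sizes = (layer_sizes[0],
                       *(s * n_resp for s in layer_sizes[1:-1]), n_resp)
        best_restart, ok = parts[0][2], all(p[3] for p in parts)
    else:
        ws, bs, best_restart, ok = _train_single(
            Xs[tr], Ys[tr], layer_sizes, config, seed, X_val, Y_val
        )

    ws, bs = _fold_standardization((ws, bs), x_mean, x_scale, y_mean, y_scale)
    net = NeuralSurrogate(
        layer_sizes=tuple(layer_sizes),
        weights=tuple(ws),
        biases=tuple(bs),
        activations=tuple(["tanh_half"] * (len(layer_sizes) - 2) + ["identity"]),
        input_space="actual",
        response_names=RESPONSE_NAMES,
        provenance=f"trained (seed={seed}, restarts={config.n_restarts})",
    )
    observed = {"training": Y_all[tr]}
    predicted = {"training": net.forward(X_all[tr])}
    if test_idx.size:
        observed["testing"] = Y_all[test_idx]
        predicted["testing"] = net.forward(X_all[test_idx])
    report = FitReport.from_partitions(
        observed, predicted, RESPONSE_NAMES,
        converged=ok, seed=seed, n_restarts=config.n_restarts,
        best_restart=best_restart,
    )
    return net, report


def _merge_block_diagonal(parts, layer_sizes):
    """Assemble per-response networks into one block-diagonal network."""
    n_resp = len(parts)
    n_hidden = len(layer_sizes) - 2
    ws, bs = [], []
    for l in range(n_hidden + 1):
        blocks_w = [p[0][l] for p in parts]
        blocks_b = [p[1][l] for p in parts]
        if l == 0:
            W = np.vstack(blocks_w)
        else:
            from scipy.linalg import block_diag

            W = block_diag(*blocks_w)
        ws.append(W)
        bs.append(np.concatenate(blocks_b))
    return ws, bs


def cross_validate(
    data: StudyDataset,
    layer_sizes: Sequence[int] = (4, 9, 9, 4),
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[list[tuple[NeuralSurrogate, FitReport]], FoldAssignment]:
    """Run the full K-fold scheme: one train/report pair per held-out fold."""
    folds = kfold_split(data.n_runs, config.k, seed)
    out = []
    for f in range(config.k):
        out.append(
            train(data, layer_sizes, config, seed=seed + f,
                  test_indices=folds.test_indices(f))
        )
    return out, folds
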