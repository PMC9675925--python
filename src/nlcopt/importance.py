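"""Relative importance of each input to each response of the surrogate.

Two methods are provided.  ``garson_importance`` is the connection-weight
(Garson) algorithm: the contribution of input j to an output is the sum over
all input-to-output paths of products of absolute weights, with each hidden
unit's share normalized by the total absolute incoming weight at that unit,
finally rescaled so the inputs sum to 100% per response.  For networks with
two hidden layers the per-layer normalized shares are chained along every
path.  ``permutation_importance`` is a model-agnostic semantic cross-check:
the mean squared disturbance of the prediction when one input column is
shuffled, normalized to 100%.

Both methods ignore biases; Garson importance is also blind to activation
saturation, which is why the permutation method is kept alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .surrogate import NeuralSurrogate

__all__ = ["ImportanceResult", "garson_importance", "permutation_importance",
           "importance_table"]


@dataclass(frozen=True)
class ImportanceResult:
    """Percent importance of each input for one response."""

    response: str
    percent_by_input: dict[str, float]
    method: str  # "garson_path" or "permutation"

    def ranking(self) -> list[str]:
        """Input symbols ordered from most to least important."""
        return sorted(self.percent_by_input,
                      key=self.percent_by_input.get, reverse=True)


def garson_importance(net: NeuralSurrogate, response: str) -> ImportanceResult:
    """Connection-weight importance of every input for ``response``."""
    if len(net.layer_sizes) < 3:
        raise ValidationError("Garson importance requires at least one hidden layer")
    j_out = net.response_names.index(response)
    # per-layer normalized absolute weight shares, chained by matrix product:
    # share[l][u, v] = |W_l[u, v]| / sum_v' |W_l[u, v']|
    shares = []
    for W in net.weights[:-1]:
        a = np.abs(W)
        denom = a.sum(axis=1, keepdims=True)
        if np.any(denom == 0):
            raise ValidationError(
                "undefined importance: a hidden unit has all-zero incoming weights"
            )
        shares.append(a / denom)
    w_out = np.abs(net.weights[-1][j_out])  # contributions of last hidden layer
    contrib = w_out
    for share in reversed(shares):
        contrib = contrib @ share  # accumulate along paths back to the inputs
    total = contrib.sum()
    if total == 0:
        raise ValidationError("undefined importance: zero weight network")
    pct = 100.0 * contrib / total
    return ImportanceResult(
        response=response,
        percent_by_input=dict(zip(net.input_names, pct.tolist())),
        method="garson_path",
    )


def permutation_importance(
    net: NeuralSurrogate,
    X: np.ndarray,
    response: str,
    seed: int = 0,
    n_perm: int = 20,
) -> ImportanceResult:
    """Permutation importance of each input over the evaluation points ``X``.

    For each input column the rows are shuffled ``n_perm`` times and the mean
    squared change of the predicted response is recorded; results are
    normalized to sum to 100%.  A constant column gets zero importance.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    base = net.predict_response(X, response)
    raw = np.zeros(net.n_inputs)
    for j in range(net.n_inputs):
        if np.ptp(X[:, j]) == 0:
            import warnings

            warnings.warn(f"input {net.input_names[j]} is constant; importance 0")
            continue
        acc = 0.0
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(X[:, j])
            acc += np.mean((net.predict_response(Xp, response) - base) ** 2)
        raw[j] = acc / n_perm
    total = raw.sum()
    pct = 100.0 * raw / total if total > 0 else raw
    return ImportanceResult(
        response=response,
        percent_by_input=dict(zip(net.input_names, pct.tolist())),
        method="permutation",
    )


def importance_table(results: list[ImportanceResult]) -> pd.DataFrame:
    """Long-format table (response, input, method, percent) for export."""
    recs = [
        (r.response, inp, r.method, pct)
        for r in results
        for inp, pct in r.percent_by_input.items()
    ]
    return pd.DataFrame(recs, columns=["response", "input", "method", "percent"])
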