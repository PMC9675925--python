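"""Derringer–Suich desirability functions and multi-response optimization.

Each response y is mapped to a desirability d(y) in [0, 1] relative to its
goal.  For a minimized response with anchors (low, high) and shape s:
d = 1 for y <= low, 0 for y >= high, ((high - y)/(high - low))^s between;
a maximized response mirrors this.  The overall desirability is the
geometric mean of the per-response values, so any fully undesirable
response vetoes a candidate.

The optimizer is a deterministic two-stage search over the coded design box
[-2, 2]^4: a dense grid pass followed by Nelder–Mead refinement from the
best grid point, clipped to the box.  No extrapolation beyond the region
supported by the design is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .design import Factor, TABLE_FACTORS, StudyDataset
from .errors import ValidationError
from .surrogate import NeuralSurrogate

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "OptimizationResult",
    "desirability_one",
    "overall_desirability",
    "spec_from_dataset",
    "optimize",
]


def desirability_one(y, goal: str, anchor_low: float, anchor_high: float,
                     shape: float = 1.0):
    """Desirability of a single response value (vectorized over ``y``)."""
    if not anchor_low < anchor_high:
        raise ValidationError(
            f"anchors must satisfy low < high, got ({anchor_low}, {anchor_high})"
        )
    if shape <= 0:
        raise ValidationError("shape exponent must be > 0")
    y = np.asarray(y, dtype=float)
    span = anchor_high - anchor_low
    if goal == "minimize":
        t = (anchor_high - y) / span
    elif goal == "maximize":
        t = (y - anchor_low) / span
    else:
        raise ValidationError(f"goal must be minimize or maximize, got {goal!r}")
    d = np.clip(t, 0.0, 1.0) ** shape
    return float(d) if d.ndim == 0 else d


def overall_desirability(d) -> float | np.ndarray:
    """Geometric mean of component desirabilities; zero if any is zero."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValidationError("empty desirability vector")
    if np.any((d < 0) | (d > 1)):
        raise ValidationError("component desirabilities must be in [0, 1]")
    out = np.exp(np.mean(np.log(np.clip(d, 1e-300, None)), axis=-1))
    out = np.where(np.any(d == 0, axis=-1), 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ResponseGoal:
    goal: str  # "minimize" | "maximize"
    anchor_low: float
    anchor_high: float
    shape: float = 1.0

    def __call__(self, y):
        return desirability_one(y, self.goal, self.anchor_low,
                                self.anchor_high, self.shape)


@dataclass(frozen=True)
class DesirabilitySpec:
    """Per-response desirability goals.

    ``zeta_mode`` controls how "minimize" is read for the (negative-valued)
    zeta potential Y3: "raw" minimizes the signed value literally;
    "magnitude" applies the goal to |y| instead.
    """

    goals: dict[str, ResponseGoal]
    zeta_mode: str = "raw"

    def component(self, response: str, y):
        g = self.goals[response]
        if response == "Y3" and self.zeta_mode == "magnitude":
            return g(np.abs(np.asarray(y, dtype=float)))
        return g(y)


def spec_from_dataset(
    data: StudyDataset,
    goals: dict[str, str] | None = None,
    zeta_mode: str = "raw",
) -> DesirabilitySpec:
    """Build a spec with anchors at the observed min/max of each response.

    Default goals follow the study: minimize size, PDI and zeta potential;
    maximize %EE.
    """
    goals = goals or {"Y1": "minimize", "Y2": "minimize",
                      "Y3": "minimize", "Y4": "maximize"}
    means = data.response_means
    out = {}
    for j, resp in enumerate(("Y1", "Y2", "Y3", "Y4")):
        col = means[:, j]
        if resp == "Y3" and zeta_mode == "magnitude":
            col = np.abs(col)
        out[resp] = ResponseGoal(goals[resp], float(col.min()), float(col.max()))
    return DesirabilitySpec(goals=out, zeta_mode=zeta_mode)


@dataclass(frozen=True)
class OptimizationResult:
    x_star_actual: tuple[float, ...]
    x_star_coded: tuple[float, ...]
    desirability: float
    predicted_responses: dict[str, float]
    component_desirabilities: dict[str, float]
    n_grid_evaluations: int
    n_refine_evaluations: int

    def to_dict(self) -> dict:
        return {
            "x_star_actual": list(self.x_star_actual),
            "x_star_coded": list(self.x_star_coded),
            "desirability": self.desirability,
            "predicted_responses": self.predicted_responses,
            "component_desirabilities": self.component_desirabilities,
            "n_grid_evaluations": self.n_grid_evaluations,
            "n_refine_evaluations": self.n_refine_evaluations,
        }


def _overall_at(net, spec, factors, coded_batch):
    """Overall desirability at a batch of coded points (n, 4)."""
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    actual = centers + coded_batch * steps
    pred = net.forward(actual)
    d = np.column_stack(
        [spec.component(resp, pred[:, j])
         for j, resp in enumerate(net.response_names)]
    )
    return overall_desirability(d), pred, d


def optimize(
    net: NeuralSurrogate,
    spec: DesirabilitySpec,
    factors: Sequence[Factor] = TABLE_FACTORS,
    grid_step: float = 0.05,
    box: tuple[float, float] = (-2.0, 2.0),
    chunk: int = 500_000,
) -> OptimizationResult:
    """Maximize the overall desirability of the surrogate over the design box.

    Deterministic two-stage search: an exhaustive coded-space grid with
    spacing ``grid_step`` per axis, then Nelder–Mead refinement from the best
    grid point (evaluations clipped to the box).  The refined point is only
    accepted if it improves on the grid incumbent.
    """
    missing = [r for r in net.response_names if r not in spec.goals]
    if missing:
        raise ValidationError(f"desirability spec missing response(s): {missing}")
    lo, hi = box
    axis = np.arange(lo, hi + grid_step / 2, grid_step)
    k = len(factors)
    n_total = len(axis) ** k
    best_d, best_x = -1.0, None
    # enumerate the grid lazily in chunks to bound memory
    for start in range(0, n_total, chunk):
        idx = np.arange(start, min(start + chunk, n_total))
        batch = np.stack(
            [axis[i] for i in np.unravel_index(idx, (len(axis),) * k)], axis=1
        )
        D, _, _ = _overall_at(net, spec, factors, batch)
        i = int(np.argmax(D))
        if D[i] > best_d:
            best_d, best_x = float(D[i]), batch[i].copy()

    n_refine = 0

    def neg_overall(x):
        nonlocal n_refine
        n_refine += 1
        xc = np.clip(x, lo, hi)
        D, _, _ = _overall_at(net, spec, factors, xc[None, :])
        return -float(D[0])

    res = minimize(neg_overall, best_x, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    x_ref = np.clip(res.x, lo, hi)
    d_ref = -neg_overall(x_ref)
    if d_ref > best_d:
        best_d, best_x = d_ref, x_ref

    D, pred, d = _overall_at(net, spec, factors, best_x[None, :])
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return OptimizationResult(
        x_star_actual=tuple((centers + best_x * steps).tolist()),
        x_star_coded=tuple(best_x.tolist()),
        desirability=float(D[0]),
        predicted_responses=dict(zip(net.response_names, pred[0].tolist())),
        component_desirabilities=dict(zip(net.response_names, d[0].tolist())),
        n_grid_evaluations=n_total,
        n_refine_evaluations=n_refine,
    )
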