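"""Drug-release kinetics: model fitting and ranking.

Five classical release laws are fitted to cumulative-release profiles
(Q in % of dose vs time in hours):

==================  =============================  ==========
model               Q(t)                           parameters
==================  =============================  ==========
zero_order          k t                            k
first_order         100 (1 - e^{-k t})             k
higuchi             k sqrt(t)                      k
hixson_crowell      100 (1 - (1 - k t)^3)          k
korsmeyer_peppas    100 k t^n                      k, n
==================  =============================  ==========

All models are fitted by nonlinear least squares on the untransformed Q
scale, and R^2 is computed on that same scale for every model so a single
R^2 list ranks them comparably.  The Korsmeyer–Peppas power law is
conventionally applied to the first 60% of release only; an optional cutoff
flag enables that restriction (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitFailureError, ValidationError

__all__ = ["ReleaseProfile", "KineticFit", "MODELS", "MODEL_N_PARAMS",
           "fit_kinetic", "fit_all_models", "rank_models"]


def _zero_order(t, k):
    return k * t


def _first_order(t, k):
    return 100.0 * (1.0 - np.exp(-k * t))


def _higuchi(t, k):
    return k * np.sqrt(t)


def _hixson_crowell(t, k):
    # cube-root law (1 - Q/100)^(1/3) = 1 - k t, solved for Q; once k t
    # exceeds 1 the dose is exhausted and Q stays at 100
    return 100.0 * (1.0 - np.clip(1.0 - k * t, 0.0, None) ** 3)


def _korsmeyer_peppas(t, k, n):
    return 100.0 * k * np.power(t, n)


MODELS = {
    "zero_order": _zero_order,
    "first_order": _first_order,
    "higuchi": _higuchi,
    "hixson_crowell": _hixson_crowell,
    "korsmeyer_peppas": _korsmeyer_peppas,
}
MODEL_N_PARAMS = {m: (2 if m == "korsmeyer_peppas" else 1) for m in MODELS}


@dataclass(frozen=True)
class ReleaseProfile:
    """A cumulative-release profile: paired times (h) and % released."""

    times: tuple[float, ...]
    cumulative_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.cumulative_pct, dtype=float)
        if t.size != q.size:
            raise ValidationError("times and cumulative_pct must have equal length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValidationError("times must be >= 0 and strictly increasing")
        if np.any((q < 0) | (q > 110)):
            raise ValidationError(
                "cumulative release must lie in [0, 110] % (small analytic "
                "overshoot tolerated)"
            )

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def q(self) -> np.ndarray:
        return np.asarray(self.cumulative_pct, dtype=float)

    @classmethod
    def from_csv(cls, path) -> "ReleaseProfile":
        df = pd.read_csv(path)
        for col in ("time_h", "cumulative_release_pct"):
            if col not in df.columns:
                raise ValidationError(f"release CSV missing column {col}")
        return cls(tuple(df["time_h"]), tuple(df["cumulative_release_pct"]))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_h": self.times, "cumulative_release_pct": self.cumulative_pct}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class KineticFit:
    model: str
    params: dict[str, float]
    r_squared: float
    converged: bool = True
    n_obs: int | None = None

    def predict(self, times) -> np.ndarray:
        return MODELS[self.model](np.asarray(times, dtype=float), **self.params)

    @property
    def n_params(self) -> int:
        return MODEL_N_PARAMS[self.model]

    @property
    def adj_r_squared(self) -> float:
        """Parameter-count-penalized R^2, used to rank non-nested fits fairly."""
        if self.n_obs is None or self.n_obs <= self.n_params + 1:
            return self.r_squared
        dof = (self.n_obs - 1) / (self.n_obs - self.n_params - 1)
        return 1.0 - (1.0 - self.r_squared) * dof


def _initial_guess(model: str, t: np.ndarray, q: np.ndarray):
    qm, tm = max(q.max(), 1e-6), t[-1]
    if model == "zero_order":
        return [qm / tm]
    if model == "higuchi":
        return [qm / np.sqrt(tm)]
    if model == "first_order":
        return [-np.log(max(1.0 - qm / 100.0, 1e-3)) / tm]
    if model == "hixson_crowell":
        return [(1.0 - max(1.0 - qm / 100.0, 1e-3) ** (1.0 / 3.0)) / tm]
    return [qm / 100.0 / np.sqrt(tm), 0.5]  # korsmeyer_peppas


def fit_kinetic(profile: ReleaseProfile, model: str,
                peppas_cutoff: bool = False) -> KineticFit:
    """Fit one release model to a profile by nonlinear least squares.

    ``peppas_cutoff=True`` restricts the Korsmeyer–Peppas fit to points with
    Q <= 60% (the power law's conventional validity range).
    """
    if model not in MODELS:
        raise ValidationError(f"unknown kinetic model {model!r}")
    t, q = profile.t, profile.q
    if model == "korsmeyer_peppas":
        if peppas_cutoff:
            keep = q <= 60.0
            t, q = t[keep], q[keep]
        if np.any(t <= 0):
            keep = t > 0  # power law undefined at t = 0
            t, q = t[keep], q[keep]
    n_par = MODEL_N_PARAMS[model]
    if t.size < max(3, n_par + 2):
        raise ValidationError(
            f"{model}: need at least {max(3, n_par + 2)} points, got {t.size}"
        )
    p0 = _initial_guess(model, t, q)
    bounds = ([0.0] * n_par, [np.inf] * n_par)
    try:
        popt, _ = curve_fit(MODELS[model], t, q, p0=p0, bounds=bounds,
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = np.asarray(p0, dtype=float), False
    pred = MODELS[model](t, *popt)
    sse = float(np.sum((q - pred) ** 2))
    sst = float(np.sum((q - q.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    names = ("k",) if n_par == 1 else ("k", "n")
    return KineticFit(model=model, params=dict(zip(names, popt.tolist())),
                      r_squared=float(r2), converged=converged,
                      n_obs=int(t.size))


def fit_all_models(profile: ReleaseProfile, **kwargs) -> list[KineticFit]:
    """Fit every model; a model that fails to fit is omitted with a warning."""
    fits = []
    for m in MODELS:
        try:
            fits.append(fit_kinetic(profile, m, **kwargs))
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            import warnings

            warnings.warn(f"{m} fit failed: {exc}")
    return fits


def rank_models(fits: list[KineticFit]) -> list[KineticFit]:
    """Order fits best-first; ties prefer fewer parameters, then name.

    Ranking uses the adjusted R^2 so that a two-parameter law (the power law
    nests the square-root law) cannot win on the free parameter alone; for
    fits with equal parameter counts this reduces to ordering by plain R^2.
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise FitFailureError("no successful kinetic fit to rank")
    return sorted(ok, key=lambda f: (-f.adj_r_squared, f.n_params, f.model))
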