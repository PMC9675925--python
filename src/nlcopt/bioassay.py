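"""Entrapment efficiency and HET-CAM irritation scoring.

Entrapment efficiency is the indirect assay: %EE = 100 (C1 - C2)/C1, where
C1 is the marker-compound concentration in the whole dispersion and C2 the
free (filtrate) concentration.

The hen's-egg chorioallantoic-membrane (HET-CAM) irritation score weights
the onset times (s, within a 300 s observation window) of three endpoints:

    score = 5 (301 - t_hemorrhage)/300
          + 7 (301 - t_lysis)/300
          + 9 (301 - t_coagulation)/300

An endpoint that never occurs within the window contributes 0, which makes
a fully non-reactive membrane score exactly 0.  Scores classify as
nonirritant [0, 1), mild [1, 5), moderate [5, 9), strong [9, inf) —
half-open bins so the values falling in the printed scale's gaps (e.g.
0.95) still classify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "NOT_OBSERVED",
    "IrritationObservation",
    "entrapment_efficiency",
    "irritation_score",
    "classify_irritation",
    "load_hetcam_csv",
]

#: sentinel for an endpoint that did not occur within the 300 s window
NOT_OBSERVED = None

_ENDPOINT_WEIGHTS = {"hemorrhage": 5.0, "lysis": 7.0, "coagulation": 9.0}


def entrapment_efficiency(c_total: float, c_free: float) -> float:
    """Percent of marker compound entrapped: 100 (C1 - C2)/C1."""
    if not (c_total > 0):
        raise ValidationError(f"total concentration must be > 0, got {c_total}")
    if c_free < 0:
        raise ValidationError(f"free concentration must be >= 0, got {c_free}")
    if c_free > c_total:
        raise ValidationError(
            f"assay inconsistency: free concentration {c_free} exceeds total "
            f"{c_total}"
        )
    return 100.0 * (c_total - c_free) / c_total


def _term(weight: float, t: float | None, name: str) -> float:
    if t is None or (isinstance(t, float) and np.isnan(t)):
        return 0.0
    if not (1.0 <= t <= 300.0):
        raise ValidationError(
            f"{name} onset time must lie in [1, 300] s, got {t}"
        )
    return weight * (301.0 - t) / 300.0


def irritation_score(
    hemorrhage_s: float | None = NOT_OBSERVED,
    lysis_s: float | None = NOT_OBSERVED,
    coagulation_s: float | None = NOT_OBSERVED,
) -> float:
    """HET-CAM irritation score from three endpoint onset times (s)."""
    return (
        _term(_ENDPOINT_WEIGHTS["hemorrhage"], hemorrhage_s, "hemorrhage")
        + _term(_ENDPOINT_WEIGHTS["lysis"], lysis_s, "lysis")
        + _term(_ENDPOINT_WEIGHTS["coagulation"], coagulation_s, "coagulation")
    )


def classify_irritation(score: float) -> str:
    """Map a score to {nonirritant, mild, moderate, strong}."""
    if score < 0:
        raise ValidationError(f"irritation score must be >= 0, got {score}")
    if score < 1.0:
        return "nonirritant"
    if score < 5.0:
        return "mild"
    if score < 9.0:
        return "moderate"
    return "strong"


@dataclass(frozen=True)
class IrritationObservation:
    """One egg's endpoint onset times with derived score and category."""

    hemorrhage_s: float | None = NOT_OBSERVED
    lysis_s: float | None = NOT_OBSERVED
    coagulation_s: float | None = NOT_OBSERVED

    @property
    def score(self) -> float:
        return irritation_score(self.hemorrhage_s, self.lysis_s,
                                self.coagulation_s)

    @property
    def category(self) -> str:
        return classify_irritation(self.score)


def load_hetcam_csv(path) -> pd.DataFrame:
    """Read a HET-CAM table (sample,hemorrhage_s,lysis_s,coagulation_s).

    Empty cells mean the endpoint was not observed.  Returns the table with
    added ``score`` and ``category`` columns.
    """
    df = pd.read_csv(path)
    required = ["sample", "hemorrhage_s", "lysis_s", "coagulation_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"HET-CAM CSV missing column(s): {missing}")

    def _clean(v):
        return None if pd.isna(v) else float(v)

    scores = [
        irritation_score(_clean(r.hemorrhage_s), _clean(r.lysis_s),
                         _clean(r.coagulation_s))
        for r in df.itertuples()
    ]
    out = df.copy()
    out["score"] = scores
    out["category"] = [classify_irritation(s) for s in scores]
    return out
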