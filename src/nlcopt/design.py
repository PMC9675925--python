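"""Four-factor central composite rotatable design (CCRD) and the study dataset.

A CCRD for k factors combines a 2^k full factorial cube (coded levels ±1),
2k axial (star) points at distance ±alpha with alpha = (2^k)^(1/4) so the
design is rotatable, and replicated center points.  For the four formulation
factors here (solid lipid, liquid lipid, emulsifier and extract content) this
gives 16 + 8 + n_center runs; the packaged study used n_center = 6, i.e. 30
runs in total.

Coded units are the canonical internal representation: a factor with center
X0 and step dX maps an actual value X to the coded value x = (X - X0)/dX.
"""

from __future__ import annotations

import importlib.resources as _resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UnsupportedDesignError, ValidationError

__all__ = [
    "Factor",
    "DesignPoint",
    "StudyDataset",
    "TABLE_FACTORS",
    "RESPONSE_NAMES",
    "RESPONSE_UNITS",
    "DATASET_COLUMNS",
    "actual_to_coded",
    "coded_to_actual",
    "generate_ccrd",
    "load_dataset",
    "packaged_dataset_path",
    "load_packaged_dataset",
]

#: canonical response identifiers and their units
RESPONSE_NAMES = ("Y1", "Y2", "Y3", "Y4")
RESPONSE_UNITS = {"Y1": "nm", "Y2": "", "Y3": "mV", "Y4": "%"}

#: bit-exact CSV schema for study datasets
DATASET_COLUMNS = [
    "run_id",
    "X1_wt_pct",
    "X2_pct_total_lipid",
    "X3_wt_pct",
    "X4_wt_pct",
    "Y1_nm_mean",
    "Y1_nm_sd",
    "Y2_pdi_mean",
    "Y2_pdi_sd",
    "Y3_mV_mean",
    "Y3_mV_sd",
    "Y4_ee_pct_mean",
    "Y4_ee_pct_sd",
    "n_replicates",
]

_FACTOR_COLUMNS = DATASET_COLUMNS[1:5]
_MEAN_COLUMNS = [f"{r}_{u}_mean" for r, u in
                 zip(RESPONSE_NAMES, ("nm", "pdi", "mV", "ee_pct"))]
_SD_COLUMNS = [c.replace("_mean", "_sd") for c in _MEAN_COLUMNS]


@dataclass(frozen=True)
class Factor:
    """One formulation variable of the design space.

    ``center`` and ``step`` are the actual-unit values that anchor the coded
    transform: coded = (actual - center)/step.
    """

    symbol: str
    name: str
    units: str
    center: float
    step: float
    coded_range: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValidationError(f"{self.symbol}: step must be > 0, got {self.step}")
        low = self.center + self.coded_range[0] * self.step
        if low < -1e-12:
            raise ValidationError(
                f"{self.symbol}: actual value at coded {self.coded_range[0]} "
                f"is negative ({low}); compositions cannot be negative"
            )

    def levels(self) -> dict[float, float]:
        """Actual values at the five canonical coded levels."""
        return {c: coded_to_actual(c, self) for c in (-2.0, -1.0, 0.0, 1.0, 2.0)}


#: the four factors of the packaged study.  The extract factor's printed
#: levels (0.13, 0.75, 1.38, 2.00, 2.63) are 2-decimal roundings of an exact
#: center 1.375 and step 0.625; the exact values are stored so the coded
#: transform is internally consistent.
TABLE_FACTORS: tuple[Factor, ...] = (
    Factor("X1", "solid lipid content", "wt%", 6.75, 3.25),
    Factor("X2", "liquid lipid content", "% of total lipid", 30.0, 15.0),
    Factor("X3", "emulsifier content", "wt%", 3.50, 1.50),
    Factor("X4", "plant extract content", "wt%", 1.375, 0.625),
)


def _check_finite(value: float, what: str) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{what} must be finite, got {value!r}")


def actual_to_coded(actual: float, factor: Factor) -> float:
    """Map an actual-unit value to coded design units: (X - X0)/dX."""
    _check_finite(actual, f"actual value for {factor.symbol}")
    return (actual - factor.center) / factor.step


def coded_to_actual(coded: float, factor: Factor) -> float:
    """Map a coded design value back to actual units: X0 + x*dX."""
    _check_finite(coded, f"coded value for {factor.symbol}")
    return factor.center + coded * factor.step


def _classify(coded: np.ndarray, alpha: float, atol: float = 0.05) -> str:
    """Infer whether a coded row is a factorial, axial or center point."""
    a = np.abs(np.asarray(coded, dtype=float))
    if np.all(a <= atol):
        return "center"
    if np.all(np.abs(a - 1.0) <= atol):
        return "factorial"
    on_axis = np.abs(a - alpha) <= atol
    if np.count_nonzero(on_axis) == 1 and np.all(a[~on_axis] <= atol):
        return "axial"
    return "other"


@dataclass(frozen=True)
class DesignPoint:
    """One run of the design, in both coordinate systems."""

    run_id: int
    coded: tuple[float, float, float, float]
    actual: tuple[float, float, float, float]
    point_class: str

    def __post_init__(self) -> None:
        if len(self.coded) != len(self.actual):
            raise ValidationError("coded and actual must have equal length")


def generate_ccrd(
    factors: Sequence[Factor] = TABLE_FACTORS,
    n_center: int = 6,
    shuffle_seed: int | None = None,
) -> list[DesignPoint]:
    """Generate the rotatable central composite design.

    Order is deterministic: the 2^4 factorial corners in binary order (last
    factor fastest, -1 before +1), then the 8 axial points factor by factor
    (-alpha before +alpha), then ``n_center`` center replicates.  Passing a
    ``shuffle_seed`` randomizes the run order (run_ids are reassigned after
    shuffling), mirroring randomized execution of the physical experiments.
    """
    if len(factors) != 4:
        raise UnsupportedDesignError(
            f"only the four-factor CCRD is supported, got {len(factors)} factors"
        )
    if n_center < 1:
        raise ValidationError("n_center must be >= 1")

    k = len(factors)
    alpha = (2**k) ** 0.25  # rotatability: alpha^4 = number of factorial points
    rows: list[np.ndarray] = []
    for i in range(2**k):
        bits = [(i >> (k - 1 - j)) & 1 for j in range(k)]
        rows.append(np.array([2.0 * b - 1.0 for b in bits]))
    for j in range(k):
        for sign in (-1.0, 1.0):
            row = np.zeros(k)
            row[j] = sign * alpha
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))

    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(rows))
        rows = [rows[i] for i in order]

    points = []
    for run_id, coded in enumerate(rows, start=1):
        actual = tuple(coded_to_actual(c, f) for c, f in zip(coded, factors))
        points.append(
            DesignPoint(
                run_id=run_id,
                coded=tuple(float(c) for c in coded),
                actual=actual,
                point_class=_classify(coded, alpha),
            )
        )
    return points


@dataclass
class StudyDataset:
    """The design-plus-responses table: one row per run, mean and SD per response."""

    table: pd.DataFrame = field(repr=False)
    factors: tuple[Factor, ...] = TABLE_FACTORS

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"dataset is missing column(s): {', '.join(missing)}")
        self.table = self.table[DATASET_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        t = self.table
        for col in DATASET_COLUMNS:
            bad = pd.to_numeric(t[col], errors="coerce").isna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise SchemaError(f"non-numeric value in column {col}, row {row}")
        if (t[_SD_COLUMNS].to_numpy() < 0).any():
            raise ValidationError("response SDs must be >= 0")
        pdi = t["Y2_pdi_mean"].to_numpy()
        if ((pdi < 0) | (pdi > 1)).any():
            raise ValidationError("PDI (Y2) must lie in [0, 1]")
        ee = t["Y4_ee_pct_mean"].to_numpy()
        if ((ee < 0) | (ee > 100)).any():
            raise ValidationError("%EE (Y4) must lie in [0, 100]")
        if (t["n_replicates"].to_numpy() < 1).any():
            raise ValidationError("n_replicates must be >= 1")

    # -- array views -------------------------------------------------------
    @property
    def n_runs(self) -> int:
        return len(self.table)

    @property
    def actual(self) -> np.ndarray:
        """(n_runs, 4) factor settings in actual units."""
        return self.table[_FACTOR_COLUMNS].to_numpy(dtype=float)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, 4) factor settings in coded units."""
        x = self.actual.copy()
        for j, f in enumerate(self.factors):
            x[:, j] = (x[:, j] - f.center) / f.step
        return x

    @property
    def response_means(self) -> np.ndarray:
        """(n_runs, 4) replicate means, columns ordered Y1..Y4."""
        return self.table[_MEAN_COLUMNS].to_numpy(dtype=float)

    @property
    def response_sds(self) -> np.ndarray:
        return self.table[_SD_COLUMNS].to_numpy(dtype=float)

    @property
    def points(self) -> list[DesignPoint]:
        alpha = (2 ** len(self.factors)) ** 0.25
        coded = self.coded
        out = []
        for i, row in self.table.iterrows():
            out.append(
                DesignPoint(
                    run_id=int(row["run_id"]),
                    coded=tuple(coded[i]),
                    actual=tuple(self.actual[i]),
                    point_class=_classify(coded[i], alpha),
                )
            )
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def load_dataset(path, factors: Sequence[Factor] = TABLE_FACTORS) -> StudyDataset:
    """Read a study dataset CSV (see :data:`DATASET_COLUMNS`) and validate it."""
    table = pd.read_csv(path)
    return StudyDataset(table=table, factors=tuple(factors))


def packaged_dataset_path():
    """Path of the packaged 30-run study dataset."""
    return _resources.files("nlcopt.data") / "table2_ccrd.csv"


def load_packaged_dataset() -> StudyDataset:
    """The packaged 30-run CCRD dataset (4 factors, 4 responses, n=3 replicates)."""
    with _resources.as_file(packaged_dataset_path()) as p:
        return load_dataset(p)
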