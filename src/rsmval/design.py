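"""Three-factor Box-Behnken designs and coded/actual level mapping.

A Box-Behnken design (BBD) for three factors places runs at the midpoints of
the edges of the factor cube — every (+/-1, +/-1, 0) pattern over the three
factor pairs, 12 runs — plus replicated centre points (0, 0, 0).  Factor
levels are handled in *coded* units, the affine rescaling that sends the low,
centre and high actual settings (here: sorbent masses in mg) to -1, 0 and +1.
All regression statistics downstream are computed on the coded scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import UnsupportedDesignError

__all__ = [
    "FactorSpec",
    "DesignTable",
    "generate_bbd",
    "transform_levels",
    "model_matrix",
    "MODEL_TERMS",
]

#: Column order of the full second-order model matrix.
MODEL_TERMS = ("Intercept", "A", "B", "C", "AB", "AC", "BC", "A2", "B2", "C2")

#: Relative tolerance for the symmetric-coding check low + high = 2 * centre.
_SYMMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class FactorSpec:
    """One design factor: a d-SPE sorbent and its mass levels in mg.

    The coding must be symmetric — the centre level is the midpoint of low and
    high — so that coded -1/0/+1 maps affinely onto the actual masses.  An
    asymmetric triple is rejected rather than silently mid-coded.
    """

    name: str
    actual_low: float
    actual_high: float
    actual_center: float | None = None

    def __post_init__(self) -> None:
        center = self.actual_center
        if center is None:
            center = 0.5 * (self.actual_low + self.actual_high)
            object.__setattr__(self, "actual_center", center)
        if not all(math.isfinite(v) for v in (self.actual_low, self.actual_high, center)):
            raise ValueError(f"factor {self.name!r}: levels must be finite")
        if min(self.actual_low, self.actual_high, center) <= 0:
            raise ValueError(f"factor {self.name!r}: sorbent masses must be strictly positive")
        if not self.actual_low < center < self.actual_high:
            raise ValueError(
                f"factor {self.name!r}: require low < center < high, got "
                f"({self.actual_low}, {center}, {self.actual_high})"
            )
        if abs(center - 0.5 * (self.actual_low + self.actual_high)) > _SYMMETRY_RTOL * self.half_range:
            raise ValueError(
                f"factor {self.name!r}: asymmetric coding (center must be the "
                f"midpoint of low and high)"
            )

    @property
    def half_range(self) -> float:
        return 0.5 * (self.actual_high - self.actual_low)

    def to_coded(self, actual: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(actual, dtype=float) - self.actual_center) / self.half_range

    def to_actual(self, coded: float | np.ndarray) -> float | np.ndarray:
        return self.actual_center + np.asarray(coded, dtype=float) * self.half_range


class DesignTable:
    """An ordered run table in coded units with edge/centre point labels.

    Parameters
    ----------
    runs : pandas.DataFrame
        Columns ``run_id``, ``point_type`` and one coded-level column per
        factor.
    factors : sequence of FactorSpec, optional
        Actual sorbent-mass levels; required only to express results in mg.
    """

    def __init__(self, runs: pd.DataFrame, factors: Sequence[FactorSpec] | None = None):
        required = {"run_id", "point_type"}
        if not required.issubset(runs.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        self.runs = runs.reset_index(drop=True)
        self.factors = tuple(factors) if factors is not None else None
        self.factor_names = [c for c in runs.columns if c not in required]
        if self.factors is not None and len(self.factors) != len(self.factor_names):
            raise ValueError("factor specs do not match design columns")

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def n_center(self) -> int:
        return int((self.runs["point_type"] == "center").sum())

    def coded(self) -> np.ndarray:
        """Coded levels as an (n_runs, n_factors) array."""
        return self.runs[self.factor_names].to_numpy(dtype=float)

    def model_matrix(self) -> np.ndarray:
        """Full second-order model matrix (n_runs, 10) in MODEL_TERMS order."""
        return model_matrix(self.coded())

    def actual(self) -> pd.DataFrame:
        """Run table with levels converted to actual units (mg)."""
        if self.factors is None:
            raise ValueError("no FactorSpecs attached; actual units unavailable")
        out = self.runs[["run_id", "point_type"]].copy()
        for spec, col in zip(self.factors, self.factor_names):
            out[col] = spec.to_actual(self.runs[col].to_numpy())
        return out

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors: Sequence[FactorSpec] | None = None) -> "DesignTable":
        return cls(pd.read_csv(path), factors=factors)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DesignTable {len(self)} runs, {self.n_factors} factors "
            f"({', '.join(self.factor_names)}), {self.n_center} centers>"
        )


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Second-order model matrix for 3 coded factors.

    Columns follow :data:`MODEL_TERMS`: intercept, linear A/B/C, two-factor
    interactions AB/AC/BC, pure quadratics A^2/B^2/C^2.
    """
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    if coded.shape[1] != 3:
        raise ValueError("model_matrix expects exactly 3 coded factor columns")
    a, b, c = coded.T
    return np.column_stack(
        [np.ones_like(a), a, b, c, a * b, a * c, b * c, a * a, b * b, c * c]
    )


def generate_bbd(factors: Sequence[FactorSpec], n_center: int = 5) -> DesignTable:
    """Generate the three-factor Box-Behnken design.

    The 12 edge runs are enumerated in a fixed canonical order — factor pairs
    (A,B), (A,C), (B,C), each in (-,-), (-,+), (+,-), (+,+) order — followed
    by the centre replicates.  Randomised run order is an execution detail of
    the bench experiment and does not affect any statistic computed here.

    Parameters
    ----------
    factors : three FactorSpec
    n_center : int
        Number of centre-point replicates (default 5, giving 17 runs and 4
        pure-error degrees of freedom).
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only the 3-factor Box-Behnken design is supported, got {len(factors)} factors"
        )
    if int(n_center) != n_center or n_center < 1:
        raise ValueError("n_center must be an integer >= 1")
    n_center = int(n_center)

    rows: list[list[float]] = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for lo in (-1.0, 1.0):
            for hi in (-1.0, 1.0):
                r = [0.0, 0.0, 0.0]
                r[i], r[j] = lo, hi
                rows.append(r)
    rows.extend([[0.0, 0.0, 0.0]] * n_center)

    names = [f.name for f in factors]
    table = pd.DataFrame(rows, columns=names)
    table.insert(0, "point_type", ["edge"] * 12 + ["center"] * n_center)
    table.insert(0, "run_id", np.arange(1, len(rows) + 1))
    return DesignTable(table, factors=factors)


def transform_levels(
    values: Iterable[float] | np.ndarray,
    specs: Sequence[FactorSpec],
    direction: str = "coded_to_actual",
) -> np.ndarray:
    """Map factor levels between coded and actual units.

    ``coded = (actual - center) / half_range`` per factor; the round trip is
    exact.  Points beyond |coded| > 1.2 are tolerated but flagged with a
    warning, since the quadratic surface is an extrapolation there.
    """
    values = np.asarray(values, dtype=float)
    flat = np.atleast_2d(values)
    if flat.shape[-1] != len(specs):
        raise ValueError("values and specs length mismatch")
    if not np.all(np.isfinite(flat)):
        raise ValueError("non-finite factor levels")
    if direction not in ("coded_to_actual", "actual_to_coded"):
        raise ValueError(f"unknown direction {direction!r}")

    out = np.empty_like(flat)
    for k, spec in enumerate(specs):
        if direction == "coded_to_actual":
            coded_k = flat[:, k]
            out[:, k] = spec.to_actual(flat[:, k])
        else:
            out[:, k] = spec.to_coded(flat[:, k])
            coded_k = out[:, k]
        if np.any(np.abs(coded_k) > 1.2):
            warnings.warn(
                f"factor {spec.name!r}: levels beyond |coded| > 1.2 are an "
                f"extrapolation outside the design region",
                stacklevel=2,
            )
    return out.reshape(values.shape)
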