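"""Stationary-point analysis and exact maximisation over the coded cube.

A quadratic in three factors is cheap to maximise exactly: the global maximum
over the cube [-1, 1]^3 lies either at the interior stationary point (when
that point is inside the cube and the Hessian is negative definite) or on a
face, edge or vertex, where the restriction is again a quadratic in fewer
variables.  Enumerating the 27 coordinate patterns {free, -1, +1}^3 and
solving each restricted stationary system therefore finds the exact optimum
— no iterative optimiser, no tolerance beyond linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .design import FactorSpec
from .exceptions import DegenerateSurfaceError
from .model import QuadraticModel

__all__ = [
    "StationaryPoint",
    "OptimizationResult",
    "stationary_point",
    "optimize_in_cube",
    "confirmation_check",
]

_EIG_ZERO_RTOL = 1e-8  # an eigenvalue below this fraction of max|eig| counts as zero


@dataclass(frozen=True)
class StationaryPoint:
    """Where the gradient vanishes, with the curvature classification."""

    coded: np.ndarray
    eigenvalues: np.ndarray
    nature: str  # "maximum" | "minimum" | "saddle"


@dataclass(frozen=True)
class OptimizationResult:
    """Constrained maximiser of the surface over the coded cube.

    ``predicted_count`` applies the rounding policy to the (real-valued)
    predicted response; the response is a count of compliant analytes, so the
    default policy truncates toward zero — a prediction of 42.55 drugs means
    42 whole drugs meet the window.
    """

    coded: np.ndarray
    predicted_response: float
    on_boundary: bool
    actual: np.ndarray | None = None
    predicted_count: int | None = None
    rounding: str = "truncate"


def stationary_point(model: QuadraticModel) -> StationaryPoint:
    """Solve grad Y = 0 and classify the point by Hessian eigenvalues.

    Raises
    ------
    DegenerateSurfaceError
        If the Hessian is singular (a flat direction); the error carries the
        null direction.
    """
    H = model.hessian()
    if not np.any(H):
        raise DegenerateSurfaceError("quadratic part is identically zero")
    eigval, eigvec = np.linalg.eigh(H)
    tol = _EIG_ZERO_RTOL * np.max(np.abs(eigval))
    if np.any(np.abs(eigval) <= tol):
        null = eigvec[:, int(np.argmin(np.abs(eigval)))]
        raise DegenerateSurfaceError(
            "singular Hessian: the surface has no isolated stationary point",
            null_direction=null,
        )
    x = np.linalg.solve(H, -np.asarray(model.linear, dtype=float))
    if np.all(eigval < -tol):
        nature = "maximum"
    elif np.all(eigval > tol):
        nature = "minimum"
    else:
        nature = "saddle"
    return StationaryPoint(coded=x, eigenvalues=eigval, nature=nature)


def _restricted_argmax(model: QuadraticModel, pattern) -> np.ndarray | None:
    """Stationary point of the surface restricted to one face of the cube.

    ``pattern`` holds -1.0/+1.0 for fixed coordinates and None for free ones.
    Returns the candidate point if the free-coordinate stationary system is
    solvable and lands inside the face's closed bounds, else None.
    """
    free = [i for i, v in enumerate(pattern) if v is None]
    x = np.array([0.0 if v is None else v for v in pattern])
    if not free:
        return x
    H = model.hessian()
    g0 = np.asarray(model.linear, dtype=float) + H @ x  # gradient with free coords at 0
    Hff = H[np.ix_(free, free)]
    if abs(np.linalg.det(Hff)) < 1e-12 * max(1.0, np.max(np.abs(Hff))) ** len(free):
        return None  # flat restriction; its optimum lies on a lower-dim face
    xf = np.linalg.solve(Hff, -g0[free])
    if np.any(np.abs(xf) > 1 + 1e-12):
        return None
    x[free] = np.clip(xf, -1.0, 1.0)
    return x


def optimize_in_cube(
    model: QuadraticModel,
    bounds: float = 1.0,
    specs: tuple[FactorSpec, ...] | None = None,
    rounding: str = "truncate",
) -> OptimizationResult:
    """Exact global maximiser of the quadratic over the coded cube.

    Parameters
    ----------
    model : QuadraticModel
    bounds : float
        Half-width of the symmetric coded cube (default 1, the design region).
    specs : FactorSpecs, optional
        When given, the optimum is also expressed in actual units (mg).
    rounding : {"truncate", "nearest", "none"}
        Policy mapping the real-valued predicted response to a whole-analyte
        count; "none" leaves ``predicted_count`` unset.

    Ties between equal-valued optima break to the lexicographically smallest
    coded coordinates.
    """
    if rounding not in ("truncate", "nearest", "none"):
        raise ValueError(f"unknown rounding policy {rounding!r}")
    b = float(bounds)
    scaled = QuadraticModel(
        intercept=model.intercept,
        linear=tuple(b * v for v in model.linear),
        interaction=tuple(b * b * v for v in model.interaction),
        quadratic=tuple(b * b * v for v in model.quadratic),
    )  # optimise on the unit cube in rescaled coordinates u = x / b

    best_val = -np.inf
    candidates: list[np.ndarray] = []
    for pattern in product((None, -1.0, 1.0), repeat=3):
        u = _restricted_argmax(scaled, pattern)
        if u is None:
            continue
        val = scaled.predict(u)
        if val > best_val + 1e-12:
            best_val, candidates = val, [u]
        elif val >= best_val - 1e-12:
            candidates.append(u)
    best_u = min(candidates, key=tuple)
    x = b * best_u
    on_boundary = bool(np.any(np.abs(best_u) >= 1 - 1e-9))
    y = float(model.predict(x))

    actual = None
    if specs is not None and all(s is not None for s in specs):
        actual = np.array([s.to_actual(v) for s, v in zip(specs, x)])

    count = None
    if rounding == "truncate":
        count = int(np.trunc(y))
    elif rounding == "nearest":
        count = int(np.rint(y))
    return OptimizationResult(
        coded=x,
        predicted_response=y,
        on_boundary=on_boundary,
        actual=actual,
        predicted_count=count,
        rounding=rounding,
    )


def confirmation_check(predicted: float, observations) -> tuple[float, float, float]:
    """Compare confirmation-run replicates with the model prediction.

    Returns ``(mean, RSD%, |mean - predicted|)`` where RSD uses the sample
    (ddof=1) standard deviation.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 confirmation observations")
    if not np.all(np.isfinite(obs)):
        raise ValueError("non-finite observation")
    mean = float(obs.mean())
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    rsd = 100.0 * float(obs.std(ddof=1)) / mean
    return mean, rsd, abs(mean - float(predicted))
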