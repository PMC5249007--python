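"""Closed-form expectations for the anti-median construction.

With zero overlaps, after sampling proportions ``theta1`` and ``theta2`` the
expected fraction of third-genome adjacencies with two free ends — hence the
maximal ``theta3`` — is ``(1 - theta1 - theta2)^2``, and the expected score of
the completed genome is ``s = 3 - (theta1 + theta2 + max_theta3)``.  The score
surface over the feasible simplex is concave with its maximum on the line
``theta1 + theta2 = 0.5``; imposing the analogous condition on all three pairs
gives the unique symmetric anti-median ``theta1 = theta2 = theta3 = 0.25``.

With general overlaps ``(psi, omega_ij)`` the included overlap adjacencies
lower the score additively: ``s = 3 - (theta1 + theta2 + max_theta3 + psi +
sum omega)``, the stationarity conditions become ``theta_i + theta_j = 0.5 -
psi - sum omega``, and the symmetric solution is ``0.25 - 0.5 (psi + sum
omega)`` in every coordinate.  Two candidate closed forms exist for the
general-case maximal theta3 (see :func:`max_theta3`); the default is the one
consistent with that stationarity system, and simulations via
:func:`antimedian.construct.empirical_max_theta3` arbitrate empirically.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import OverlapProfile

__all__ = [
    "SurfacePoint",
    "REFERENCE_GRID",
    "max_theta3",
    "expected_score",
    "score_gradient",
    "antimedian_solution",
    "stationarity_residuals",
    "proportional_scheme",
    "surface_sweep",
    "validate_reference_grid",
]

_ZERO = OverlapProfile()

#: Published maximal-theta3 / score grid for the zero-overlap case:
#: {(theta1, theta2): (max_theta3, score)} at the 0.05 grid over [0.15, 0.35].
REFERENCE_GRID: dict[tuple[float, float], tuple[float, float]] = {
    (0.15, 0.15): (0.4900, 2.2100),
    (0.15, 0.20): (0.4225, 2.2275),
    (0.15, 0.25): (0.3600, 2.2400),
    (0.15, 0.30): (0.3025, 2.2475),
    (0.15, 0.35): (0.2500, 2.2500),
    (0.20, 0.15): (0.4225, 2.2275),
    (0.20, 0.20): (0.3600, 2.2400),
    (0.20, 0.25): (0.3025, 2.2475),
    (0.20, 0.30): (0.2500, 2.2500),
    (0.20, 0.35): (0.2025, 2.2475),
    (0.25, 0.15): (0.3600, 2.2400),
    (0.25, 0.20): (0.3025, 2.2475),
    (0.25, 0.25): (0.2500, 2.2500),
    (0.25, 0.30): (0.2025, 2.2475),
    (0.25, 0.35): (0.1600, 2.2400),
    (0.30, 0.15): (0.3025, 2.2475),
    (0.30, 0.20): (0.2500, 2.2500),
    (0.30, 0.25): (0.2025, 2.2475),
    (0.30, 0.30): (0.1600, 2.2400),
    (0.30, 0.35): (0.1225, 2.2275),
    (0.35, 0.15): (0.2500, 2.2500),
    (0.35, 0.20): (0.2025, 2.2475),
    (0.35, 0.25): (0.1600, 2.2400),
    (0.35, 0.30): (0.1225, 2.2275),
    (0.35, 0.35): (0.0900, 2.2100),
}


@dataclass(frozen=True)
class SurfacePoint:
    """One point of the score surface in barycentric coordinates."""

    theta1: float
    theta2: float
    theta3: float
    score: float


def _check_feasible(theta1: float, theta2: float, ov: OverlapProfile) -> None:
    if theta1 < 0 or theta2 < 0:
        raise ValueError("sampling proportions must be nonnegative")
    if theta1 + theta2 + ov.total > 1.0 + 1e-12:
        raise ValueError(
            f"theta1 + theta2 + overlaps = {theta1 + theta2 + ov.total:.4f} "
            "exceeds 1: outside the feasible simplex"
        )


def max_theta3(
    theta1: float,
    theta2: float,
    overlaps: OverlapProfile | None = None,
    model: str = "stationary",
) -> float:
    """Expected maximal third-stage proportion given the first two.

    ``model="stationary"`` (default) returns
    ``(1 - psi - sum omega - theta1 - theta2)**2``, the form the symmetric
    stationarity system requires; ``model="conditional"`` divides by
    ``1 - psi - omega13 - omega23``, conditioning on the third genome's own
    shared ends.  Both reduce to ``(1 - theta1 - theta2)**2`` at zero
    overlaps.
    """
    ov = overlaps or _ZERO
    _check_feasible(theta1, theta2, ov)
    room = 1.0 - ov.total - theta1 - theta2
    if model == "stationary":
        return room * room
    if model == "conditional":
        exclusive3 = 1.0 - ov.psi - ov.omega13 - ov.omega23
        if exclusive3 <= 0.0:
            return 0.0
        return room * room / exclusive3
    raise ValueError(f"unknown model {model!r}")


def expected_score(
    theta1: float,
    theta2: float,
    overlaps: OverlapProfile | None = None,
    model: str = "stationary",
) -> float:
    """Expected score of the maximal construction at ``(theta1, theta2)``.

    ``s = 3 - (theta1 + theta2 + max_theta3 + omega12 + omega13 + omega23 +
    psi)``: every included adjacency class lowers the distance sum.
    """
    ov = overlaps or _ZERO
    t3 = max_theta3(theta1, theta2, ov, model=model)
    return 3.0 - (theta1 + theta2 + t3 + ov.total)


def score_gradient(theta1: float, theta2: float) -> float:
    """Partial derivative of the zero-overlap expected score in either theta.

    Equals ``1 - 2*theta1 - 2*theta2``; zero exactly on the ridge
    ``theta1 + theta2 = 0.5``.
    """
    return 1.0 - 2.0 * theta1 - 2.0 * theta2


def antimedian_solution(
    overlaps: OverlapProfile | None = None,
) -> tuple[float, float, float]:
    """The unique symmetric maximizer of the expected score.

    Solves the three pairwise stationarity equations
    ``theta_i + theta_j = 0.5 - psi - sum omega``; each coordinate is
    ``0.25 - 0.5 * (psi + sum omega)``.  Requires ``psi + sum omega <= 0.5``
    (otherwise the solution would be negative).
    """
    ov = overlaps or _ZERO
    if ov.total > 0.5 + 1e-12:
        raise ValueError(
            f"psi + sum omega = {ov.total:.4f} > 0.5: the symmetric solution "
            "would be negative"
        )
    t = 0.25 - 0.5 * ov.total
    return (t, t, t)


def stationarity_residuals(
    thetas: tuple[float, float, float],
    overlaps: OverlapProfile | None = None,
) -> tuple[float, float, float]:
    """Residuals of the three pairwise stationarity equations at ``thetas``.

    Each equation reads ``theta_i + theta_j - (0.5 - psi - sum omega)``;
    all three vanish exactly at :func:`antimedian_solution`.
    """
    ov = overlaps or _ZERO
    rhs = 0.5 - ov.total
    t1, t2, t3 = thetas
    return (t1 + t2 - rhs, t2 + t3 - rhs, t3 + t1 - rhs)


def proportional_scheme(
    overlaps: OverlapProfile,
) -> tuple[float, float, float]:
    """Overlap-proportional allocation of the thetas, normalized to sum 1.

    Allocates to each genome in proportion to what it already contributes
    through the overlaps: raw weight ``(omega_ij + omega_ik)/2 + psi/3`` for
    genome i.  Provided for comparison only — it does not satisfy the
    stationarity equations except in symmetric cases, and is not the
    anti-median criterion.
    """
    raw = (
        0.5 * (overlaps.omega12 + overlaps.omega13) + overlaps.psi / 3.0,
        0.5 * (overlaps.omega12 + overlaps.omega23) + overlaps.psi / 3.0,
        0.5 * (overlaps.omega13 + overlaps.omega23) + overlaps.psi / 3.0,
    )
    total = sum(raw)
    if total == 0.0:
        raise ValueError("all overlap proportions are zero: ratios undefined")
    return tuple(w / total for w in raw)


def surface_sweep(
    grid_step: float,
    overlaps: OverlapProfile | None = None,
    model: str = "stationary",
) -> pd.DataFrame:
    """Score surface on a regular ``(theta1, theta2)`` grid.

    Enumerates feasible grid points (``theta1 + theta2 + overlaps <= 1``),
    fills ``theta3`` with :func:`max_theta3` and the expected score; returns a
    DataFrame with columns theta1, theta2, theta3, score.
    """
    if not 0.0 < grid_step <= 0.25:
        raise ValueError(f"grid_step must be in (0, 0.25], got {grid_step}")
    ov = overlaps or _ZERO
    rows = []
    steps = int(round(1.0 / grid_step))
    for i in range(steps + 1):
        t1 = i * grid_step
        for j in range(steps + 1 - i):
            t2 = j * grid_step
            if t1 + t2 + ov.total > 1.0 + 1e-12:
                continue
            t3 = max_theta3(t1, t2, ov, model=model)
            rows.append(
                SurfacePoint(t1, t2, t3, expected_score(t1, t2, ov, model=model))
            )
    return pd.DataFrame(rows)


def validate_reference_grid() -> pd.DataFrame:
    """Compare the closed forms against the published 25-cell grid.

    Returns one row per grid cell with the analytic values rounded to 4
    decimals, the published values, and a boolean ``match`` column.
    """
    rows = []
    for (t1, t2), (ref_t3, ref_s) in sorted(REFERENCE_GRID.items()):
        t3 = round(max_theta3(t1, t2), 4)
        s = round(expected_score(t1, t2), 4)
        rows.append(
            {
                "theta1": t1,
                "theta2": t2,
                "theta3": t3,
                "score": s,
                "theta3_ref": ref_t3,
                "score_ref": ref_s,
                "match": t3 == ref_t3 and s == ref_s,
            }
        )
    return pd.DataFrame(rows)
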