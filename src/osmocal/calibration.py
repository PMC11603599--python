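"""Calibration of the cross-interaction scale factor against an
experimental virial target.

A lambda scan maps the scale factor to simulated (or synthetic) B23
estimates.  Because B23 decreases monotonically in lambda (stronger
cross attraction pulls the virial coefficient down), the optimum is read
off by piecewise-linear interpolation of B23(lambda) at the experimental
target; no functional form is fitted and no extrapolation beyond the
scanned range is attempted.  The uncertainty interval propagates the
target's standard error combined in quadrature with the scan's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ScanPoint",
    "LambdaScan",
    "CalibrationResult",
    "ExtrapolationError",
    "MonotonicityError",
    "fit_lambda",
    "LambdaCalibrator",
]


class ExtrapolationError(ValueError):
    """The target lies outside the scanned B23 range."""


class MonotonicityError(ValueError):
    """B23 increases with lambda beyond what the scan noise allows."""


@dataclass(frozen=True)
class ScanPoint:
    lam: float
    B23: float
    sem: float = 0.0
    run_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass
class LambdaScan:
    """Scan points (unique lambdas, stored sorted) plus the experimental
    target value with its standard error."""

    points: list[ScanPoint]
    target: tuple[float, float]
    source_protein: str = ""

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.lam)
        lams = [p.lam for p in self.points]
        if len(set(lams)) != len(lams):
            raise ValueError("lambda values must be unique")
        if self.target[1] < 0:
            raise ValueError("target sem must be non-negative")

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([p.lam for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.B23 for p in self.points])

    @property
    def sems(self) -> np.ndarray:
        return np.array([p.sem for p in self.points])


@dataclass
class CalibrationResult:
    """Interpolated optimum with a 1-SEM interval and diagnostics.

    ``consistent_lambdas`` lists scanned points whose B23 lies within one
    combined standard error of the target — the statistical sense in
    which a scanned lambda "matches" the experiment.
    """

    lambda_star: float
    lambda_interval: tuple[float, float]
    method: str = "piecewise-linear"
    monotone: bool = True
    residual_at_star: float = 0.0
    consistent_lambdas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.lambda_interval
        if not lo - 1e-12 <= self.lambda_star <= hi + 1e-12:
            raise ValueError("lambda_star must lie inside lambda_interval")


def _interp_lambda(lams: np.ndarray, values: np.ndarray, b: float) -> float:
    """Invert the decreasing piecewise-linear B23(lambda) at level b.

    Rises small enough to be tolerated as noise are flattened onto the
    running-minimum envelope so the inversion stays well defined.
    """
    env = np.minimum.accumulate(values)
    # np.interp needs increasing x; B23 decreases with lambda.
    return float(np.interp(b, env[::-1], lams[::-1]))


def fit_lambda(scan: LambdaScan, noise_factor: float = 1.0) -> CalibrationResult:
    """Read the optimal scale factor off a lambda scan.

    Requires >= 2 points and B23 decreasing in lambda (an increase is
    tolerated up to ``noise_factor`` combined SEMs of the two points
    involved; beyond that :class:`MonotonicityError` is raised).  The
    target must fall inside the scanned B23 range, otherwise
    :class:`ExtrapolationError` — refusing is better than guessing the
    shape of B23(lambda) outside the scan.
    """
    if len(scan.points) < 2:
        raise ValueError("need at least 2 scan points")
    lams, values, sems = scan.lambdas, scan.values, scan.sems
    target, target_sem = scan.target

    monotone = bool(np.all(np.diff(values) < 0))
    rises = np.diff(values)
    allowed = noise_factor * np.sqrt(sems[1:] ** 2 + sems[:-1] ** 2)
    if np.any(rises > allowed + 1e-12):
        k = int(np.argmax(rises - allowed))
        raise MonotonicityError(
            f"B23 rises from lambda={lams[k]} to {lams[k + 1]} "
            f"({values[k]} -> {values[k + 1]}) beyond the scan noise"
        )

    if not (values.min() - 1e-12 <= target <= values.max() + 1e-12):
        raise ExtrapolationError(
            f"target {target} outside scanned B23 range "
            f"[{values.min()}, {values.max()}]; refusing to extrapolate"
        )
    lam_star = _interp_lambda(lams, values, target)
    sem_at_star = float(np.interp(lam_star, lams, sems))
    combined = float(np.hypot(target_sem, sem_at_star))
    lo_b, hi_b = target - combined, target + combined
    lam_at = [
        _interp_lambda(lams, values, np.clip(b, values.min(), values.max()))
        for b in (hi_b, lo_b)  # higher B -> lower lambda
    ]
    interval = (min(lam_at), max(lam_at))
    consistent = [
        float(l)
        for l, v, s in zip(lams, values, sems)
        if abs(v - target) <= np.hypot(target_sem, s) + 1e-12
    ]
    # Residual of the interpolant at lambda*; zero up to floating point.
    residual = float(np.interp(lam_star, lams, values) - target)
    return CalibrationResult(
        lambda_star=lam_star,
        lambda_interval=interval,
        monotone=monotone,
        residual_at_star=residual,
        consistent_lambdas=consistent,
    )


class LambdaCalibrator(BaseEstimator):
    """Scan-to-target calibration with a scikit-learn interface.

    Parameters
    ----------
    target_value, target_sem:
        Experimental B23 target in L/mol and its standard error.

    After ``fit(lambdas, B23, sem)`` the optimum is in ``lambda_star_``
    with its interval in ``lambda_interval_``.
    """

    def __init__(self, target_value: float = 12.0, target_sem: float = 2.0):
        self.target_value = target_value
        self.target_sem = target_sem

    def fit(self, X, y, sem=None):
        """Fit on scan lambdas ``X`` and B23 values ``y`` (SEMs optional)."""
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if sem is None:
            sem = np.zeros_like(X)
        sem = np.asarray(sem, dtype=float).ravel()
        scan = LambdaScan(
            points=[ScanPoint(l, b, s) for l, b, s in zip(X, y, sem)],
            target=(self.target_value, self.target_sem),
        )
        result = fit_lambda(scan)
        self.result_ = result
        self.lambda_star_ = result.lambda_star
        self.lambda_interval_ = result.lambda_interval
        self.consistent_lambdas_ = result.consistent_lambdas
        self.monotone_ = result.monotone
        return self

    def predict(self, X=None) -> float:
        """The calibrated scale factor."""
        return self.lambda_star_
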