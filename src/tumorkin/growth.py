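"""Untreated Gompertz growth and therapy-convolved trajectories.

The untreated tumor volume follows the Gompertz law

    V(t) = V0 * exp[ ln(V_inf/V0) * (1 - e^{-k (t - t0)}) ],

which starts exponentially at rate k*ln(V_inf/V0) and saturates at the
carrying capacity V_inf.  An instantaneous therapy kill rate F(t)
(log-volume loss per day) enters the growth exponent through a
convolution with the Gompertz memory kernel:

    ln V(t) = ln V_gl(t) - \\int_{t0}^{t} F(t') e^{-k (t - t')} dt'.

All internal arithmetic is carried out in log-volume space so that very
large ln(V_inf/V0) or strongly supercritical therapies never overflow.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "GompertzParams",
    "VolumeTrajectory",
    "ResponseClass",
    "gl_volume",
    "gl_log_ratio",
    "therapy_integral",
    "treated_volume",
    "treated_log_ratio",
    "classify_long_term",
]

#: Instantaneous log-volume kill rate, day^-1; domain [t0, inf).
TherapyFunction = Callable[[float], float]

# Quadrature tolerances for the kernel integral.  Closed forms exist for
# the test oracles, so these are verifiable choices.
QUAD_ABS_TOL = 1e-10
QUAD_REL_TOL = 1e-8

#: log-ratio below this (and still decreasing) counts as complete response;
#: e^{-20} is far below any measurable volume fraction.
CR_LOG_THRESHOLD = -20.0


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz growth law.

    V0 and V_inf share arbitrary volume units (mm^3, SLD^3 fraction, ...);
    k is in day^-1 and t0 in days.  k may be negative in degenerate
    effective fits, but saturating growth requires k > 0.
    """

    V0: float
    V_inf: float
    k: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.V0 > 0):
            raise ValueError(f"V0 must be positive, got {self.V0}")
        if not (self.V_inf > 0):
            raise ValueError(f"V_inf must be positive, got {self.V_inf}")
        if not math.isfinite(self.k):
            raise ValueError(f"k must be finite, got {self.k}")

    @property
    def log_ratio(self) -> float:
        """ln(V_inf / V0), the saturation exponent of untreated growth."""
        return math.log(self.V_inf / self.V0)


@dataclass(frozen=True)
class VolumeTrajectory:
    """A longitudinal tumor-size series (volume or SLD-derived)."""

    times: np.ndarray
    values: np.ndarray
    rel_error: float = 0.025
    label: str = "volume"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(times) != len(values):
            raise ValueError(
                f"length mismatch: {len(times)} times vs {len(values)} values"
            )
        if len(times) < 2:
            raise ValueError("a trajectory needs at least two points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(values > 0):
            raise ValueError("volumes must be positive")
        if not (self.rel_error > 0):
            raise ValueError("rel_error must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def sigma(self) -> np.ndarray:
        """Per-point measurement SD under the relative-error model."""
        return self.rel_error * self.values


class ResponseClass(enum.Enum):
    """Asymptotic outcome of a treated trajectory."""

    CR = "complete_response"
    PR = "partial_response"
    NO_REGRESSION = "no_regression"
    INDETERMINATE = "indeterminate"


def gl_log_ratio(params: GompertzParams, t: float | np.ndarray) -> float | np.ndarray:
    """ln(V(t)/V0) of untreated Gompertz growth."""
    t = np.asarray(t, dtype=float)
    if np.any(t < params.t0):
        raise ValueError("t must be >= t0")
    out = params.log_ratio * (1.0 - np.exp(-params.k * (t - params.t0)))
    return out.item() if out.ndim == 0 else out


def gl_volume(params: GompertzParams, t: float | np.ndarray) -> float | np.ndarray:
    """Untreated Gompertz volume V(t)."""
    return params.V0 * np.exp(gl_log_ratio(params, t))


def therapy_integral(
    params: GompertzParams,
    F: TherapyFunction,
    t: float,
    *,
    abs_tol: float = QUAD_ABS_TOL,
    rel_tol: float = QUAD_REL_TOL,
) -> float:
    """Kernel-weighted cumulative therapy effect int F(t') e^{-k(t-t')} dt'.

    Evaluated by adaptive quadrature on [t0, t]; raises RuntimeError with
    the quadrature diagnostic if the estimate does not converge.
    """
    if t < params.t0:
        raise ValueError("t must be >= t0")
    if t == params.t0:
        return 0.0
    k = params.k

    def integrand(tp: float) -> float:
        return F(tp) * math.exp(-k * (t - tp))

    value, err = quad(integrand, params.t0, t, epsabs=abs_tol, epsrel=rel_tol,
                      limit=200)
    if not math.isfinite(value) or err > max(abs_tol, rel_tol * abs(value)) * 1e3:
        raise RuntimeError(
            f"therapy-effect quadrature did not converge on [{params.t0}, {t}]: "
            f"value={value}, error estimate={err}"
        )
    return value


def treated_log_ratio(params: GompertzParams, F: TherapyFunction, t: float) -> float:
    """ln(V(t)/V0) under therapy F."""
    return float(gl_log_ratio(params, t)) - therapy_integral(params, F, t)


def treated_volume(params: GompertzParams, F: TherapyFunction, t: float) -> float:
    """Therapy-convolved volume: Gompertz growth times exp(-kernel integral)."""
    return params.V0 * math.exp(treated_log_ratio(params, F, t))


def classify_long_term(
    params: GompertzParams,
    F: TherapyFunction,
    horizon: float,
    *,
    n_checkpoints: int = 16,
    cr_threshold: float = CR_LOG_THRESHOLD,
    convergence_tol: float = 1e-3,
) -> ResponseClass:
    """Classify the asymptotic response by the sign/divergence of the log-limit.

    The log-ratio ln(V(t)/V0) is evaluated on an expanding grid up to
    ``horizon``:

    * CR  -- the tail decreases monotonically below ``cr_threshold``
      (the volume fraction falls below e^{-20}: complete response);
    * PR  -- the tail converges to a finite negative value;
    * NO_REGRESSION -- the tail converges to a non-negative value;
    * INDETERMINATE -- the tail neither converges nor decreases
      monotonically within the horizon (e.g. oscillatory F).
    """
    if params.k <= 0:
        raise ValueError("classification requires k > 0 (saturating growth)")
    if horizon <= params.t0:
        raise ValueError("horizon must exceed t0")
    # geometric spacing emphasises the tail
    span = horizon - params.t0
    grid = params.t0 + span * np.geomspace(0.01, 1.0, n_checkpoints)
    logr = np.array([treated_log_ratio(params, F, float(t)) for t in grid])

    tail = logr[-4:]
    diffs = np.diff(tail)
    decreasing = bool(np.all(diffs < 0))
    converged = abs(logr[-1] - logr[-2]) < convergence_tol * (1.0 + abs(logr[-1]))

    if decreasing and logr[-1] < cr_threshold:
        return ResponseClass.CR
    if converged:
        return ResponseClass.PR if logr[-1] < 0 else ResponseClass.NO_REGRESSION
    if decreasing:
        # still heading down but not yet past the CR threshold
        return ResponseClass.INDETERMINATE
    return ResponseClass.INDETERMINATE
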