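"""Dose-response analysis for fractionally delivered conventional radiotherapy.

Each dose group's trajectory is fitted with dose-dependent effective
Gompertz parameters,

    V_d(t)/V(0) = exp[ ln(V_d_inf/V(0)) (1 - e^{-k_d t}) ],

falling back to the exponential product form
exp[ ln(V_d_inf/V(0)) k_d t ] when the series cannot disentangle the
carrying capacity from k (early-time data, k t << 1).  The dose
dependence of the chosen observable is then summarised by a power law

    y(d) = baseline - c d^lambda,

and the critical dose is where y crosses the regression threshold:
ratio = 1 for the carrying-capacity observable (V_d_inf = V(0)), 0 for
the product observable (sign change of ln(V_d_inf/V(0)) k_d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .fitting import (
    FitConfig,
    FitResult,
    exponential_model,
    fit_model,
    gompertz_ratio_model,
    identifiability_check,
)
from .growth import VolumeTrajectory

__all__ = [
    "EffectiveDoseFit",
    "DoseLaw",
    "fit_effective_per_dose",
    "fit_dose_law",
    "critical_dose",
    "interpolate_critical_dose",
]

#: lambda search interval and multistart grid for the dose-law fit; the
#: objective is multimodal in lambda and fitted exponents span 0.5 - 15.
LAMBDA_BOUNDS = (1e-6, 30.0)
LAMBDA_STARTS = (0.5, 2.0, 5.0, 15.0)


@dataclass(frozen=True)
class EffectiveDoseFit:
    """Effective-parameter fit of one dose group.

    mode FULL populates (V_inf_ratio, k_d); mode PRODUCT populates only
    g_d = ln(V_d_inf/V(0)) * k_d, the single identifiable combination of
    an exponential-regime series.
    """

    d: float
    mode: str
    V_inf_ratio: float | None = None
    k_d: float | None = None
    g_d: float | None = None
    sd: dict[str, float] | None = None
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        if self.mode == "FULL":
            if self.V_inf_ratio is None or self.k_d is None or self.g_d is not None:
                raise ValueError("FULL mode requires (V_inf_ratio, k_d) and no g_d")
        elif self.mode == "PRODUCT":
            if self.g_d is None or self.V_inf_ratio is not None or self.k_d is not None:
                raise ValueError("PRODUCT mode requires g_d only")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sd and any(s < 0 for s in self.sd.values()):
            raise ValueError("SD errors must be non-negative")

    @property
    def product(self) -> float:
        """ln(V_d_inf/V(0)) * k_d regardless of mode."""
        if self.mode == "PRODUCT":
            return float(self.g_d)
        return math.log(self.V_inf_ratio) * self.k_d


@dataclass(frozen=True)
class DoseLaw:
    """Power-law dose dependence y(d) = baseline - c d^lambda.

    observable CC_RATIO: y is V_d_inf/V(0), threshold ratio 1;
    observable PRODUCT: y is ln(V_d_inf/V(0)) k_d (day^-1), threshold 0.
    """

    observable: str
    baseline: float
    c: float
    lam: float

    def __post_init__(self) -> None:
        if self.observable not in ("CC_RATIO", "PRODUCT"):
            raise ValueError(f"unknown observable {self.observable!r}")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if not (self.lam > 0):
            raise ValueError("lambda must be positive")

    def __call__(self, d: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(d, dtype=float)
        out = self.baseline - self.c * np.power(d, self.lam)
        return out.item() if out.ndim == 0 else out

    @property
    def threshold(self) -> float:
        return 1.0 if self.observable == "CC_RATIO" else 0.0


def fit_effective_per_dose(
    traj: VolumeTrajectory, d: float, cfg: FitConfig | None = None
) -> EffectiveDoseFit:
    """Fit one dose group with effective Gompertz parameters.

    Attempts the two-parameter fit first; when the identifiability check
    flags a degenerate (exponential-regime) series, refits the
    single-parameter product model and reports mode PRODUCT.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 points per dose group")
    cfg = cfg or FitConfig()
    full = fit_model(traj, gompertz_ratio_model, cfg)
    if identifiability_check(full) == "FULL":
        lnr, k = full.params["log_vinf_ratio"], full.params["k"]
        return EffectiveDoseFit(
            d=d,
            mode="FULL",
            V_inf_ratio=math.exp(lnr),
            k_d=k,
            sd={"log_vinf_ratio": full.sd["log_vinf_ratio"], "k": full.sd["k"]},
            fit=full,
        )
    prod = fit_model(traj, exponential_model, cfg)
    prod = FitResult(**{**prod.__dict__, "mode": "PRODUCT"})
    return EffectiveDoseFit(
        d=d, mode="PRODUCT", g_d=prod.params["g"], sd={"g": prod.sd["g"]}, fit=prod
    )


def _observable_value(fit: EffectiveDoseFit, observable: str) -> float:
    if observable == "CC_RATIO":
        if fit.mode != "FULL":
            raise ValueError(
                f"dose {fit.d}: CC_RATIO law needs FULL-mode fits (got PRODUCT)"
            )
        return float(fit.V_inf_ratio)
    return fit.product


def fit_dose_law(
    fits: Sequence[EffectiveDoseFit], observable: str = "PRODUCT"
) -> DoseLaw:
    """Fit the power law baseline - c d^lambda to per-dose estimates.

    The baseline is anchored at the d = 0 (control) fit and held fixed —
    untreated growth is characterised first, therapy effects are measured
    against it.  c and lambda are free, with a multistart over lambda
    because the objective is multimodal in the exponent.
    """
    if len(fits) < 3:
        raise ValueError("need >= 3 dose points including the d=0 control")
    doses = np.array([f.d for f in fits], dtype=float)
    if np.all(doses == doses[0]):
        raise ValueError("degenerate design: all doses identical")
    try:
        i0 = next(i for i, f in enumerate(fits) if f.d == 0)
    except StopIteration:
        raise ValueError("a d=0 control fit is required to anchor the baseline")
    baseline = _observable_value(fits[i0], observable)
    d_pos = np.array([f.d for f in fits if f.d > 0], dtype=float)
    y_pos = np.array(
        [_observable_value(f, observable) for f in fits if f.d > 0], dtype=float
    )
    if len(d_pos) < 2:
        raise ValueError("need >= 2 non-zero dose points to fit (c, lambda)")

    def resid(theta: np.ndarray) -> np.ndarray:
        log_c, lam = theta
        return baseline - math.exp(log_c) * np.power(d_pos, lam) - y_pos

    best = None
    for lam0 in LAMBDA_STARTS:
        # moment start for c at the largest dose
        drop = max(baseline - y_pos[np.argmax(d_pos)], 1e-12)
        c0 = drop / d_pos.max() ** lam0
        sol = least_squares(
            resid,
            x0=[math.log(c0), lam0],
            bounds=([-80.0, LAMBDA_BOUNDS[0]], [20.0, LAMBDA_BOUNDS[1]]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    c_hat = math.exp(best.x[0])
    return DoseLaw(observable=observable, baseline=baseline, c=c_hat, lam=best.x[1])


def critical_dose(law: DoseLaw) -> float | None:
    """Dose at which the dose law crosses its regression threshold (Gy).

    Solves baseline - c d^lambda = threshold by bracketed root-finding.
    Returns 0.0 when the baseline is already at/below threshold (boundary:
    the control itself regresses) and None when no positive-dose root
    exists (c = 0, or the law never reaches the threshold).
    """
    if law.baseline <= law.threshold:
        return 0.0
    if law.c == 0:
        return None
    d_star = ((law.baseline - law.threshold) / law.c) ** (1.0 / law.lam)

    def f(d: float) -> float:
        return law(d) - law.threshold

    return float(brentq(f, 0.0, 2.0 * d_star, xtol=1e-10, rtol=1e-12))


def interpolate_critical_dose(
    doses: Sequence[float], slopes: Sequence[float]
) -> float:
    """Critical dose from growth slopes observed at different doses.

    When only per-dose log-size slopes are available (e.g. a drug dose
    lowered mid-treatment), the critical dose is estimated as the zero
    crossing of the straight line through (dose, slope) pairs: negative
    slope means regression, positive regrowth.  With two points this is
    plain linear interpolation; with more, an OLS line.
    """
    d = np.asarray(doses, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if len(d) != len(s) or len(d) < 2:
        raise ValueError("need matching dose/slope arrays with >= 2 entries")
    if np.all(s > 0) or np.all(s < 0):
        raise ValueError("slopes do not change sign: no critical dose in range")
    slope, intercept = np.polyfit(d, s, 1)
    if slope == 0:
        raise ValueError("degenerate: slope independent of dose")
    return float(-intercept / slope)
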