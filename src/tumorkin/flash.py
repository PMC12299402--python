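"""FLASH / conventional radiotherapy effect model.

A single radiation dose is described phenomenologically by the kill rate

    F(t) = c0 + c1 e^{-c2 t} - cf t            (t in days after the dose)

whose pieces map onto the observed phases of response: c0 + c1 is the
immediate cell-killing rate, c2 the decay of that direct effect, and cf
the late-time linear term.  The sign of cf is the order parameter of the
long-term outcome: cf < 0 drives complete response, cf = 0 a partial
response plateau, cf > 0 eventual regrowth.  The dose at which cf
changes sign is the critical dose.

Convolving F against the Gompertz kernel gives the closed-form ratio

    V(t)/V(0) = exp[ (lnr - c0/k - cf/k^2)(1 - e^{-kt})
                     - c1/(k - c2) (e^{-c2 t} - e^{-kt}) + t cf/k ],

with lnr = ln(V_inf/V(0)); the k -> c2 limit of the transient term is
c1 t e^{-kt} (removable singularity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .growth import GompertzParams

__all__ = [
    "FlashParams",
    "FlashDoseLaw",
    "flash_kill_rate",
    "flash_log_ratio",
    "flash_volume",
    "early_slope",
    "late_exponent",
    "regrowth_time",
    "cf_of_dose",
    "flash_critical_dose",
]

# relative |k - c2| gap below which the transient term switches to its
# analytic limit; fitted rates can legitimately approach this regime
K_C2_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class FlashParams:
    """Coefficients of the single-dose kill-rate parameterization.

    c0, c1, c2 in day^-1; cf in day^-2.  c2 >= 0 (the transient must
    decay); cf may take either sign — it is the order parameter.
    """

    c0: float
    c1: float
    c2: float
    cf: float

    def __post_init__(self) -> None:
        for name in ("c0", "c1", "c2", "cf"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.c2 < 0:
            raise ValueError(f"c2 must be >= 0, got {self.c2}")


@dataclass(frozen=True)
class FlashDoseLaw:
    """Dose dependence of the late-time coefficient: cf(d) = a - b (d - d_ref)^p.

    a in day^-2 (offset), b in day^-2 Gy^-p, d_ref in Gy (pivot dose),
    p dimensionless; valid for d >= d_ref.
    """

    a: float
    b: float
    d_ref: float
    p: float

    def __post_init__(self) -> None:
        if not (self.b > 0):
            raise ValueError(f"b must be positive, got {self.b}")
        if not (self.p > 0):
            raise ValueError(f"p must be positive, got {self.p}")


def flash_kill_rate(fp: FlashParams, t: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous kill rate F(t) = c0 + c1 e^{-c2 t} - cf t (day^-1)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time since the dose)")
    out = fp.c0 + fp.c1 * np.exp(-fp.c2 * t) - fp.cf * t
    return out.item() if out.ndim == 0 else out

def flash_log_ratio(
    gp: GompertzParams, fp: FlashParams, t: float | np.ndarray
) -> float | np.ndarray:
    """ln[V(t)/V(0)] of the closed-form treated trajectory."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    k, c2 = gp.k, fp.c2
    lnr = gp.log_ratio
    main = (lnr - fp.c0 / k - fp.cf / k**2) * (1.0 - np.exp(-k * t))
    if abs(k - c2) < K_C2_DEGENERACY_RTOL * max(abs(k), abs(c2), 1e-300):
        transient = fp.c1 * t * np.exp(-k * t)
    else:
        transient = fp.c1 / (k - c2) * (np.exp(-c2 * t) - np.exp(-k * t))
    out = main - transient + t * fp.cf / k
    return out.item() if out.ndim == 0 else out


def flash_volume(
    gp: GompertzParams, fp: FlashParams, t: float | np.ndarray
) -> float | np.ndarray:
    """Volume ratio V(t)/V(0) under a single FLASH/conventional dose."""
    return np.exp(flash_log_ratio(gp, fp, t))


def early_slope(gp: GompertzParams, fp: FlashParams) -> float:
    """Initial log-volume slope k ln(V_inf/V0) - c0 - c1 (day^-1, k t << 1).

    Negative means the volume shrinks immediately after the dose; c2 and
    cf play no role in this limit.
    """
    return gp.k * gp.log_ratio - fp.c0 - fp.c1


def late_exponent(gp: GompertzParams, fp: FlashParams, t: float | np.ndarray):
    """Late-time (k t >> 1) approximation of ln[V(t)/V(0)].

    Linear in t with slope cf/k: the sign of cf alone decides between
    continued regression and regrowth.
    """
    t = np.asarray(t, dtype=float)
    k = gp.k
    out = (gp.log_ratio - fp.c0 / k - fp.cf / k**2) + t * fp.cf / k
    return out.item() if out.ndim == 0 else out


def regrowth_time(gp: GompertzParams, fp: FlashParams) -> float | None:
    """Time t* at which a subcritical (cf > 0) trajectory rejoins the untreated trend.

    Solves (c0/k + cf/k^2) = t* cf/k, i.e. t* = c0/cf + 1/k; at t* the
    late exponent equals the untreated saturation exponent ln(V_inf/V0),
    and the model assumes plain Gompertz regrowth for t > t*.  Returns
    None for cf <= 0 (CR/PR branch: no return to the untreated trend).
    """
    if gp.k <= 0:
        raise ValueError("regrowth time requires k > 0")
    if fp.cf <= 0:
        return None
    return fp.c0 / fp.cf + 1.0 / gp.k


def cf_of_dose(law: FlashDoseLaw, d: float | np.ndarray) -> float | np.ndarray:
    """Late-time coefficient at dose d: cf(d) = a - b (d - d_ref)^p (day^-2)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < law.d_ref):
        raise ValueError(f"dose must be >= pivot {law.d_ref} Gy")
    out = law.a - law.b * np.power(d - law.d_ref, law.p)
    return out.item() if out.ndim == 0 else out


def flash_critical_dose(law: FlashDoseLaw) -> float:
    """Dose at which cf changes sign — the CR/regrowth threshold (Gy).

    cf(d) is strictly decreasing for d > d_ref, so the root is unique;
    it is located by bracketed root-finding on
    [d_ref, d_ref + 2 (a/b)^{1/p}].  If a <= 0 the sign change already
    sits at or below the pivot and d_ref is returned as a boundary value.
    """
    if law.a <= 0:
        return law.d_ref
    width = (law.a / law.b) ** (1.0 / law.p)
    lo, hi = law.d_ref, law.d_ref + 2.0 * width

    def f(d: float) -> float:
        return law.a - law.b * (d - law.d_ref) ** law.p

    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
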