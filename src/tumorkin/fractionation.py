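"""Discrete-dose bookkeeping for fractionated therapy.

Between doses the tumor regrows on the untreated Gompertz law; each
fraction n contributes a log-volume reduction RT(n) accumulated over the
following interval, so that one step reads

    V(n+1-) = V(n-) * exp[ ln(V_inf/V(n-)) (1 - e^{-k dt}) - RT(n) ].

The ratio of consecutive pre-dose volumes factorises into regrowth and
therapy parts, V(n+1-)/V(n-) = RG * TH with

    RG = exp[ ln(V_inf/V(n-)) (1 - e^{-k dt}) ]  >= 1 below saturation,
    TH = e^{-RT(n)}                              < 1 for effective doses,

and the cumulative, kernel-discounted effect after n doses

    RTtot(n) = sum_{m=1}^{n-1} RT(m) e^{-k dt (n - (m+1))}

decides net regression: V(n-) < V(1-) iff
ln(V_inf/V(1-)) (1 - e^{-(n-1) k dt}) < RTtot(n) (strict inequality).

All stepping formulas are stated for a fixed inter-dose interval dt but
generalise to irregular schedules by replacing the discounts with
e^{-k (t_n - t_m)}; the helpers below accept a scalar dt or a sequence
of interval lengths and reduce exactly to the fixed-interval forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth import GompertzParams

__all__ = [
    "FractionSchedule",
    "FractionRecord",
    "NextDosePrediction",
    "step_forward",
    "estimate_rt_series",
    "cumulative_rt",
    "regression_condition",
    "decompose_interval",
    "predict_next_dose",
    "analyze_fractions",
]


@dataclass(frozen=True)
class FractionSchedule:
    """Dose times t1..tn plus the pre-treatment observation protocol.

    The pre-treatment times (diagnosis at 0, an intermediate tau1, and
    t1-) are where untreated growth is characterised before the first
    dose; they must precede t1.
    """

    dose_times: np.ndarray
    delta_t: float | None = None
    pre_treatment_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        dose_times = np.asarray(self.dose_times, dtype=float)
        pre = np.asarray(self.pre_treatment_times, dtype=float)
        object.__setattr__(self, "dose_times", dose_times)
        object.__setattr__(self, "pre_treatment_times", pre)
        if len(dose_times) < 1:
            raise ValueError("need at least one dose time")
        if not np.all(np.diff(dose_times) > 0):
            raise ValueError("dose times must be strictly increasing")
        if self.delta_t is not None and not (self.delta_t > 0):
            raise ValueError("delta_t must be positive when set")
        # the last pre-treatment observation V(1-) is taken at t1 itself,
        # immediately before the first dose, so equality is allowed
        if len(pre) and not np.all(pre <= dose_times[0]):
            raise ValueError("pre-treatment observations must precede the first dose")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-dose interval lengths t2-t1, t3-t2, ..."""
        if len(self.dose_times) >= 2:
            return np.diff(self.dose_times)
        if self.delta_t is None:
            raise ValueError("single dose time and no delta_t: intervals unknown")
        return np.array([self.delta_t])


@dataclass(frozen=True)
class FractionRecord:
    """Per-interval therapy bookkeeping derived from pre-dose volumes.

    post_dose_volumes (V(n+), immediately after each dose) may be
    recorded when measured but enter no computation.
    """

    pre_dose_volumes: np.ndarray
    rt: np.ndarray
    rt_tot: float
    rg: np.ndarray
    th: np.ndarray
    post_dose_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.pre_dose_volumes, dtype=float)
        object.__setattr__(self, "pre_dose_volumes", v)
        object.__setattr__(self, "rt", np.asarray(self.rt, dtype=float))
        object.__setattr__(self, "rg", np.asarray(self.rg, dtype=float))
        object.__setattr__(self, "th", np.asarray(self.th, dtype=float))
        if not np.all(v > 0):
            raise ValueError("pre-dose volumes must be positive")
        if not np.all(self.th > 0):
            raise ValueError("TH factors must be positive")
        ratios = v[1:] / v[:-1]
        if not np.allclose(ratios, self.rg * self.th, rtol=0, atol=1e-10):
            raise ValueError("RG*TH does not reproduce the volume ratios")


def _intervals(dt: float | Sequence[float], n: int) -> np.ndarray:
    """Normalise a scalar or per-interval dt to an array of n lengths."""
    arr = np.asarray(dt, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if len(arr) != n:
        raise ValueError(f"expected {n} interval lengths, got {len(arr)}")
    if not np.all(arr > 0):
        raise ValueError("interval lengths must be positive")
    return arr


def step_forward(
    V_prev: float, gp: GompertzParams, dt: float, rt: float
) -> float:
    """One inter-dose step: Gompertz regrowth over dt minus log-reduction rt."""
    if V_prev <= 0:
        raise ValueError("V_prev must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    growth = math.log(gp.V_inf / V_prev) * (1.0 - math.exp(-gp.k * dt))
    return V_prev * math.exp(growth - rt)


def estimate_rt_series(
    volumes: Sequence[float], gp: GompertzParams, dt: float | Sequence[float]
) -> np.ndarray:
    """Invert consecutive pre-dose volumes into per-fraction effects RT(n).

    RT(n) = ln(V(n-)/V(n+1-)) + ln(V_inf/V(n-)) (1 - e^{-k dt_n});
    exact round-trip with step_forward by construction.  Untreated
    Gompertz volumes yield RT identically zero.
    """
    v = np.asarray(volumes, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two pre-dose volumes")
    if not np.all(v > 0):
        raise ValueError("volumes must be positive")
    dts = _intervals(dt, len(v) - 1)
    growth = np.log(gp.V_inf / v[:-1]) * (1.0 - np.exp(-gp.k * dts))
    return np.log(v[:-1] / v[1:]) + growth


def cumulative_rt(
    rt: Sequence[float], k: float, dt: float | Sequence[float], n: int
) -> float:
    """Discounted cumulative effect RTtot(n) after n doses.

    RTtot(n) = sum_{m=1}^{n-1} RT(m) e^{-k dt (n-(m+1))} for a fixed
    interval; with per-interval lengths the discount for RT(m) is
    e^{-k (t_n - t_{m+1})}.  n = 2 reduces to RT(1).
    """
    rt = np.asarray(rt, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2 (RTtot is defined after the first interval)")
    if n > len(rt) + 1:
        raise ValueError(f"n={n} needs {n - 1} RT values, got {len(rt)}")
    dts = _intervals(dt, n - 1)
    # lag from the end of interval m (time t_{m+1}) to t_n
    times = np.concatenate([[0.0], np.cumsum(dts)])  # t_1..t_n relative to t_1
    lags = times[-1] - times[1:n]
    return float(np.sum(rt[: n - 1] * np.exp(-k * lags)))


def regression_condition(
    gp: GompertzParams,
    V1: float,
    rt: Sequence[float],
    n: int,
    dt: float | Sequence[float],
) -> bool:
    """True iff V(n-) < V(1-): cumulative therapy beats untreated regrowth.

    Strict inequality: equality of the growth term and RTtot is not a
    regression.
    """
    if V1 <= 0:
        raise ValueError("V1 must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    dts = _intervals(dt, n - 1)
    total_span = float(np.sum(dts))
    growth = math.log(gp.V_inf / V1) * (1.0 - math.exp(-gp.k * total_span))
    return growth < cumulative_rt(rt, gp.k, dts, n)


def decompose_interval(
    V_prev: float, V_next: float, gp: GompertzParams, dt: float
) -> tuple[float, float]:
    """Split one inter-dose ratio into (RG, TH) with V_next/V_prev = RG*TH.

    RG = exp[ln(V_inf/V_prev)(1-e^{-k dt})] is the untreated regrowth
    factor (>= 1 below saturation); TH = e^{-RT} < 1 quantifies the net
    cell-killing over the interval.  The identity RG*TH = V_next/V_prev
    holds exactly.
    """
    if V_prev <= 0 or V_next <= 0:
        raise ValueError("volumes must be positive")
    rg = math.exp(math.log(gp.V_inf / V_prev) * (1.0 - math.exp(-gp.k * dt)))
    th = (V_next / V_prev) / rg
    return rg, th


@dataclass(frozen=True)
class NextDosePrediction:
    """Outcome of the next-dose decision rule."""

    regression_expected: bool
    extrapolated_rt: float
    growth_term: float
    rt_tot: float


def predict_next_dose(
    gp: GompertzParams,
    V1: float,
    rt_history: Sequence[float],
    dt: float,
    *,
    extrapolation: str = "linear",
) -> NextDosePrediction:
    """Decide whether the next dose should push the volume below V(1-).

    The next per-fraction effect is extrapolated from the observed RT
    series (default: ordinary least squares of RT(m) on the dose index
    m, i.e. continue the linear trend; "carry_forward" repeats the last
    value).  The regression condition is then evaluated with the
    extended, kernel-discounted sum — with three observed values this is
    the four-term sum RT(1)e^{-3k dt} + RT(2)e^{-2k dt}
    + RT(3)e^{-k dt} + RT(4) against ln(V_inf/V(1-))(1 - e^{-4k dt}).
    """
    rt_history = np.asarray(rt_history, dtype=float)
    if len(rt_history) < 2:
        raise ValueError("need at least two observed RT values to extrapolate")
    m = np.arange(1, len(rt_history) + 1, dtype=float)
    if extrapolation == "linear":
        slope, intercept = np.polyfit(m, rt_history, 1)
        rt_next = float(slope * (len(rt_history) + 1) + intercept)
    elif extrapolation == "carry_forward":
        rt_next = float(rt_history[-1])
    else:
        raise ValueError(f"unknown extrapolation rule {extrapolation!r}")
    rt_ext = np.append(rt_history, rt_next)
    n = len(rt_ext) + 1
    growth = math.log(gp.V_inf / V1) * (1.0 - math.exp(-gp.k * (n - 1) * dt))
    rt_tot = cumulative_rt(rt_ext, gp.k, dt, n)
    return NextDosePrediction(
        regression_expected=bool(growth < rt_tot),
        extrapolated_rt=rt_next,
        growth_term=growth,
        rt_tot=rt_tot,
    )


def analyze_fractions(
    volumes: Sequence[float],
    gp: GompertzParams,
    schedule: FractionSchedule,
) -> FractionRecord:
    """Full per-interval bookkeeping from observed pre-dose volumes."""
    v = np.asarray(volumes, dtype=float)
    if len(v) != len(schedule.dose_times):
        raise ValueError(
            f"{len(v)} volumes but {len(schedule.dose_times)} dose times"
        )
    dts = schedule.intervals[: len(v) - 1]
    rt = estimate_rt_series(v, gp, dts)
    rg = np.empty(len(v) - 1)
    th = np.empty(len(v) - 1)
    for i in range(len(v) - 1):
        rg[i], th[i] = decompose_interval(v[i], v[i + 1], gp, float(dts[i]))
    rt_tot = cumulative_rt(rt, gp.k, dts, len(v))
    return FractionRecord(
        pre_dose_volumes=v, rt=rt, rt_tot=rt_tot, rg=rg, th=th
    )
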