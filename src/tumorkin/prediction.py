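"""Post-therapy extrapolation and response classification.

Above the critical dose the monitored series shrinks monotonically and
can be fitted directly with effective Gompertz parameters; the evolution
after the end of therapy is then

    V(t)/V(te) = exp[ ln(V_inf_eff/V(te)) (1 - e^{-k_eff (t - te)}) ]

with te and V(te) the time and volume of the last observation used in
the fit.  The effective carrying capacity relative to V(te) — the CC
ratio — summarises the long-term outcome: much smaller than 1 means the
tumor keeps shrinking toward zero (CR-like), near 1 an equilibrium
plateau (PR-like), much larger than 1 rapid regrowth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import FitConfig, FitResult, fit_model, gompertz_ratio_model, residual_percent
from .growth import GompertzParams, VolumeTrajectory

__all__ = [
    "ClassThresholds",
    "ExtrapolationResult",
    "extrapolate",
    "classify_response",
    "truncated_fit_predict",
]


@dataclass(frozen=True)
class ClassThresholds:
    """CC-ratio cutpoints for the response classes.

    The boundaries between "very small", "close to V(te)" and "much
    larger" are inherently qualitative; these documented defaults
    (0.1 and 2.0) are configurable.
    """

    cr: float = 0.1
    regrowth: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.cr < self.regrowth):
            raise ValueError("need 0 < cr threshold < regrowth threshold")


@dataclass(frozen=True)
class ExtrapolationResult:
    """Forward curve from the end of therapy plus its classification."""

    te: float
    V_te: float
    eff: GompertzParams
    predicted: VolumeTrajectory
    response_class: str
    cc_ratio: float

    def __post_init__(self) -> None:
        if not (self.cc_ratio > 0):
            raise ValueError("cc_ratio must be positive")
        if self.predicted.times[0] != self.te:
            raise ValueError("predicted trajectory must start at te")


def extrapolate(
    eff: GompertzParams,
    te: float,
    V_te: float,
    horizon: float,
    *,
    n_points: int = 101,
) -> VolumeTrajectory:
    """Evaluate the effective-parameter forward curve on [te, horizon].

    eff.V_inf is the effective carrying capacity in the same units as
    V_te; the curve starts at V_te and saturates at eff.V_inf.  Requires
    k_eff > 0 — a non-positive effective rate is outside the regime this
    forward law describes.
    """
    if eff.k <= 0:
        raise ValueError(
            f"extrapolation requires k_eff > 0 (got {eff.k}); a non-positive "
            "rate is outside the saturating forward-curve regime"
        )
    if V_te <= 0:
        raise ValueError("V_te must be positive")
    if horizon <= te:
        raise ValueError("horizon must exceed te")
    t = np.linspace(te, horizon, n_points)
    lnr = math.log(eff.V_inf / V_te)
    v = V_te * np.exp(lnr * (1.0 - np.exp(-eff.k * (t - te))))
    return VolumeTrajectory(times=t, values=v, label="extrapolated")


def classify_response(
    cc_ratio: float, thresholds: ClassThresholds | None = None
) -> str:
    """Classify the long-term outcome from the CC ratio V_inf_eff / V(te)."""
    if cc_ratio <= 0:
        raise ValueError("cc_ratio must be positive")
    th = thresholds or ClassThresholds()
    if cc_ratio < th.cr:
        return "CR_LIKE"
    if cc_ratio <= th.regrowth:
        return "PR_LIKE"
    return "REGROWTH_RISK"


def truncated_fit_predict(
    traj: VolumeTrajectory,
    cutoff: float,
    cfg: FitConfig | None = None,
    *,
    thresholds: ClassThresholds | None = None,
    horizon: float | None = None,
) -> tuple[FitResult, ExtrapolationResult, dict[float, float]]:
    """Fit only the observations up to ``cutoff`` and predict the rest.

    Emulates the clinical situation where a decision must be taken from
    a truncated series: the effective Gompertz parameters are fitted to
    points with t <= cutoff, the forward curve is extrapolated, and each
    held-out observation is scored by its percent residual.  The
    returned FitResult additionally carries the chi2/dof of the *full*
    series evaluated under the truncated-fit parameters.
    """
    cfg = cfg or FitConfig()
    mask = traj.times <= cutoff
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 3:
        raise ValueError(f"need >= 3 points at or before the cutoff, got {n_in}")

    fit_traj = VolumeTrajectory(
        times=traj.times[mask], values=traj.values[mask],
        rel_error=traj.rel_error, label=traj.label,
    )
    fit = fit_model(fit_traj, gompertz_ratio_model, cfg)

    te = float(fit_traj.times[-1])
    V_te = float(fit_traj.values[-1])
    lnr, k = fit.params["log_vinf_ratio"], fit.params["k"]
    # effective params are anchored at the fitted model's baseline: the
    # first measured value under the normalise convention, exactly 1 when
    # the series already is a ratio curve
    V0 = float(fit_traj.values[0]) if cfg.normalize else 1.0
    V_inf_eff = V0 * math.exp(lnr)
    eff = GompertzParams(V0=V_te, V_inf=V_inf_eff, k=k, t0=te)

    end = horizon if horizon is not None else float(traj.times[-1])
    if end <= te:
        end = te + 1.0  # cutoff beyond the last point: nothing held out
    predicted = extrapolate(eff, te, V_te, end)

    cc_ratio = V_inf_eff / V_te
    result = ExtrapolationResult(
        te=te,
        V_te=V_te,
        eff=eff,
        predicted=predicted,
        response_class=classify_response(cc_ratio, thresholds),
        cc_ratio=cc_ratio,
    )

    # held-out percent residuals, model evaluated at the exact times
    residuals: dict[float, float] = {}
    t0_fit = float(fit_traj.times[0])
    for t_i, v_i in zip(traj.times[~mask], traj.values[~mask]):
        pred = V0 * math.exp(lnr * (1.0 - math.exp(-k * (t_i - t0_fit))))
        residuals[float(t_i)] = residual_percent(pred, float(v_i))

    # chi2 of the full series under the truncated-fit parameters,
    # computed in the same normalised space as fit_model's residual
    t_full = traj.times - traj.times[0]
    y_full = traj.values / (traj.values[0] if cfg.normalize else 1.0)
    sigma_full = cfg.rel_error * y_full
    model_full = np.exp(lnr * (1.0 - np.exp(-k * t_full)))
    chi2_full = float(np.sum(((model_full - y_full) / sigma_full) ** 2))
    dof_full = len(traj) - len([n for n in fit.params if n not in cfg.fixed])
    fit = FitResult(
        **{
            **fit.__dict__,
            "chi2": chi2_full,
            "dof": dof_full,
            "chi2_per_dof": chi2_full / dof_full if dof_full > 0 else None,
        }
    )
    if n_out == 0:
        assert not residuals
    return fit, result, residuals
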