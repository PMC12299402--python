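"""Shared chi-square minimisation engine for all trajectory fits.

Every model fit in the package minimises

    chi2 = sum_i ( (V_i - model(t_i)) / sigma_i )^2,       sigma_i = rel_error * V_i,

i.e. a relative (multiplicative) measurement-error model, the default
level being 2.5%.  One-SD parameter errors and the correlation matrix
come from the covariance at the optimum; a multistart loop over a small
grid of initial guesses guards against the flat exponential-regime
directions of the Gompertz objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .growth import VolumeTrajectory

__all__ = [
    "FitConfig",
    "FitResult",
    "TrajectoryModel",
    "gompertz_ratio_model",
    "exponential_model",
    "fit_model",
    "identifiability_check",
    "residual_percent",
]


@dataclass(frozen=True)
class FitConfig:
    """Configuration shared by all chi-square fits.

    rel_error   -- relative measurement SD used for the chi-square weights
                   (per-point sigma overrides it when the trajectory
                   carries its own error column).
    fixed       -- parameters clamped to a value (e.g. k = 0.0342 day^-1,
                   the average in-vivo rate, when the series is too short
                   to constrain k).
    bounds      -- per-parameter (lo, hi) intervals.
    multistart  -- explicit list of initial-guess dicts; defaults to the
                   model's own start grid.
    weighted    -- set False for an unweighted least-squares objective.
    normalize   -- divide the series by its first value before fitting
                   (the ratio convention for absolute-volume data); set
                   False when the data already are ratios, so the
                   baseline measurement's noise is not double-counted.
    """

    rel_error: float = 0.025
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    multistart: Sequence[Mapping[str, float]] | None = None
    seed: int = 0
    weighted: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (self.rel_error > 0):
            raise ValueError("rel_error must be positive")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} are not well-ordered: ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a chi-square fit: estimates, 1-SD errors, quality metrics."""

    params: dict[str, float]
    sd: dict[str, float]
    chi2: float
    dof: int
    chi2_per_dof: float | None
    corr: dict[str, dict[str, float]]
    mode: str = "FULL"
    model_name: str = ""
    n_points: int = 0

    def to_json(self, **kwargs) -> str:
        payload = {
            "model": self.model_name,
            "mode": self.mode,
            "params": self.params,
            "sd": self.sd,
            "chi2": self.chi2,
            "dof": self.dof,
            "chi2_per_dof": self.chi2_per_dof,
            "corr": self.corr,
            "n_points": self.n_points,
        }
        return json.dumps(payload, sort_keys=True, **kwargs)


class TrajectoryModel:
    """A named parametric family V(t; theta)/V(0) with a default start grid."""

    def __init__(self, name, param_names, func, starts, default_bounds=None):
        self.name = name
        self.param_names = tuple(param_names)
        self._func = func
        self._starts = [dict(s) for s in starts]
        self.default_bounds = dict(default_bounds or {})

    def __call__(self, params: Mapping[str, float], t: np.ndarray) -> np.ndarray:
        return self._func(params, np.asarray(t, dtype=float))

    def starts(self) -> list[dict[str, float]]:
        return [dict(s) for s in self._starts]


def _gompertz_ratio(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    return np.exp(p["log_vinf_ratio"] * (1.0 - np.exp(-p["k"] * t)))


def _exponential(p: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    return np.exp(p["g"] * t)


#: Gompertz ratio curve V(t)/V(0) = exp[lnr (1 - e^{-k t})] with
#: lnr = ln(V_inf/V(0)).  Start grid spans regressing (lnr<0) and growing
#: trajectories and slow-to-fast rates.
gompertz_ratio_model = TrajectoryModel(
    "gompertz_ratio",
    ("log_vinf_ratio", "k"),
    _gompertz_ratio,
    starts=[
        {"log_vinf_ratio": lnr, "k": k}
        for lnr in (math.log(0.2), 0.0, math.log(5.0))
        for k in (0.005, 0.03, 0.1)
    ],
    default_bounds={"k": (-1.0, 5.0), "log_vinf_ratio": (-50.0, 50.0)},
)

#: Degenerate early-time limit: V(t)/V(0) = exp(g t) with
#: g = ln(V_inf/V(0)) * k, the only combination identifiable when k*t << 1.
exponential_model = TrajectoryModel(
    "exponential",
    ("g",),
    _exponential,
    starts=[{"g": g} for g in (-0.05, -0.005, 0.005, 0.05)],
    default_bounds={"g": (-5.0, 5.0)},
)


def _sigma(traj: VolumeTrajectory, cfg: FitConfig) -> np.ndarray:
    if not cfg.weighted:
        return np.ones_like(traj.values)
    return cfg.rel_error * traj.values


def fit_model(
    traj: VolumeTrajectory,
    model: TrajectoryModel,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Fit a trajectory family by chi-square minimisation with multistart.

    Times are shifted so the model clock starts at the first observation
    and volumes are normalised to the first value, matching the ratio
    convention V(t)/V(0) of all model families.  Returns the best of the
    multistart optima with covariance-based 1-SD errors.
    """
    cfg = cfg or FitConfig()
    t = traj.times - traj.times[0]
    scale = traj.values[0] if cfg.normalize else 1.0
    y = traj.values / scale
    sigma = _sigma(traj, cfg) / scale

    free = [n for n in model.param_names if n not in cfg.fixed]
    if len(traj) < len(free):
        raise ValueError(
            f"{len(traj)} points cannot constrain {len(free)} free parameters"
        )

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        vals = {n: pars[n].value for n in model.param_names}
        return (model(vals, t) - y) / sigma

    starts = [dict(s) for s in (cfg.multistart or model.starts())]
    best = None
    failures: list[str] = []
    for start in starts:
        pars = lmfit.Parameters()
        for name in model.param_names:
            lo, hi = cfg.bounds.get(
                name, model.default_bounds.get(name, (-np.inf, np.inf))
            )
            if name in cfg.fixed:
                pars.add(name, value=cfg.fixed[name], vary=False)
            else:
                value = float(np.clip(start.get(name, 0.0), lo, hi))
                pars.add(name, value=value, min=lo, max=hi)
        try:
            # scale_covar=False: sigma_i is an absolute measurement model
            # (2.5% relative by default), so the covariance is not rescaled
            # by the reduced chi2 and SDs propagate rel_error linearly
            out = lmfit.minimize(
                residual, pars, method="leastsq", scale_covar=False,
                xtol=1e-12, ftol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            failures.append(f"start {start}: {exc}")
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError(
            "chi-square fit failed from every start:\n" + "\n".join(failures)
        )

    params = {n: float(best.params[n].value) for n in model.param_names}
    sd = {
        n: float(best.params[n].stderr) if best.params[n].stderr is not None else 0.0
        for n in model.param_names
    }
    corr: dict[str, dict[str, float]] = {}
    for a in free:
        row = {}
        for b in free:
            if a == b:
                row[b] = 1.0
            else:
                c = (best.params[a].correl or {}).get(b)
                row[b] = float(c) if c is not None and math.isfinite(c) else 0.0
        corr[a] = row

    dof = len(traj) - len(free)
    chi2 = float(best.chisqr)
    return FitResult(
        params=params,
        sd=sd,
        chi2=chi2,
        dof=dof,
        chi2_per_dof=chi2 / dof if dof > 0 else None,
        corr=corr,
        mode="FULL",
        model_name=model.name,
        n_points=len(traj),
    )


def identifiability_check(
    fr: FitResult,
    *,
    corr_threshold: float = 0.999,
    rel_sd_threshold: float = 1.0,
) -> str:
    """Diagnose whether a two-parameter Gompertz fit is actually identifiable.

    On early-time data (k * t_max << 1) the carrying-capacity ratio and k
    cannot be disentangled — only their product is determined and the
    curve degenerates to an exponential.  Returns "PRODUCT" when the free
    parameters are near-perfectly correlated (|corr| > 0.999) or any
    relative SD exceeds 1, else "FULL".  Single-parameter fits are FULL
    by construction.
    """
    free = list(fr.corr.keys())
    if len(free) < 2:
        return "FULL"
    for i, a in enumerate(free):
        for b in free[i + 1:]:
            if abs(fr.corr[a][b]) > corr_threshold:
                return "PRODUCT"
    for name in free:
        value, sd = fr.params[name], fr.sd[name]
        if sd == 0.0:
            # optimizer could not produce an error estimate: degenerate
            return "PRODUCT"
        if abs(value) > 0 and sd / abs(value) > rel_sd_threshold:
            return "PRODUCT"
        if value == 0 and sd > rel_sd_threshold:
            return "PRODUCT"
    return "FULL"


def residual_percent(predicted: float, observed: float) -> float:
    """Percent residual 100 |predicted - observed| / observed."""
    if observed <= 0:
        raise ValueError("observed must be positive")
    return 100.0 * abs(predicted - observed) / observed
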