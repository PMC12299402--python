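"""Synthetic trajectory generators.

Every pipeline stage is testable without external data: these helpers
sample the untreated Gompertz law, the single-dose FLASH closed form, or
a fractionated schedule with planted per-dose effects, and corrupt the
mean curve with multiplicative Gaussian measurement noise.

The noise model mirrors how the chi-square engine weighs data — an SD
proportional to the measured value, 2.5% by default, the level typical
of careful serial caliper / imaging measurements.  Draws are truncated
at -3 SD so generated volumes stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .flash import FlashParams, flash_volume
from .fractionation import FractionSchedule, step_forward
from .growth import (
    GompertzParams,
    TherapyFunction,
    VolumeTrajectory,
    gl_volume,
    therapy_integral,
    treated_volume,
)

__all__ = ["NoiseModel", "gen_gl", "gen_flash", "gen_fractionated"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, truncated at -3 SD."""

    rel_sd: float = 0.025
    seed: int = 0
    kind: str = "MULTIPLICATIVE_GAUSSIAN"

    def __post_init__(self) -> None:
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")
        if self.kind != "MULTIPLICATIVE_GAUSSIAN":
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.rel_sd == 0:
            return np.asarray(values, dtype=float).copy()
        rng = np.random.default_rng(self.seed)
        eps = rng.normal(0.0, self.rel_sd, size=len(values))
        eps = np.maximum(eps, -3.0 * self.rel_sd)
        return np.asarray(values, dtype=float) * (1.0 + eps)


def gen_gl(
    params: GompertzParams, times: Sequence[float], noise: NoiseModel | None = None
) -> VolumeTrajectory:
    """Sample noisy untreated Gompertz volumes at the given times."""
    noise = noise or NoiseModel(rel_sd=0.0)
    times = np.asarray(times, dtype=float)
    mean = gl_volume(params, times)
    return VolumeTrajectory(
        times=times,
        values=noise.apply(np.atleast_1d(mean)),
        rel_error=max(noise.rel_sd, 1e-6),
        label="synthetic_gl",
    )


def gen_flash(
    gp: GompertzParams,
    fp: FlashParams,
    times: Sequence[float],
    noise: NoiseModel | None = None,
) -> VolumeTrajectory:
    """Sample noisy single-dose volume ratios V(t)/V(0) from the closed form."""
    noise = noise or NoiseModel(rel_sd=0.0)
    times = np.asarray(times, dtype=float)
    mean = np.atleast_1d(flash_volume(gp, fp, times))
    return VolumeTrajectory(
        times=times,
        values=noise.apply(mean),
        rel_error=max(noise.rel_sd, 1e-6),
        label="synthetic_flash_ratio",
    )


def gen_fractionated(
    gp: GompertzParams,
    schedule: FractionSchedule,
    rt_true: Sequence[float] | None = None,
    F: TherapyFunction | None = None,
    noise: NoiseModel | None = None,
) -> tuple[VolumeTrajectory, np.ndarray]:
    """Pre-dose volume series with planted therapy effects.

    Either plant explicit per-fraction effects ``rt_true`` (iterated
    discrete stepping) or supply a kill-rate function ``F`` (exact
    kernel convolution); in the latter case the implied RT values

        RT(n) = int_{t_n}^{t_{n+1}} F(t') e^{-k (t_{n+1} - t')} dt'

    are returned as ground truth alongside the trajectory.
    """
    if (rt_true is None) == (F is None):
        raise ValueError("supply exactly one of rt_true or F")
    noise = noise or NoiseModel(rel_sd=0.0)
    t_dose = schedule.dose_times
    if F is not None:
        gp0 = GompertzParams(V0=gp.V0, V_inf=gp.V_inf, k=gp.k, t0=float(t_dose[0]))
        volumes = np.array([treated_volume(gp0, F, float(t)) for t in t_dose])
        rt_implied = np.empty(len(t_dose) - 1)
        for i in range(len(t_dose) - 1):
            shifted = GompertzParams(
                V0=gp.V0, V_inf=gp.V_inf, k=gp.k, t0=float(t_dose[i])
            )
            rt_implied[i] = therapy_integral(shifted, F, float(t_dose[i + 1]))
    else:
        rt_true = np.asarray(rt_true, dtype=float)
        if len(rt_true) != len(t_dose) - 1:
            raise ValueError(
                f"{len(t_dose)} dose times need {len(t_dose) - 1} planted RT values"
            )
        volumes = np.empty(len(t_dose))
        volumes[0] = gp.V0
        for i in range(len(t_dose) - 1):
            volumes[i + 1] = step_forward(
                volumes[i], gp, float(t_dose[i + 1] - t_dose[i]), float(rt_true[i])
            )
        rt_implied = rt_true.copy()
    traj = VolumeTrajectory(
        times=t_dose,
        values=noise.apply(volumes),
        rel_error=max(noise.rel_sd, 1e-6),
        label="synthetic_fractionated",
    )
    return traj, rt_implied
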