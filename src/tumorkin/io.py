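"""CSV/JSON readers and writers and the monitoring pipeline.

Trajectory CSV dialect: UTF-8, comma-separated, header
``time_day,volume[,rel_error]``; times in float days, volumes positive.
An SLD series (sum of longest diameters) is converted to relative volume
by cubing the normalised SLD, assuming spherical lesions.

``run_pipeline`` chains the full monitoring protocol: characterise
untreated growth from the pre-treatment observations, invert the
pre-dose volume series into per-fraction effects, check the regression
condition after each dose, and extrapolate the next-dose decision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitConfig, fit_model, gompertz_ratio_model
from .fractionation import (
    FractionSchedule,
    analyze_fractions,
    predict_next_dose,
    regression_condition,
)
from .growth import GompertzParams, VolumeTrajectory

__all__ = [
    "read_trajectory",
    "write_report",
    "read_gompertz_params",
    "RunConfig",
    "run_pipeline",
]

_HEADER = ("time_day", "volume")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


def read_trajectory(
    path: str | Path,
    *,
    observable: str = "volume",
    rel_error: float = 0.025,
) -> VolumeTrajectory:
    """Read a trajectory CSV, validating row by row.

    With ``observable="sld"`` the series is converted to relative volume
    by cubing the SLD normalised to its first value.  A third
    ``rel_error`` column, when present, overrides the default relative
    error (a single shared value is supported).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty input, no header") from None
    cols = list(df.columns)
    if cols[:2] != list(_HEADER):
        raise TrajectoryFormatError(
            f"{path}: expected header 'time_day,volume[,rel_error]', got {cols}"
        )
    if len(df) == 0:
        raise TrajectoryFormatError(f"{path}: empty input, no data rows")
    times = df["time_day"].to_numpy(dtype=float)
    values = df["volume"].to_numpy(dtype=float)
    for i in range(len(df)):
        line_no = i + 2  # header is line 1
        if not np.isfinite(times[i]) or not np.isfinite(values[i]):
            raise TrajectoryFormatError(f"{path}: non-numeric entry at line {line_no}")
        if values[i] <= 0:
            raise TrajectoryFormatError(
                f"{path}: non-positive volume {values[i]} at line {line_no}"
            )
        if i > 0 and times[i] <= times[i - 1]:
            raise TrajectoryFormatError(
                f"{path}: time not increasing at line {line_no} "
                f"({times[i]} after {times[i - 1]})"
            )
    if "rel_error" in df.columns:
        rels = df["rel_error"].to_numpy(dtype=float)
        if not np.all(rels > 0):
            raise TrajectoryFormatError(f"{path}: rel_error entries must be positive")
        rel_error = float(rels[0])
    label = observable
    if observable == "sld":
        values = (values / values[0]) ** 3
        label = "volume_from_sld"
    elif observable != "volume":
        raise ValueError(f"unknown observable {observable!r}")
    return VolumeTrajectory(
        times=times, values=values, rel_error=rel_error, label=label
    )


def write_trajectory(traj: VolumeTrajectory, path: str | Path) -> None:
    """Write a trajectory in the canonical CSV dialect (full precision)."""
    df = pd.DataFrame({"time_day": traj.times, "volume": traj.values})
    df["rel_error"] = traj.rel_error
    df.to_csv(path, index=False, float_format="%.17g")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(result: Any, path: str | Path) -> None:
    """Serialise any result object/dict to a sorted-key JSON report."""
    payload = _jsonable(result)
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


def read_gompertz_params(path: str | Path) -> GompertzParams:
    """Read growth parameters from JSON with keys V0, V_inf, k, t0."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return GompertzParams(
        V0=data["V0"], V_inf=data["V_inf"], k=data["k"], t0=data.get("t0", 0.0)
    )


@dataclass(frozen=True)
class RunConfig:
    """Inputs of the end-to-end monitoring pipeline.

    pre_treatment: untreated observations (diagnosis through the first
    dose) used to fit the Gompertz parameters; pre_dose_volumes: the
    series V(1-), V(2-), ... at the dose times.
    """

    pre_treatment: VolumeTrajectory
    pre_dose_times: np.ndarray
    pre_dose_volumes: np.ndarray
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    input_paths: tuple[str, ...] = ()


def _hash_inputs(paths: tuple[str, ...]) -> dict[str, str]:
    out = {}
    for p in paths:
        out[p] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Control fit -> per-dose RT estimation -> regression checks -> prediction.

    Returns a deterministic, JSON-ready report with stage-level status;
    a failing stage leaves a partial report rather than raising.
    """
    report: dict[str, Any] = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "input_hashes": _hash_inputs(config.input_paths),
        },
        "stages": {},
    }

    # stage 1: untreated growth from pre-treatment observations
    try:
        fit = fit_model(config.pre_treatment, gompertz_ratio_model, config.fit)
        lnr, k = fit.params["log_vinf_ratio"], fit.params["k"]
        V0 = float(config.pre_treatment.values[0])
        gp = GompertzParams(
            V0=V0,
            V_inf=V0 * float(np.exp(lnr)),
            k=k,
            t0=float(config.pre_treatment.times[0]),
        )
        report["stages"]["growth_fit"] = {
            "status": "ok",
            "params": fit.params,
            "sd": fit.sd,
            "chi2_per_dof": fit.chi2_per_dof,
        }
    except Exception as exc:
        report["stages"]["growth_fit"] = {"status": "failed", "error": str(exc)}
        return report

    # stage 2: per-fraction effects and RG/TH decomposition
    try:
        schedule = FractionSchedule(
            dose_times=config.pre_dose_times,
            pre_treatment_times=config.pre_treatment.times,
        )
        record = analyze_fractions(config.pre_dose_volumes, gp, schedule)
        report["stages"]["fractions"] = {
            "status": "ok",
            "rt": record.rt.tolist(),
            "rt_tot": record.rt_tot,
            "rg": record.rg.tolist(),
            "th": record.th.tolist(),
        }
    except Exception as exc:
        report["stages"]["fractions"] = {"status": "failed", "error": str(exc)}
        return report

    # stage 3: regression condition after each dose
    try:
        V1 = float(config.pre_dose_volumes[0])
        dts = np.diff(config.pre_dose_times)
        flags = [
            regression_condition(gp, V1, record.rt, n, dts[: n - 1])
            for n in range(2, len(config.pre_dose_volumes) + 1)
        ]
        report["stages"]["regression"] = {
            "status": "ok",
            "regression_after_dose": {str(n): bool(f) for n, f in
                                      zip(range(2, len(flags) + 2), flags)},
        }
    except Exception as exc:
        report["stages"]["regression"] = {"status": "failed", "error": str(exc)}
        return report

    # stage 4: next-dose decision (needs a regular schedule and >= 2 RT)
    try:
        if len(record.rt) >= 2:
            dt = float(np.mean(dts))
            pred = predict_next_dose(gp, V1, record.rt, dt)
            report["stages"]["next_dose"] = {
                "status": "ok",
                "regression_expected": pred.regression_expected,
                "extrapolated_rt": pred.extrapolated_rt,
            }
        else:
            report["stages"]["next_dose"] = {
                "status": "skipped",
                "reason": "fewer than two observed RT values",
            }
    except Exception as exc:
        report["stages"]["next_dose"] = {"status": "failed", "error": str(exc)}
    return report
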