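"""Packaged reference constants.

Fitted model parameters published for the in-vivo cohorts the framework
was calibrated on (lung-CSC conventional radiotherapy, FLASH vs
conventional single-dose response, colorectal neoadjuvant therapy,
renal-carcinoma everolimus monitoring).  Values are stored verbatim in
``data/reference_values.json`` and exposed here as typed objects so
tests and examples never hard-code them.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources
from typing import Any

from .dose_response import DoseLaw, EffectiveDoseFit
from .flash import FlashDoseLaw, FlashParams

__all__ = [
    "load_raw",
    "data_sha256",
    "flash_params",
    "flash_fit_labels",
    "flash_dose_law",
    "cell_line_labels",
    "cell_line_dose_values",
    "cell_line_fits",
    "cell_line_law",
    "patient_intervals",
    "th_critical",
    "colorectal_effective_params",
    "k_in_vivo",
    "everolimus_dose_slopes",
]

_DATA = resources.files("tumorkin.data").joinpath("reference_values.json")


@lru_cache(maxsize=1)
def load_raw() -> dict[str, Any]:
    """The raw reference-constant dictionary (immutable by convention)."""
    return json.loads(_DATA.read_text(encoding="utf-8"))


def data_sha256() -> str:
    """Checksum of the packaged constants file, for integrity tests."""
    return hashlib.sha256(_DATA.read_bytes()).hexdigest()


def flash_fit_labels() -> list[str]:
    return list(load_raw()["flash_fits"].keys())


def flash_params(label: str) -> FlashParams:
    """Kill-rate coefficients fitted to one dose arm, e.g. '20_gy_flash'."""
    row = load_raw()["flash_fits"][label]
    return FlashParams(
        c0=row["c0_per_day"],
        c1=row["c1_per_day"],
        c2=row["c2_per_day"],
        cf=row["cf_per_day2"],
    )


def flash_param_sd(label: str) -> dict[str, float]:
    row = load_raw()["flash_fits"][label]
    return {p: row[f"{p}_sd"] for p in ("c0", "c1", "c2", "cf")}


def flash_dose_law() -> FlashDoseLaw:
    """The fitted dose dependence of the late-time coefficient cf."""
    row = load_raw()["flash_cf_dose_law"]
    return FlashDoseLaw(
        a=row["a_per_day2"],
        b=row["b_per_day2_per_gy_p"],
        d_ref=row["d_ref_gy"],
        p=row["p"],
    )


def cell_line_labels() -> list[str]:
    return list(load_raw()["cell_line_dose_response"].keys())


def cell_line_dose_values(line: str) -> dict[float, float]:
    """Per-dose effective-parameter estimates for one cell line."""
    row = load_raw()["cell_line_dose_response"][line]
    return {float(d): v for d, v in row["values"].items()}


def cell_line_fits(line: str) -> list[EffectiveDoseFit]:
    """Per-dose estimates wrapped as EffectiveDoseFit records."""
    row = load_raw()["cell_line_dose_response"][line]
    fits = []
    for d, v in cell_line_dose_values(line).items():
        if row["observable"] == "CC_RATIO":
            # k is not tabulated for the CC observable; carry the ratio only
            fits.append(
                EffectiveDoseFit(d=d, mode="FULL", V_inf_ratio=v, k_d=float("nan"))
            )
        else:
            fits.append(EffectiveDoseFit(d=d, mode="PRODUCT", g_d=v))
    return fits


def cell_line_law(line: str) -> DoseLaw | None:
    """The published power-law constants for one cell line, or None."""
    row = load_raw()["cell_line_dose_response"][line]
    if row["c"] is None:
        return None
    baseline = cell_line_dose_values(line)[0.0]
    return DoseLaw(
        observable=row["observable"], baseline=baseline, c=row["c"], lam=row["lam"]
    )


def patient_intervals() -> dict[str, dict[str, list[float | None]]]:
    """Per-patient inter-dose volume ratios and their RG/TH decomposition."""
    return load_raw()["patient_intervals"]


def th_critical() -> dict[str, float]:
    """Patient-specific TH threshold below which therapy wins over regrowth."""
    return load_raw()["th_critical"]


def colorectal_effective_params(which: str = "during_therapy") -> dict[str, float]:
    """Effective (log-ratio, k) pairs for the neoadjuvant colorectal series."""
    return load_raw()["colorectal_effective_fits"][which]


def k_in_vivo() -> float:
    """Average in-vivo Gompertz rate (day^-1), used as a fixed-k option."""
    return load_raw()["k_in_vivo_per_day"]


def everolimus_dose_slopes() -> tuple[list[float], list[float]]:
    """(doses in mg, fitted log-size slopes in day^-1) for the dose-change patient."""
    row = load_raw()["everolimus_dose_slopes"]
    return list(row["doses_mg"]), list(row["slopes_per_day"])
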