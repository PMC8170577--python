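"""Packaged registry tables for the external-validation workflow.

Three small CSVs ship with the package:

* ``baseline_bmi_groups.csv`` — baseline characteristics of the five
  BMI groups of the UK primary/secondary-care registry cohort (normal
  weight 18.5-24.9 kg/m2 is the reference group);
* ``cox_hazard_ratios.csv`` — Cox proportional hazard ratios per BMI
  group for UA/MI, stroke/TIA, incident T2D and all-cause mortality;
* ``observed_vs_predicted_rates.csv`` — observed (Cox-adjusted) event
  rates per 1000 patient-years versus the published model predictions,
  for the base case and the prediabetes-prevalence scenario.

Each file is integrity-checked against a frozen SHA-256 on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .config import CohortProfile
from .risk import HazardRatioTable

__all__ = [
    "BMI_GROUPS",
    "GROUP_MEAN_BMI",
    "HSE_SCENARIO_SPLIT",
    "load_baseline_groups",
    "load_hazard_ratios",
    "load_rate_table",
    "observed_rates",
    "predicted_rates",
    "group_profile",
    "validation_profile",
    "fixture_tables",
]

#: Ordered BMI-group labels (kg/m2); the first is the reference group.
BMI_GROUPS = ("18.5-24.9", "25.0-29.9", "30.0-34.9", "35.0-39.9", "40.0-44.9")

#: Prediabetes-prevalence scenario split (no dysglycemia, prediabetes,
#: T2D) from the 2011 Health Survey for England normal-weight stratum;
#: baseline T2D prevalence is unchanged.
HSE_SCENARIO_SPLIT = (0.714, 0.259, 0.027)

_CHECKSUMS = {
    "baseline_bmi_groups.csv": "c066ad1650e5f43f289305a142b27e555bd917680133c8e369bcb77be8bd5d6c",
    "cox_hazard_ratios.csv": "28ca53e62009091b66ca8a7e0658c449b36373c232415bc2e1f7761f579a9ec8",
    "observed_vs_predicted_rates.csv": "1f04cf8e8dbac0bdb797e7f5d686881baa35151ade6a97e8c77d8fb64014c253",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("obesim.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"packaged table {name} failed its integrity check "
            f"(sha256 {digest} != {_CHECKSUMS[name]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_baseline_groups() -> pd.DataFrame:
    """Baseline characteristics, one row per BMI group."""
    return _read("baseline_bmi_groups.csv")


def load_hazard_ratios() -> dict[str, HazardRatioTable]:
    """Cox HR tables keyed by outcome (uami, stroke_tia, t2d, mortality)."""
    df = _read("cox_hazard_ratios.csv")
    return {
        outcome: HazardRatioTable.from_frame(df, outcome)
        for outcome in df["outcome"].unique()
    }


def load_rate_table() -> pd.DataFrame:
    """Observed and published-model predicted rates, tidy format."""
    return _read("observed_vs_predicted_rates.csv")


GROUP_MEAN_BMI = dict(
    zip(BMI_GROUPS, (22.5, 27.3, 32.1, 37.0, 42.3))
)


def _series(df: pd.DataFrame, outcome: str, series: str) -> np.ndarray:
    sub = df[(df["outcome"] == outcome) & (df["series"] == series)]
    if len(sub) != len(BMI_GROUPS):
        raise KeyError(f"no rate series '{series}' for outcome '{outcome}'")
    ordered = sub.set_index("group").loc[list(BMI_GROUPS), "rate"]
    return ordered.to_numpy(dtype=float)


def observed_rates(outcome: str) -> np.ndarray:
    """Observed (Cox-adjusted) rates per 1000 PY across the five groups."""
    return _series(load_rate_table(), outcome, "observed")


def predicted_rates(outcome: str, series: str = "com8_base") -> np.ndarray:
    """Published model predictions: series com8_base / com8_scenario / com61_base."""
    return _series(load_rate_table(), outcome, series)


def _profile_from_row(row: pd.Series, n: float) -> CohortProfile:
    return CohortProfile(
        n=n,
        age=row["age_years"],
        bmi=row["bmi"],
        sex_share_women=row["women_pct"] / 100.0,
        height_cm=row["height_m"] * 100.0,
        sbp=row["sbp_mmhg"],
        total_chol=row["total_chol_mgdl"],
        hdl_chol=row["hdl_mgdl"],
        hba1c_pct=row["hba1c_pct"],
        t2d_duration=row["t2d_duration_years"],
        triglycerides=row["triglycerides_mgdl"],
        share_tg_ge_150=row["tg_ge_150_pct"] / 100.0,
        share_smokers=row["smoking_pct"] / 100.0,
        share_antihypertensive=row["antihypertensive_pct"] / 100.0,
        share_lipid_lowering=row["lipid_lowering_pct"] / 100.0,
        share_no_dysglycemia=row["no_dysglycemia_pct"] / 100.0,
        share_prediabetes=row["prediabetes_pct"] / 100.0,
        share_t2d=row["t2d_pct"] / 100.0,
    )


def group_profile(group: str, n: float = 100.0) -> CohortProfile:
    """Cohort profile of one BMI group, using that group's own characteristics."""
    df = load_baseline_groups().set_index("group")
    if group not in df.index:
        raise KeyError(f"unknown BMI group '{group}'; expected one of {BMI_GROUPS}")
    return _profile_from_row(df.loc[group], n)


def validation_profile(
    group: str, scenario: str = "base", n: float = 100.0
) -> CohortProfile:
    """Cohort used in the comparative analysis for one BMI group.

    The reference group's baseline characteristics are kept and only the
    mean BMI is swapped to the simulated group's value; the glycemic
    split is the reference group's (base) or the survey-based
    prediabetes-adjusted split (``"hse-prediabetes"``).
    """
    if group not in BMI_GROUPS:
        raise KeyError(f"unknown BMI group '{group}'; expected one of {BMI_GROUPS}")
    ref = group_profile(BMI_GROUPS[0], n=n)
    update: dict = {"bmi": GROUP_MEAN_BMI[group]}
    if scenario in ("hse-prediabetes", "prediabetes_adjusted", "scenario"):
        ngt, pre, t2d = HSE_SCENARIO_SPLIT
        update |= {
            "share_no_dysglycemia": ngt,
            "share_prediabetes": pre,
            "share_t2d": t2d,
        }
    elif scenario != "base":
        raise ValueError(f"unknown scenario '{scenario}'")
    return ref.model_copy(update=update)


def fixture_tables() -> dict:
    """All packaged tables as typed objects (checksummed on read)."""
    return {
        "baseline_groups": load_baseline_groups(),
        "hazard_ratios": load_hazard_ratios(),
        "rates": load_rate_table(),
    }
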