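"""Thermophysiological and lactational performance arithmetic.

Covers the derived quantities around the study's performance table: the
NRC-1971 dry-bulb temperature-humidity index, fat-corrected milk, balanced
crossover treatment means (equal to least-squares means in a balanced
design) and the headline treatment contrasts (differences, ratios, percent
changes).  The full repeated-measures mixed model is deliberately not
reimplemented; in the balanced crossover the plain treatment means already
reproduce the published least-squares means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "THI_FORMULA",
    "TABLE1_MEANS",
    "thi",
    "fcm",
    "crossover_means",
    "derived_changes",
    "headline_quantities",
]

#: Which THI variant :func:`thi` evaluates.  NRC 1971 lists several
#: (dry-bulb, wet-bulb, dew-point based); this is the dry-bulb/relative-
#: humidity approximation.
THI_FORMULA = "NRC-1971 dry-bulb: (1.8*T + 32) - (0.55 - 0.0055*RH)*(1.8*T - 26)"

#: Published treatment least-squares means of the performance table
#: (thermoneutral TN vs heat stress HS).  Units: temperatures degC,
#: respiratory rates breaths/min, intakes kg/d or L/d, weights kg,
#: yields L/d, milk composition %.
TABLE1_MEANS: dict[str, tuple[float, float]] = {
    "rectal_temp_0800": (38.5, 39.1),
    "rectal_temp_1200": (38.7, 39.7),
    "rectal_temp_1700": (38.7, 39.9),
    "resp_rate_0800": (27.0, 69.0),
    "resp_rate_1200": (39.0, 131.0),
    "resp_rate_1700": (37.0, 130.0),
    "dmi": (2.26, 1.47),
    "water": (6.1, 10.6),
    "final_body_weight": (48.6, 39.8),
    "body_weight_variation": (3.5, -2.1),
    "milk_yield": (1.88, 1.79),
    "fcm_yield": (2.17, 1.86),
    "fat": (3.98, 3.64),
    "protein": (3.40, 2.85),
    "lactose": (4.51, 4.30),
}


def thi(t_db, rh):
    """Temperature-humidity index from dry-bulb temperature (degC) and
    relative humidity (%), NRC-1971 dry-bulb approximation.

    THI = (1.8*T + 32) - (0.55 - 0.0055*RH) * (1.8*T - 26)
    """
    t_db = np.asarray(t_db, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise InvalidInputError("relative humidity must be in [0, 100]%")
    out = (1.8 * t_db + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t_db - 26.0)
    return float(out) if out.ndim == 0 else out


def fcm(liters, fat_pct):
    """Fat-corrected milk (3.5% reference): FCM = L * (0.432 + 0.162 * fat%)."""
    liters = np.asarray(liters, dtype=float)
    fat_pct = np.asarray(fat_pct, dtype=float)
    if np.any(liters < 0) or np.any(fat_pct < 0):
        raise InvalidInputError("milk volume and fat % must be non-negative")
    out = liters * (0.432 + 0.162 * fat_pct)
    return float(out) if out.ndim == 0 else out


def crossover_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable treatment means over animal x period cells.

    ``records`` is tidy: columns animal_id, period, treatment, variable,
    value (a ``day`` column, if present, is averaged out first).  In a
    balanced crossover these means equal the least-squares means.  An
    unbalanced design triggers a warning and a ``balanced=False`` flag.
    """
    required = {"animal_id", "treatment", "variable", "value"}
    missing = required - set(records.columns)
    if missing:
        raise InvalidInputError(f"records missing columns {sorted(missing)}")
    rows = []
    for var, grp in records.groupby("variable", sort=True):
        cell = grp.groupby(["animal_id", "treatment"])["value"].mean().unstack()
        balanced = (
            set(cell.columns) == {"TN", "HS"} and not cell.isna().any().any()
        )
        if not balanced:
            warnings.warn(
                f"{var}: unbalanced crossover; reporting simple means",
                stacklevel=2,
            )
        tn = float(grp.loc[grp["treatment"] == "TN", "value"].mean())
        hs = float(grp.loc[grp["treatment"] == "HS", "value"].mean())
        rows.append(
            {
                "variable": var,
                "tn_mean": tn,
                "hs_mean": hs,
                "difference": hs - tn,
                "percent_change": (hs - tn) / tn * 100.0,
                "ratio": hs / tn,
                "balanced": balanced,
            }
        )
    return pd.DataFrame(rows)


def derived_changes(means: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Differences, ratios and percent changes from (TN, HS) mean pairs."""
    means = TABLE1_MEANS if means is None else means
    rows = []
    for var, (tn, hs) in means.items():
        rows.append(
            {
                "variable": var,
                "tn_mean": tn,
                "hs_mean": hs,
                "difference": hs - tn,
                "percent_change": (hs - tn) / tn * 100.0,
                "ratio": hs / tn,
            }
        )
    return pd.DataFrame(rows)


def headline_quantities(means: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
    """The headline treatment contrasts, rounded to reporting precision
    (temperatures and ratios to 0.1, percent changes to the integer).
    """
    d = derived_changes(means).set_index("variable")
    return {
        "rectal_temp_rise_1700_c": round(float(d.loc["rectal_temp_1700", "difference"]), 1),
        "resp_rate_ratio_1700": round(float(d.loc["resp_rate_1700", "ratio"]), 1),
        "dmi_change_pct": round(float(d.loc["dmi", "percent_change"])),
        "water_change_pct": round(float(d.loc["water", "percent_change"])),
        "fat_change_pct": round(float(d.loc["fat", "percent_change"])),
        "protein_change_pct": round(float(d.loc["protein", "percent_change"])),
        "lactose_change_pct": round(float(d.loc["lactose", "percent_change"])),
        "fcm_change_pct": round(float(d.loc["fcm_yield", "percent_change"])),
    }
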