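"""Volcano screen: per-bin paired fold change and paired t-test between the
HS and TN samples of each animal, with Benjamini-Hochberg FDR control.

A bin is flagged significant only when all three conditions hold:
|log2 fold change| >= 1.5, raw paired-t P < 0.01, and BH-adjusted P < 0.05.
Fold changes are reported both as mean log2 differences (HS - TN) and on
the signed-ratio convention (2^|mean log2 diff| carrying the sign of the
mean: negative values mean higher excretion under TN).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, InsufficientDataError, InvalidInputError
from .preprocess import FeatureMatrix

__all__ = ["paired_differences", "paired_t_test", "bh_adjust", "volcano"]


def paired_differences(X: FeatureMatrix) -> pd.DataFrame:
    """Per-animal HS - TN differences (log2 scale): one row per animal."""
    design = X.design
    rows = []
    animals = []
    for animal, grp in design.groupby("animal_id", sort=True):
        trts = sorted(grp["treatment"])
        if trts != ["HS", "TN"]:
            raise DesignError(
                f"animal {animal} is not paired (treatments {list(grp['treatment'])})"
            )
        hs_id = grp.loc[grp["treatment"] == "HS", "sample_id"].iloc[0]
        tn_id = grp.loc[grp["treatment"] == "TN", "sample_id"].iloc[0]
        rows.append(X.values.loc[hs_id] - X.values.loc[tn_id])
        animals.append(animal)
    return pd.DataFrame(rows, index=pd.Index(animals, name="animal_id"))


def paired_t_test(diffs: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Two-sided one-sample t on per-animal differences vs 0 (df = n - 1).

    Zero-variance bins get p = 1 with a warning rather than an error.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    n = d.shape[0]
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 animals")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} bins have zero difference variance; p set to 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = 1.0
    return p


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in
    the original order.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError("p_raw must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def volcano(
    X: FeatureMatrix,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-bin volcano table over the retained bins.

    Columns: ppm, log2fc (mean HS - TN log2 difference), fc_signed
    (signed-ratio convention), p_raw, p_bh, significant.  ``fc_threshold``
    applies to |log2fc|.
    """
    diffs = paired_differences(X)
    log2fc = diffs.to_numpy().mean(axis=0)
    p_raw = paired_t_test(diffs)
    p_bh = bh_adjust(p_raw)
    fc_signed = np.sign(log2fc) * 2.0 ** np.abs(log2fc)
    fc_signed[log2fc == 0] = 1.0
    significant = (
        (np.abs(log2fc) >= fc_threshold)
        & (p_raw < p_threshold)
        & (p_bh < fdr_threshold)
    )
    return pd.DataFrame(
        {
            "ppm": X.bin_centers,
            "log2fc": log2fc,
            "fc_signed": fc_signed,
            "p_raw": p_raw,
            "p_bh": p_bh,
            "significant": significant,
        }
    )
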