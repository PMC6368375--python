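"""Chemical-shift assignment of selected bins against the packaged library.

A bin matches every library resonance within ``tolerance`` ppm of its
center; overlapping candidates (e.g. trimethylamine N-oxide at 3.27 vs
histamine at 3.28) are all reported, ordered by |delta ppm|, never silently
resolved.  A metabolite counts as "supported" when at least a configurable
fraction (default half) of its library resonances are matched by
significant bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidParameterError
from .library import MetaboliteLibrary

__all__ = ["assign_shifts", "supported_metabolites"]


def assign_shifts(
    bins,
    lib: MetaboliteLibrary,
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Match query ppm positions against library shifts.

    Returns one row per (bin, matching resonance), ordered within each bin
    by |delta ppm|; unmatched bins appear once with a null metabolite.
    """
    if tolerance <= 0:
        raise InvalidParameterError("tolerance must be positive")
    if len(lib) == 0:
        raise ConfigurationError("empty metabolite library")
    rows = []
    for b in np.atleast_1d(np.asarray(bins, dtype=float)):
        matches = []
        for entry, shift, _amp in lib.iter_peaks():
            delta = abs(b - shift)
            if delta <= tolerance:
                matches.append(
                    {
                        "bin_ppm": b,
                        "metabolite": entry.name,
                        "pathway": entry.pathway,
                        "library_shift": shift,
                        "delta_ppm": delta,
                    }
                )
        if matches:
            rows.extend(sorted(matches, key=lambda r: r["delta_ppm"]))
        else:
            rows.append(
                {
                    "bin_ppm": b,
                    "metabolite": None,
                    "pathway": None,
                    "library_shift": np.nan,
                    "delta_ppm": np.nan,
                }
            )
    return pd.DataFrame(rows)


def supported_metabolites(
    significant_bins: pd.DataFrame,
    lib: MetaboliteLibrary,
    tolerance: float = 0.01,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Summarise library metabolites by how many of their resonances are hit.

    ``significant_bins`` needs a ``ppm`` column and, optionally, ``log2fc``
    to infer the excretion direction (positive mean log2fc over matched
    bins = over-excreted under HS).
    """
    ppms = significant_bins["ppm"].to_numpy(dtype=float)
    has_fc = "log2fc" in significant_bins
    rows = []
    for entry in lib.entries:
        matched = []
        fcs = []
        for shift in entry.shifts:
            deltas = np.abs(ppms - shift)
            hit = deltas <= tolerance
            if hit.any():
                matched.append(shift)
                if has_fc:
                    fcs.append(
                        float(significant_bins["log2fc"].to_numpy()[hit].mean())
                    )
        frac = len(matched) / len(entry.shifts)
        direction = None
        if fcs:
            direction = "over-excreted in HS" if np.mean(fcs) > 0 else \
                "under-excreted in HS"
        rows.append(
            {
                "metabolite": entry.name,
                "pathway": entry.pathway,
                "n_shifts": len(entry.shifts),
                "n_matched": len(matched),
                "fraction_matched": frac,
                "supported": frac >= min_fraction,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
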