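"""Synthetic crossover cohorts of one-dimensional urine NMR spectra.

The generator emulates already-processed (Fourier-transformed, phased,
referenced) 600-MHz proton spectra of goat urine: Lorentzian multiplets at
library chemical shifts, a creatinine reference resonance, per-sample
urinary dilution, per-animal metabolite baselines, small chemical-shift
jitter, a smooth spectral background and additive noise.  Treatments follow
a 2x2 crossover: each animal is measured once under thermoneutral (TN) and
once under heat-stress (HS) conditions, and designated metabolites carry a
known HS/TN concentration ratio, so downstream recovery can be checked
against ground truth.

Model for the concentration multiplier of metabolite m in sample i
(animal a, treatment g):

    c[i, m] = base[m] * animal[a, m] * effect[m]^(g == HS) * dilution[i]

with ``animal`` and ``dilution`` log-normal.  Creatinine scales with
dilution only, so normalizing to its resonance cancels dilution exactly.
The spectral background scales with dilution as well (it is urine signal,
not instrument artefact), which keeps that cancellation exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DesignError, InvalidParameterError
from .library import MetaboliteLibrary, default_library
from .preprocess import Spectrum

__all__ = [
    "SimConfig",
    "lorentzian",
    "gaussian_peak",
    "make_crossover_design",
    "simulate_cohort",
    "write_cohort",
]

#: Baseline (TN, undiluted) concentration multiplier of the creatinine
#: reference relative to the candidate metabolites.  Creatinine dominates
#: goat urine spectra, so it is given several-fold the unit baseline.
CREATININE_BASELINE = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the acquisition and design of the heat-stress study:
    16 does in a 2x2 crossover (32 spectra), 32,768 points, and a ppm axis
    covering the analysed 9.0-0.5 ppm window with margin.
    """

    n_animals: int = 16
    n_points: int = 32768
    ppm_range: tuple[float, float] = (9.5, -0.5)
    linewidth: float = 0.002          # Lorentzian half width at half maximum, ppm
    shift_jitter_sd: float = 0.003    # per sample x metabolite shift wobble, ppm
    dilution_sd: float = 0.3          # log-scale sd of per-sample dilution
    noise_sd: float = 0.01            # additive noise, fraction of median peak height
    animal_effect_sd: float = 0.15    # log-scale sd of per-animal metabolite levels
    baseline_amplitude: float = 0.1   # smooth background, fraction of median peak height
    lineshape: str = "lorentzian"     # or "gaussian"
    effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise InvalidParameterError("n_points must be positive")
        if self.n_animals <= 0:
            raise InvalidParameterError("n_animals must be positive")
        if self.ppm_range[0] == self.ppm_range[1]:
            raise InvalidParameterError("ppm_range must be non-empty")
        if self.linewidth <= 0:
            raise InvalidParameterError("linewidth must be positive")
        for sd in (self.shift_jitter_sd, self.dilution_sd, self.noise_sd,
                   self.animal_effect_sd, self.baseline_amplitude):
            if sd < 0:
                raise InvalidParameterError("scale parameters must be >= 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise InvalidParameterError(f"unknown lineshape {self.lineshape!r}")
        for name, fc in self.effects.items():
            if not fc > 0:
                raise InvalidParameterError(
                    f"fold change for {name} must be positive, got {fc}"
                )

    def ppm_axis(self) -> np.ndarray:
        """Descending ppm axis (NMR display convention)."""
        hi, lo = max(self.ppm_range), min(self.ppm_range)
        return np.linspace(hi, lo, self.n_points)

    def with_effects(self, effects: dict[str, float]) -> "SimConfig":
        return replace(self, effects=effects)


def lorentzian(center: float, hwhm: float, amplitude: float,
               axis: np.ndarray) -> np.ndarray:
    """Lorentzian lineshape a * h^2 / (h^2 + (x - c)^2), peak height ``amplitude``."""
    if hwhm <= 0:
        raise InvalidParameterError("hwhm must be positive")
    delta = np.asarray(axis, dtype=float) - center
    return amplitude * hwhm**2 / (hwhm**2 + delta**2)


def gaussian_peak(center: float, hwhm: float, amplitude: float,
                  axis: np.ndarray) -> np.ndarray:
    """Gaussian lineshape with the same half-width convention as :func:`lorentzian`."""
    if hwhm <= 0:
        raise InvalidParameterError("hwhm must be positive")
    delta = np.asarray(axis, dtype=float) - center
    return amplitude * np.exp(-np.log(2.0) * (delta / hwhm) ** 2)


def make_crossover_design(n_animals: int = 16) -> pd.DataFrame:
    """Balanced 2x2 crossover: half the animals get TN then HS, half the reverse.

    Returns one row per sample with columns sample_id, animal_id, period,
    treatment.  Requires an even number of animals.
    """
    if n_animals < 2 or n_animals % 2:
        raise DesignError("crossover balance requires an even n_animals >= 2")
    rows = []
    for a in range(1, n_animals + 1):
        first = "TN" if a <= n_animals // 2 else "HS"
        second = "HS" if first == "TN" else "TN"
        for period, trt in ((1, first), (2, second)):
            rows.append(
                {
                    "sample_id": f"A{a:02d}_P{period}",
                    "animal_id": a,
                    "period": period,
                    "treatment": trt,
                }
            )
    return pd.DataFrame(rows)


def _peak_fn(lineshape: str):
    return lorentzian if lineshape == "lorentzian" else gaussian_peak


def simulate_cohort(
    cfg: SimConfig,
    lib: MetaboliteLibrary | None = None,
) -> tuple[list[Spectrum], pd.DataFrame, pd.DataFrame]:
    """Simulate one crossover cohort.

    Returns ``(spectra, design, ground_truth)`` where ``ground_truth`` has one
    row per sample x metabolite recording the concentration multiplier and
    its factors (animal effect, treatment effect, dilution).
    """
    if lib is None:
        lib = default_library()
    for name in cfg.effects:
        if name not in lib:
            raise ConfigurationError(f"effects refers to unknown metabolite {name!r}")
    lib.check_range(cfg.ppm_range)

    rng = np.random.default_rng(cfg.seed)
    design = make_crossover_design(cfg.n_animals)
    axis = cfg.ppm_axis()
    peak = _peak_fn(cfg.lineshape)

    metabolites = lib.names
    n_met = len(metabolites)
    n_samples = len(design)

    base = np.array(
        [CREATININE_BASELINE if m == "Creatinine" else 1.0 for m in metabolites]
    )
    # Per-animal, per-metabolite biological level (creatinine excluded: it is
    # the dilution reference and must not carry between-sample biology).
    animal_eff = np.exp(
        rng.normal(0.0, cfg.animal_effect_sd, size=(cfg.n_animals, n_met))
    )
    animal_eff[:, [i for i, m in enumerate(metabolites) if m == "Creatinine"]] = 1.0
    dilution = np.exp(rng.normal(0.0, cfg.dilution_sd, size=n_samples))
    jitter = rng.normal(0.0, cfg.shift_jitter_sd, size=(n_samples, n_met))

    # Smooth spectral background, one fixed shape per cohort: a few broad
    # Gaussian humps plus a pedestal, later scaled by dilution per sample.
    hi, lo = max(cfg.ppm_range), min(cfg.ppm_range)
    n_humps = 4
    hump_centers = rng.uniform(lo + 0.5, hi - 0.5, size=n_humps)
    hump_widths = rng.uniform(0.8, 2.0, size=n_humps)
    hump_heights = rng.uniform(0.5, 1.0, size=n_humps)
    background_shape = 0.3 + sum(
        h * np.exp(-0.5 * ((axis - c) / w) ** 2)
        for c, w, h in zip(hump_centers, hump_widths, hump_heights)
    )

    effect_vec = np.array([cfg.effects.get(m, 1.0) for m in metabolites])
    is_hs = (design["treatment"] == "HS").to_numpy()
    animal_idx = design["animal_id"].to_numpy() - 1

    # concentration multipliers, samples x metabolites
    conc = base[None, :] * animal_eff[animal_idx, :]
    conc = conc * np.where(is_hs[:, None], effect_vec[None, :], 1.0)
    conc = conc * dilution[:, None]

    # reference scale for noise and background: median peak height over all
    # clean resonances of the cohort
    rel_amps = [(j, s, a) for j, m in enumerate(metabolites)
                for s, a in zip(lib.get(m).shifts, lib.get(m).relative_amplitudes)]
    all_heights = np.concatenate(
        [conc[:, j] * a for j, _s, a in rel_amps]
    )
    height_scale = float(np.median(all_heights))
    noise_scale = cfg.noise_sd * height_scale
    bg_scale = cfg.baseline_amplitude * height_scale

    spectra: list[Spectrum] = []
    truth_rows = []
    for i, row in enumerate(design.itertuples()):
        intensity = bg_scale * dilution[i] * background_shape.copy()
        for j, m in enumerate(metabolites):
            entry = lib.get(m)
            jit = jitter[i, j]
            for s, a in zip(entry.shifts, entry.relative_amplitudes):
                intensity += peak(s + jit, cfg.linewidth, conc[i, j] * a, axis)
            truth_rows.append(
                {
                    "sample_id": row.sample_id,
                    "animal_id": row.animal_id,
                    "treatment": row.treatment,
                    "metabolite": m,
                    "concentration": conc[i, j],
                    "animal_effect": animal_eff[animal_idx[i], j],
                    "treatment_effect": effect_vec[j] if is_hs[i] else 1.0,
                    "dilution": dilution[i],
                }
            )
        if noise_scale > 0:
            intensity = intensity + rng.normal(0.0, noise_scale, size=cfg.n_points)
        spectra.append(Spectrum(ppm=axis.copy(), intensity=intensity,
                                sample_id=row.sample_id))
    return spectra, design, pd.DataFrame(truth_rows)


def write_cohort(out_dir: str | Path, spectra: list[Spectrum],
                 design: pd.DataFrame, truth: pd.DataFrame | None = None) -> None:
    """Write spectra as two-column text plus design/ground-truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        s.to_text(out / f"{s.sample_id}.txt")
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
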