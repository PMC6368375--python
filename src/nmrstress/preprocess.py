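"""Spectral pre-processing: binning, window exclusion, creatinine
normalization, log2 transform and feature-matrix assembly.

The fixed order of operations is

    bin -> (reference integral computed on the full binned spectrum)
        -> exclusion windows applied -> normalization applied -> log2

Binning sums the point intensities of consecutive groups of
``points_per_bin`` points (default 20); the trailing remainder is dropped.
The default retained window is 9.0-0.5 ppm minus the residual-water window
(5.5-4.6) and the three pH-sensitive histidine-family windows (8.17-7.87,
7.15-7.01, 3.77-3.71).  Every window test uses the half-open convention
[low, high) on bin centers.  Normalization divides by the integral of the
creatinine methyl resonance, taken over a window around 3.05 ppm
(default 3.02-3.08) rather than a single bin so that shift jitter cannot
move the reference out from under a bin edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DesignError,
    EmptyMatrixError,
    InvalidInputError,
    InvalidParameterError,
    NormalizationError,
)

__all__ = [
    "Spectrum",
    "BinnedSpectrum",
    "FeatureMatrix",
    "DEFAULT_KEEP",
    "DEFAULT_EXCLUSIONS",
    "DEFAULT_REF_WINDOW",
    "bin_spectrum",
    "exclude_regions",
    "normalize_to_reference",
    "log2_transform",
    "preprocess_spectrum",
    "preprocess_cohort",
    "assemble_matrix",
    "read_jcampdx",
    "write_jcampdx",
]

DEFAULT_KEEP: tuple[float, float] = (0.5, 9.0)
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = (
    (4.6, 5.5),    # residual water suppression
    (7.87, 8.17),  # histidine
    (7.01, 7.15),  # 1-methylhistidine
    (3.71, 3.77),  # 3-methylhistidine
)
DEFAULT_REF_WINDOW: tuple[float, float] = (3.02, 3.08)
LOG2_FLOOR = 1e-12  # relative to the unit reference integral after normalization


def _sorted_interval(iv) -> tuple[float, float]:
    lo, hi = float(min(iv)), float(max(iv))
    return lo, hi


def _in_window(centers: np.ndarray, window) -> np.ndarray:
    """Half-open membership test: low <= center < high."""
    lo, hi = _sorted_interval(window)
    return (centers >= lo) & (centers < hi)


@dataclass
class Spectrum:
    """One processed 1D spectrum: ppm axis (strictly monotone) + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size == 0:
            raise InvalidInputError("empty spectrum")
        if self.ppm.shape != self.intensity.shape:
            raise InvalidInputError("ppm and intensity lengths differ")
        d = np.diff(self.ppm)
        if self.ppm.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("ppm axis must be strictly monotone")

    def to_text(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.ppm, self.intensity]),
                   fmt="%.10g", header="ppm\tintensity", delimiter="\t")

    @classmethod
    def from_text(cls, path: str | Path, sample_id: str | None = None) -> "Spectrum":
        arr = np.loadtxt(path, delimiter=None)
        if sample_id is None:
            sample_id = Path(path).stem
        return cls(ppm=arr[:, 0], intensity=arr[:, 1], sample_id=sample_id)


@dataclass
class BinnedSpectrum:
    bin_centers: np.ndarray
    bin_values: np.ndarray
    bin_width: float
    sample_id: str = ""
    normalized: bool = False
    log2: bool = False
    reference_integral: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if self.bin_centers.shape != self.bin_values.shape:
            raise InvalidInputError("bin centers and values lengths differ")


def bin_spectrum(s: Spectrum, points_per_bin: int = 20) -> BinnedSpectrum:
    """Integrate consecutive groups of points into bins.

    Bin value = sum of point intensities; bin center = mean ppm of its
    points; trailing points that do not fill a bin are dropped.
    """
    n = s.ppm.size
    if points_per_bin < 1 or points_per_bin > n:
        raise InvalidParameterError(
            f"points_per_bin must be in 1..{n}, got {points_per_bin}"
        )
    n_bins = n // points_per_bin
    used = n_bins * points_per_bin
    ppm = s.ppm[:used].reshape(n_bins, points_per_bin)
    vals = s.intensity[:used].reshape(n_bins, points_per_bin)
    spacing = float(np.median(np.abs(np.diff(s.ppm)))) if n > 1 else 0.0
    return BinnedSpectrum(
        bin_centers=ppm.mean(axis=1),
        bin_values=vals.sum(axis=1),
        bin_width=points_per_bin * spacing,
        sample_id=s.sample_id,
    )


def exclude_regions(
    b: BinnedSpectrum,
    keep=DEFAULT_KEEP,
    drop=DEFAULT_EXCLUSIONS,
) -> BinnedSpectrum:
    """Retain bins whose center lies inside ``keep`` and outside every ``drop``.

    All interval tests are half-open [low, high) on the center, so a center
    exactly on a window's low edge is inside that window.
    """
    mask = _in_window(b.bin_centers, keep)
    for window in drop:
        mask &= ~_in_window(b.bin_centers, window)
    if not mask.any():
        raise EmptyMatrixError(f"{b.sample_id or 'spectrum'}: all bins excluded")
    return replace(b, bin_centers=b.bin_centers[mask], bin_values=b.bin_values[mask])


def reference_integral(b: BinnedSpectrum, ref_window=DEFAULT_REF_WINDOW) -> float:
    """Sum of bin values whose center lies in the reference window."""
    mask = _in_window(b.bin_centers, ref_window)
    if not mask.any():
        raise NormalizationError(
            f"{b.sample_id or 'spectrum'}: no bins in reference window {ref_window}"
        )
    return float(b.bin_values[mask].sum())


def normalize_to_reference(
    b: BinnedSpectrum,
    ref_window=DEFAULT_REF_WINDOW,
    reference: float | None = None,
) -> BinnedSpectrum:
    """Divide every bin by the creatinine reference integral.

    ``reference`` may be supplied when it was computed on the spectrum
    before exclusion windows removed bins (the pipeline does this); by
    default it is computed from ``b`` itself.
    """
    if reference is None:
        reference = reference_integral(b, ref_window)
    if not reference > 0:
        raise NormalizationError(
            f"{b.sample_id or 'spectrum'}: reference integral {reference} <= 0"
        )
    return replace(
        b,
        bin_values=b.bin_values / reference,
        normalized=True,
        reference_integral=reference,
    )


def log2_transform(b: BinnedSpectrum, floor: float = LOG2_FLOOR) -> BinnedSpectrum:
    """value -> log2(max(value, floor)); requires a normalized spectrum."""
    if not b.normalized:
        raise InvalidInputError("log2_transform expects a normalized spectrum")
    return replace(b, bin_values=np.log2(np.maximum(b.bin_values, floor)), log2=True)


def preprocess_spectrum(
    s: Spectrum,
    points_per_bin: int = 20,
    keep=DEFAULT_KEEP,
    drop=DEFAULT_EXCLUSIONS,
    ref_window=DEFAULT_REF_WINDOW,
    floor: float = LOG2_FLOOR,
) -> BinnedSpectrum:
    """Full per-spectrum pipeline: bin -> reference -> exclude -> normalize -> log2."""
    binned = bin_spectrum(s, points_per_bin)
    ref = reference_integral(binned, ref_window)
    retained = exclude_regions(binned, keep, drop)
    normalized = normalize_to_reference(retained, ref_window, reference=ref)
    return log2_transform(normalized, floor)


@dataclass
class FeatureMatrix:
    """Samples x retained-bins matrix of normalized log2 intensities."""

    values: pd.DataFrame          # index sample_id, columns float ppm centers
    design: pd.DataFrame          # sample_id, animal_id, period, treatment
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise InvalidInputError("feature matrix contains missing values")
        if list(self.values.index) != list(self.design["sample_id"]):
            raise DesignError("design rows do not align with matrix rows")

    @property
    def bin_centers(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Class coding TN -> 0, HS -> 1."""
        return (self.design["treatment"].to_numpy() == "HS").astype(float)

    def to_tsv(self, path: str | Path, design_path: str | Path | None = None) -> None:
        """Write as a flat sample-by-bin TSV: sample_id column + bin-center header.

        Centers are printed to 4 decimals (the dialect), values at full
        precision so a round trip is lossless.
        """
        df = self.values.copy()
        df.columns = [f"{c:.4f}" for c in self.bin_centers]
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 design: pd.DataFrame | str | Path | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id",
                         float_precision="round_trip")
        df.columns = [float(c) for c in df.columns]
        if design is None:
            design = _design_from_sample_ids(list(df.index))
        elif not isinstance(design, pd.DataFrame):
            design = pd.read_csv(design, sep="\t")
        design = design.set_index("sample_id").loc[list(df.index)].reset_index()
        return cls(values=df, design=design)


def _design_from_sample_ids(sample_ids: list[str]) -> pd.DataFrame:
    """Recover a design table from ids of the form A01_P1, plus TN/HS tags if present."""
    rows = []
    for sid in sample_ids:
        parts = sid.split("_")
        try:
            animal = int(parts[0].lstrip("A"))
            period = int(parts[1].lstrip("P"))
        except (ValueError, IndexError) as err:
            raise DesignError(
                f"cannot infer design from sample id {sid!r}; pass a design table"
            ) from err
        trt = parts[2] if len(parts) > 2 else ""
        rows.append({"sample_id": sid, "animal_id": animal,
                     "period": period, "treatment": trt})
    return pd.DataFrame(rows)


def assemble_matrix(
    spectra: list[BinnedSpectrum],
    design: pd.DataFrame,
    grid_tol: float = 1e-9,
    provenance: dict | None = None,
) -> FeatureMatrix:
    """Stack per-sample binned spectra (common grid) in design order."""
    if not spectra:
        raise InvalidInputError("no spectra to assemble")
    by_id = {b.sample_id: b for b in spectra}
    missing = [sid for sid in design["sample_id"] if sid not in by_id]
    if missing:
        raise DesignError(f"design rows without spectra: {missing}")
    ref_centers = spectra[0].bin_centers
    for b in spectra[1:]:
        if b.bin_centers.shape != ref_centers.shape or np.any(
            np.abs(b.bin_centers - ref_centers) > grid_tol
        ):
            raise AlignmentError(
                f"{b.sample_id}: bin grid differs from {spectra[0].sample_id}"
            )
    values = pd.DataFrame(
        [by_id[sid].bin_values for sid in design["sample_id"]],
        index=list(design["sample_id"]),
        columns=ref_centers,
    )
    return FeatureMatrix(values=values, design=design.reset_index(drop=True),
                         provenance=provenance or {})


def preprocess_cohort(
    spectra: list[Spectrum],
    design: pd.DataFrame,
    points_per_bin: int = 20,
    keep=DEFAULT_KEEP,
    drop=DEFAULT_EXCLUSIONS,
    ref_window=DEFAULT_REF_WINDOW,
    floor: float = LOG2_FLOOR,
) -> FeatureMatrix:
    """Apply the per-spectrum pipeline to a cohort and assemble the matrix."""
    processed = [
        preprocess_spectrum(s, points_per_bin, keep, drop, ref_window, floor)
        for s in spectra
    ]
    provenance = {
        "points_per_bin": points_per_bin,
        "keep_window": tuple(keep),
        "excluded_windows": tuple(tuple(w) for w in drop),
        "ref_window": tuple(ref_window),
        "log2_floor": floor,
    }
    return assemble_matrix(processed, design, provenance=provenance)


# --- minimal JCAMP-DX support (AFFN, one Y per line or X++(Y..Y) tables) ---

def write_jcampdx(s: Spectrum, path: str | Path, title: str | None = None) -> None:
    """Write a spectrum as a minimal JCAMP-DX 5.01 XYDATA=(XY..XY) record."""
    lines = [
        f"##TITLE={title or s.sample_id or 'spectrum'}",
        "##JCAMP-DX=5.01",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY",
        f"##NPOINTS={s.ppm.size}",
        f"##FIRSTX={s.ppm[0]:.10g}",
        f"##LASTX={s.ppm[-1]:.10g}",
        "##XYDATA=(XY..XY)",
    ]
    lines += [f"{x:.10g}, {y:.10g}" for x, y in zip(s.ppm, s.intensity)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcampdx(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read the minimal JCAMP-DX dialect written by :func:`write_jcampdx`.

    Supports (XY..XY) pairs and simple X++(Y..Y) AFFN tables.
    """
    text = Path(path).read_text().splitlines()
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    firstx = lastx = npoints = None
    for line in text:
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                mode = "xy" if "XY..XY" in val else "xpp"
            elif key == "FIRSTX":
                firstx = float(val)
            elif key == "LASTX":
                lastx = float(val)
            elif key == "NPOINTS":
                npoints = int(val)
            elif key == "END":
                break
            continue
        if mode == "xy":
            x_str, _, y_str = line.partition(",")
            xs.append(float(x_str))
            ys.append(float(y_str))
        elif mode == "xpp":
            vals = line.replace(",", " ").split()
            ys.extend(float(v) for v in vals[1:])
    if mode == "xpp":
        if firstx is None or lastx is None or npoints is None:
            raise InvalidInputError("JCAMP-DX X++(Y..Y) needs FIRSTX/LASTX/NPOINTS")
        xs = list(np.linspace(firstx, lastx, npoints))
        ys = ys[:npoints]
    if not xs:
        raise InvalidInputError(f"no XYDATA found in {path}")
    if sample_id is None:
        sample_id = Path(path).stem
    return Spectrum(ppm=np.array(xs), intensity=np.array(ys), sample_id=sample_id)
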