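import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmrstress.preprocess as pp
from nmrstress import (
    Spectrum,
    assemble_matrix,
    bin_spectrum,
    exclude_regions,
    log2_transform,
    make_crossover_design,
    normalize_to_reference,
    preprocess_cohort,
    preprocess_spectrum,
)
from nmrstress.exceptions import (
    AlignmentError,
    DesignError,
    EmptyMatrixError,
    InvalidInputError,
    InvalidParameterError,
    NormalizationError,
)


def _flat_spectrum(n=100, value=2.0, sid="s"):
    return Spectrum(ppm=np.linspace(10, 0, n), intensity=np.full(n, value), sample_id=sid)


class TestBinning:
    def test_constant_spectrum(self):
        b = bin_spectrum(_flat_spectrum(100, 2.0), 20)
        assert b.bin_values.shape == (5,)
        assert b.bin_values == pytest.approx(np.full(5, 40.0))

    def test_floor_arithmetic_full_size(self):
        s = Spectrum(ppm=np.linspace(9.5, -0.5, 32768),
                     intensity=np.zeros(32768), sample_id="s")
        b = bin_spectrum(s, 20)
        assert b.bin_values.size == 1638  # 8 trailing points dropped

    def test_bin_width_matches_point_spacing(self):
        # 12.0 ppm over 32768 points binned by 20 -> about 0.0073 ppm per bin
        s = Spectrum(ppm=np.linspace(10.0, -2.0, 32768),
                     intensity=np.zeros(32768), sample_id="s")
        b = bin_spectrum(s, 20)
        assert b.bin_width == pytest.approx(20 * 12.0 / 32767, rel=1e-3)
        assert b.bin_width == pytest.approx(0.0073, abs=2e-4)

    def test_centers_are_point_means_and_monotone(self):
        s = _flat_spectrum(60)
        b = bin_spectrum(s, 20)
        assert b.bin_centers == pytest.approx(
            s.ppm[:60].reshape(3, 20).mean(axis=1)
        )
        assert np.all(np.diff(b.bin_centers) < 0)

    @given(
        n=st.integers(min_value=21, max_value=400),
        ppb=st.integers(min_value=1, max_value=20),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_intensity_conservation(self, n, ppb, seed):
        """Sum over bins equals sum of point intensities over the binned range."""
        rng = np.random.default_rng(seed)
        s = Spectrum(ppm=np.linspace(9, 0, n), intensity=rng.normal(size=n),
                     sample_id="s")
        b = bin_spectrum(s, ppb)
        used = (n // ppb) * ppb
        assert b.bin_values.sum() == pytest.approx(
            s.intensity[:used].sum(), rel=1e-9, abs=1e-12
        )

    def test_invalid_points_per_bin(self):
        with pytest.raises(InvalidParameterError):
            bin_spectrum(_flat_spectrum(10), 0)
        with pytest.raises(InvalidParameterError):
            bin_spectrum(_flat_spectrum(10), 11)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(InvalidInputError):
            Spectrum(ppm=np.array([]), intensity=np.array([]))


class TestExclusion:
    def _binned(self, centers):
        centers = np.asarray(centers, dtype=float)
        return pp.BinnedSpectrum(bin_centers=centers,
                                 bin_values=np.ones_like(centers),
                                 bin_width=0.007, sample_id="s")

    @pytest.mark.parametrize(
        "center, retained",
        [
            (7.83, True),    # hippurate survives next to the histidine window
            (5.0, False),    # residual water window
            (9.4, False),    # outside 9.0-0.5
            (9.0, False),    # half-open: the keep window is [0.5, 9.0)
            (0.5, True),
            (7.87, False),   # exactly on an exclusion window's low edge
            (3.05, True),    # creatinine reference is never excluded
        ],
    )
    def test_boundary_rules(self, center, retained):
        b = self._binned([center, 2.0])  # 2.0 always retained as company
        out = exclude_regions(b)
        assert (center in out.bin_centers) == retained

    def test_idempotent(self, effect_cohort):
        spectra, _, _ = effect_cohort
        b = bin_spectrum(spectra[0], 20)
        once = exclude_regions(b)
        twice = exclude_regions(once)
        assert np.array_equal(once.bin_centers, twice.bin_centers)
        assert np.array_equal(once.bin_values, twice.bin_values)

    def test_all_excluded_raises(self):
        with pytest.raises(EmptyMatrixError):
            exclude_regions(self._binned([9.4, 10.0]))


class TestNormalization:
    def test_reference_window_sums_to_one(self, effect_cohort):
        spectra, _, _ = effect_cohort
        b = normalize_to_reference(bin_spectrum(spectra[0], 20))
        mask = (b.bin_centers >= 3.02) & (b.bin_centers < 3.08)
        assert b.bin_values[mask].sum() == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        n = 2000
        ppm = np.linspace(9.5, -0.5, n)
        base = np.abs(rng.normal(1.0, 0.2, n))
        s1 = Spectrum(ppm=ppm, intensity=base, sample_id="a")
        s2 = Spectrum(ppm=ppm, intensity=7.3 * base, sample_id="b")
        b1 = preprocess_spectrum(s1)
        b2 = preprocess_spectrum(s2)
        assert b1.bin_values == pytest.approx(b2.bin_values, rel=1e-12)

    def test_dilution_cancellation(self, lib):
        """Per-sample multiplicative dilution has no effect on any
        normalized bin (noise off), to within 1e-9 relative."""
        from nmrstress import SimConfig, simulate_cohort

        cfg = SimConfig(n_points=4096, seed=9, effects={"Hippurate": 2.74},
                        noise_sd=0.0, dilution_sd=0.3)
        spectra, design, _ = simulate_cohort(cfg, lib)
        rng = np.random.default_rng(1)
        rescaled = [
            Spectrum(ppm=s.ppm, intensity=s.intensity * f, sample_id=s.sample_id)
            for s, f in zip(spectra, np.exp(rng.normal(0, 0.5, len(spectra))))
        ]
        x1 = preprocess_cohort(spectra, design).x
        x2 = preprocess_cohort(rescaled, design).x
        assert np.max(np.abs(x2 - x1) / (np.abs(x1) + 1e-30)) < 1e-9

    def test_zero_reference_raises_with_sample_name(self):
        s = Spectrum(ppm=np.linspace(9.5, -0.5, 1000),
                     intensity=np.zeros(1000), sample_id="doe42")
        with pytest.raises(NormalizationError, match="doe42"):
            preprocess_spectrum(s)


class TestLog2:
    def test_closed_form_values(self):
        b = pp.BinnedSpectrum(
            bin_centers=np.array([3.0, 2.0, 1.0]),
            bin_values=np.array([1.0, 0.25, 8.0]),
            bin_width=0.01, normalized=True,
        )
        out = log2_transform(b)
        assert out.bin_values == pytest.approx([0.0, -2.0, 3.0])

    def test_flooring_handles_nonpositive_bins(self):
        b = pp.BinnedSpectrum(
            bin_centers=np.array([1.0, 2.0]),
            bin_values=np.array([-0.5, 0.0]),
            bin_width=0.01, normalized=True,
        )
        out = log2_transform(b, floor=1e-12)
        assert np.all(np.isfinite(out.bin_values))
        assert out.bin_values == pytest.approx([np.log2(1e-12)] * 2)

    def test_requires_normalized_input(self):
        b = pp.BinnedSpectrum(bin_centers=np.array([1.0]),
                              bin_values=np.array([2.0]), bin_width=0.01)
        with pytest.raises(InvalidInputError):
            log2_transform(b)


class TestMatrixAssembly:
    def test_cohort_shape(self, effect_matrix):
        assert effect_matrix.values.shape[0] == 32
        assert effect_matrix.values.shape[1] > 100
        # retained bins all inside 0.5-9.0 and outside the water window
        c = effect_matrix.bin_centers
        assert c.min() >= 0.5 and c.max() < 9.0
        assert not ((c >= 4.6) & (c < 5.5)).any()

    def test_grid_mismatch_rejected(self, effect_cohort):
        spectra, design, _ = effect_cohort
        a = preprocess_spectrum(spectra[0])
        b = preprocess_spectrum(spectra[1])
        b.bin_centers = b.bin_centers + 1e-6
        with pytest.raises(AlignmentError):
            assemble_matrix([a, b], design.iloc[:2])

    def test_missing_design_row_rejected(self, effect_cohort):
        spectra, design, _ = effect_cohort
        a = preprocess_spectrum(spectra[0])
        with pytest.raises(DesignError):
            assemble_matrix([a], design.iloc[:3])

    def test_tsv_round_trip_lossless(self, effect_matrix, tmp_path):
        path = tmp_path / "matrix.tsv"
        dpath = tmp_path / "design.tsv"
        effect_matrix.to_tsv(path, dpath)
        back = pp.FeatureMatrix.from_tsv(path, dpath)
        assert np.array_equal(back.x, effect_matrix.x)
        assert back.bin_centers == pytest.approx(effect_matrix.bin_centers, abs=1e-4)
        assert back.design["treatment"].tolist() == \
            effect_matrix.design["treatment"].tolist()

    def test_flat_matrix_text_parses_bit_exactly(self, tmp_path):
        """A hand-written sample-by-bin matrix (sample_id column +
        ppm-center header) loads with exactly the printed values."""
        text = (
            "sample_id\t7.8280\t3.0510\t0.9870\n"
            "A01_P1\t-1.25\t0.5\t-13.2578125\n"
            "A01_P2\t-0.75\t0.5\t-12.5\n"
        )
        path = tmp_path / "flat_matrix.txt"
        path.write_text(text)
        design = pd.DataFrame(
            {
                "sample_id": ["A01_P1", "A01_P2"],
                "animal_id": [1, 1],
                "period": [1, 2],
                "treatment": ["TN", "HS"],
            }
        )
        X = pp.FeatureMatrix.from_tsv(path, design)
        assert X.x.tolist() == [[-1.25, 0.5, -13.2578125], [-0.75, 0.5, -12.5]]
        assert X.bin_centers.tolist() == [7.828, 3.051, 0.987]


class TestSpectrumIO:
    def test_two_column_text_round_trip(self, tmp_path):
        s = _flat_spectrum(50, 1.5, "roundtrip")
        s.intensity = s.intensity + np.sin(s.ppm)
        path = tmp_path / "roundtrip.txt"
        s.to_text(path)
        back = Spectrum.from_text(path)
        assert back.sample_id == "roundtrip"
        assert back.ppm == pytest.approx(s.ppm, rel=1e-9)
        assert back.intensity == pytest.approx(s.intensity, rel=1e-9)

    def test_jcampdx_round_trip(self, tmp_path):
        s = _flat_spectrum(40, 2.0, "jdx")
        s.intensity = s.intensity + np.cos(s.ppm)
        path = tmp_path / "jdx.jdx"
        pp.write_jcampdx(s, path)
        back = pp.read_jcampdx(path)
        assert back.ppm == pytest.approx(s.ppm, rel=1e-9)
        assert back.intensity == pytest.approx(s.intensity, rel=1e-9)
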