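"""Referencing, bucketing geometry, matrix assembly, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrmetab.preprocess import (
    DEFAULT_EXCLUSIONS,
    BinnedMatrix,
    SpectrumRecord,
    bin_spectrum,
    build_matrix,
    reference_to_lactate,
    total_sum_normalize,
)


def lorentzian(axis, center, fwhm=0.004, area=1.0):
    hw = fwhm / 2.0
    return area * (hw / np.pi) / ((axis - center) ** 2 + hw ** 2)


def flat_spectrum(value=1.0, spacing=0.0005, sample_id="s"):
    # axis offset by half a spacing so no point sits exactly on a bin edge
    axis = np.arange(0.4, 9.2, spacing) + spacing / 2.0
    return SpectrumRecord(sample_id, "", axis, np.full(axis.size, value))


def doublet_spectrum(center, sep=0.014, sample_id="s"):
    axis = np.arange(0.4, 9.2, 0.0005)
    y = lorentzian(axis, center - sep / 2) + lorentzian(axis, center + sep / 2)
    return SpectrumRecord(sample_id, "", axis, y)


class TestSpectrumRecord:
    def test_descending_axis_is_normalized_to_ascending(self):
        s = SpectrumRecord("x", "", np.array([3.0, 2.0, 1.0]),
                           np.array([1.0, 2.0, 3.0]))
        assert np.all(np.diff(s.ppm) > 0)
        assert s.intensity[0] == 3.0

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError):
            SpectrumRecord("x", "", np.array([1.0, 3.0, 2.0]), np.zeros(3))


class TestLactateReferencing:
    def test_offset_doublet_recentred(self):
        spec = doublet_spectrum(1.36)
        ref = reference_to_lactate(spec)
        shift = ref.ppm[0] - spec.ppm[0]
        assert shift == pytest.approx(-0.03, abs=0.001)

    def test_already_centred_is_fixed_point(self):
        spec = doublet_spectrum(1.33)
        ref = reference_to_lactate(spec)
        assert np.allclose(ref.ppm, spec.ppm, atol=1e-9)

    def test_against_brute_force_symmetry_search(self):
        # brute-force oracle: candidate shift maximizing the peak of the
        # window's cross-correlation with its mirror image
        spec = doublet_spectrum(1.30)
        ref = reference_to_lactate(spec)
        applied = ref.ppm[0] - spec.ppm[0]

        candidates = np.arange(-0.05, 0.0501, 0.0005)
        def symmetry_score(shift):
            ppm = spec.ppm + shift
            m = (ppm >= 1.28) & (ppm <= 1.38)
            w = spec.intensity[m]
            mid = ppm[m] - 1.33
            return -abs(np.sum(mid * w) / np.sum(w))  # centroid at 1.33
        best = candidates[np.argmax([symmetry_score(c) for c in candidates])]
        assert applied == pytest.approx(best, abs=0.002)
        assert applied == pytest.approx(+0.03, abs=0.002)

    def test_single_peak_fallback_warns(self, caplog):
        axis = np.arange(1.0, 2.0, 0.0005)
        y = lorentzian(axis, 1.35)
        spec = SpectrumRecord("s", "", axis, y)
        with caplog.at_level("WARNING"):
            ref = reference_to_lactate(spec)
        assert "tallest" in caplog.text
        m = np.argmax(ref.intensity)
        assert ref.ppm[m] == pytest.approx(1.33, abs=0.001)


class TestBinning:
    def test_default_geometry_3385_bins(self):
        values, (left, right) = bin_spectrum(flat_spectrum())
        assert values.size == 3385
        assert left.size == right.size == 3385
        # descending report order, equal widths
        assert np.all(np.diff(left) < 0)
        assert np.allclose(right - left, 0.002, atol=1e-12)

    def test_exclusion_boundaries_on_edges(self):
        _, (left, right) = bin_spectrum(flat_spectrum())
        edges = np.union1d(left, right)
        for window in DEFAULT_EXCLUSIONS:
            for bound in window:
                assert np.min(np.abs(edges - bound)) < 1e-9

    def test_no_bin_overlaps_exclusion(self):
        _, (left, right) = bin_spectrum(flat_spectrum())
        for whi, wlo in DEFAULT_EXCLUSIONS:
            assert not np.any((left >= wlo - 1e-12) & (right <= whi + 1e-12))

    def test_constant_intensity_gives_equal_bins(self):
        values, _ = bin_spectrum(flat_spectrum(value=2.5, spacing=0.0005))
        assert np.allclose(values, values[0])

    def test_signal_inside_excluded_window_vanishes(self):
        axis = np.arange(0.4, 9.2, 0.0005)
        y = lorentzian(axis, 5.95)  # inside the water window 5.50-6.40
        values, _ = bin_spectrum(SpectrumRecord("s", "", axis, y))
        assert values.max() < 5e-3 * y.max()

    def test_total_signal_conserved_over_retained_windows(self):
        spec = doublet_spectrum(1.33)
        values, _ = bin_spectrum(spec)
        retained = (
            ((spec.ppm >= 0.5) & (spec.ppm < 4.36))
            | ((spec.ppm >= 5.19) & (spec.ppm < 5.50))
            | ((spec.ppm >= 6.40) & (spec.ppm < 9.0))
        )
        assert values.sum() == pytest.approx(
            spec.intensity[retained].sum(), rel=1e-12
        )

    def test_width_not_dividing_region_rejected(self):
        with pytest.raises(ValueError):
            bin_spectrum(flat_spectrum(), region=(9.0, 0.5), width=0.003)

    def test_sparse_axis_fills_empty_bins_with_warning(self):
        axis = np.arange(0.4, 9.2, 0.005)  # coarser than the bin width
        spec = SpectrumRecord("s", "", axis, np.full(axis.size, 1.0))
        with pytest.warns(UserWarning, match="empty"):
            values, _ = bin_spectrum(spec)
        assert np.all(values > 0)


class TestMatrixAssembly:
    def test_default_cohort_matrix_shape(self, normalized_matrix):
        assert normalized_matrix.values.shape == (36, 3385)

    def test_single_spectrum_matches_bin_spectrum(self):
        spec = doublet_spectrum(1.33, sample_id="a")
        m = build_matrix([spec], {"a": "G1"})
        vals, _ = bin_spectrum(spec)
        assert np.array_equal(m.values[0], vals)

    def test_duplicated_spectrum_two_rows(self):
        s1 = doublet_spectrum(1.33, sample_id="a")
        s2 = doublet_spectrum(1.33, sample_id="b")
        m = build_matrix([s1, s2], {"a": "G1", "b": "G2"})
        assert np.array_equal(m.values[0], m.values[1])

    def test_missing_manifest_entry_names_sample(self):
        spec = doublet_spectrum(1.33, sample_id="orphan")
        with pytest.raises(ValueError, match="orphan"):
            build_matrix([spec], {"other": "G1"})

    def test_rows_follow_manifest_order(self):
        s1 = doublet_spectrum(1.33, sample_id="a")
        s2 = doublet_spectrum(1.40, sample_id="b")
        manifest = pd.DataFrame(
            {"sample_id": ["b", "a"], "group": ["G2", "G1"]}
        )
        m = build_matrix([s1, s2], manifest)
        assert m.sample_ids == ["b", "a"]
        assert m.groups == ["G2", "G1"]


class TestNormalization:
    def test_row_arithmetic(self):
        m = BinnedMatrix(
            sample_ids=["a"], groups=["G"],
            values=np.array([[1.0, 2.0, 2.0]]),
            left_edges=np.array([3.0, 2.0, 1.0]),
            right_edges=np.array([3.002, 2.002, 1.002]),
        )
        out = total_sum_normalize(m)
        assert np.allclose(out.values, [[0.2, 0.4, 0.4]])
        assert out.normalized

    def test_renormalization_rejected_but_idempotent_in_values(self):
        m = BinnedMatrix(
            sample_ids=["a"], groups=["G"],
            values=np.array([[0.2, 0.4, 0.4]]),
            left_edges=np.array([3.0, 2.0, 1.0]),
            right_edges=np.array([3.002, 2.002, 1.002]),
        )
        out = total_sum_normalize(m)
        assert np.allclose(out.values, m.values)  # already summing to 1
        with pytest.raises(ValueError):
            total_sum_normalize(out)

    def test_non_positive_row_names_sample(self):
        m = BinnedMatrix(
            sample_ids=["bad"], groups=["G"],
            values=np.array([[0.0, 0.0]]),
            left_edges=np.array([2.0, 1.0]),
            right_edges=np.array([2.002, 1.002]),
        )
        with pytest.raises(ValueError, match="bad"):
            total_sum_normalize(m)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(1, 6), st.integers(2, 8), st.integers(0, 2 ** 31 - 1))
    def test_rows_sum_to_one(self, n, p, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.01, 5.0, size=(n, p))
        m = BinnedMatrix(
            sample_ids=[f"s{i}" for i in range(n)], groups=["G"] * n,
            values=vals,
            left_edges=np.arange(p, 0, -1.0),
            right_edges=np.arange(p, 0, -1.0) + 0.002,
        )
        out = total_sum_normalize(m)
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_global_intensity_scaling(self, default_cohort):
        spectra, _, manifest = default_cohort
        import nmrmetab as nm

        base = nm.preprocess_spectra(spectra[:6], manifest.iloc[:6])
        scaled = [
            SpectrumRecord(s.sample_id, s.group, s.ppm,
                           s.intensity * (7.0 if i == 2 else 1.0))
            for i, s in enumerate(spectra[:6])
        ]
        again = nm.preprocess_spectra(scaled, manifest.iloc[:6])
        assert np.allclose(base.values, again.values, atol=1e-12)
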