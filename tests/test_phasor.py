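"""Spectral phasor transform: worked values, invariants, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srsphasor.errors import DomainError, ValidationError
from srsphasor.phasor import (
    concat_windows,
    phasor_histogram,
    phasor_of_mixture,
    phasor_transform,
)
from conftest import make_stack


def naive_phasor(spectrum: np.ndarray, harmonic: int = 1) -> tuple[float, float]:
    """Independent per-pixel oracle: direct summation, no vectorization."""
    n = len(spectrum)
    g = s = tot = 0.0
    for k in range(n):
        g += spectrum[k] * np.cos(2 * np.pi * harmonic * k / n)
        s += spectrum[k] * np.sin(2 * np.pi * harmonic * k / n)
        tot += spectrum[k]
    return g / tot, s / tot


def single_pixel_phasor(spectrum, **kw):
    stack = make_stack(np.asarray(spectrum, dtype=float).reshape(1, 1, -1))
    f = phasor_transform(stack, intensity_threshold=0.0, **kw)
    return float(f.G[0, 0]), float(f.S[0, 0])


class TestWorkedValues:
    def test_delta_at_first_frame_maps_to_one_zero(self):
        for n in (4, 7, 16):
            spec = np.zeros(n)
            spec[0] = 5.0
            assert single_pixel_phasor(spec) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_constant_spectrum_maps_to_origin(self):
        assert single_pixel_phasor([3.0, 3.0, 3.0, 3.0]) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_hand_evaluated_four_frame_spectrum(self):
        # I = [2,1,0,1]: G = (2*1 + 1*0 + 0*(-1) + 1*0)/4 = 0.5, S = (1-1)/4 = 0
        assert single_pixel_phasor([2.0, 1.0, 0.0, 1.0]) == pytest.approx((0.5, 0.0), abs=1e-12)

    def test_oracle_equivalence_on_random_stacks(self):
        rng = np.random.default_rng(42)
        stack = make_stack(rng.uniform(0.1, 4.0, size=(8, 8, 16)))
        field = phasor_transform(stack, intensity_threshold=0.0)
        for r in range(8):
            for c in range(8):
                g, s = naive_phasor(stack.intensities[r, c])
                assert field.G[r, c] == pytest.approx(g, rel=1e-12, abs=1e-12)
                assert field.S[r, c] == pytest.approx(s, rel=1e-12, abs=1e-12)

    def test_descending_acquisition_order_sorted_internally(self):
        spec = np.array([2.0, 1.0, 0.0, 1.0])
        # same spectrum delivered descending must give the same phasor
        asc = make_stack(spec.reshape(1, 1, 4), wavenumbers=[2000, 2007, 2014, 2021])
        desc = make_stack(spec[::-1].reshape(1, 1, 4), wavenumbers=[2021, 2014, 2007, 2000])
        fa = phasor_transform(asc, intensity_threshold=0.0)
        fd = phasor_transform(desc, intensity_threshold=0.0)
        assert fa.G[0, 0] == pytest.approx(fd.G[0, 0], abs=1e-14)
        assert fa.S[0, 0] == pytest.approx(fd.S[0, 0], abs=1e-14)


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_boundedness_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        spec = rng.uniform(0.0, 10.0, size=rng.integers(2, 40))
        if spec.sum() == 0:
            spec[0] = 1.0
        g, s = single_pixel_phasor(spec)
        assert g * g + s * s <= 1 + 1e-9
        c = float(rng.uniform(0.1, 100.0))
        g2, s2 = single_pixel_phasor(c * spec)
        assert (g2, s2) == pytest.approx((g, s), abs=1e-12)

    def test_linearity_matches_mixture_law(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 5, 24)
        b = rng.uniform(0, 5, 24)
        pa, pb = single_pixel_phasor(a), single_pixel_phasor(b)
        predicted = phasor_of_mixture([(pa, a.sum()), (pb, b.sum())])
        actual = single_pixel_phasor(a + b)
        assert actual == pytest.approx(predicted, rel=1e-12, abs=1e-12)

    def test_mixture_of_gaussian_peak_spectra(self):
        # mixture law vs the actual summed spectra of two synthetic peaks
        axis = np.arange(64, dtype=float)
        peak1 = np.exp(-0.5 * ((axis - 12) / 4.0) ** 2)
        peak2 = 2.5 * np.exp(-0.5 * ((axis - 45) / 6.0) ** 2)
        p1, p2 = single_pixel_phasor(peak1), single_pixel_phasor(peak2)
        predicted = phasor_of_mixture([(p1, peak1.sum()), (p2, peak2.sum())])
        assert single_pixel_phasor(peak1 + peak2) == pytest.approx(predicted, abs=1e-12)

    def test_peak_shift_moves_phasor_monotonically_in_angle(self):
        axis = np.arange(48, dtype=float)
        angles = []
        for center in np.linspace(8, 40, 9):
            spec = np.exp(-0.5 * ((axis - center) / 3.0) ** 2)
            g, s = single_pixel_phasor(spec)
            angles.append(np.arctan2(s, g) % (2 * np.pi))
        # translating the peak later in the scan rotates the phasor one way
        diffs = np.diff(angles)
        assert (diffs < 0).all() or (diffs > 0).all()


class TestMixtureEdges:
    def test_single_component_identity(self):
        assert phasor_of_mixture([((0.3, -0.4), 2.0)]) == pytest.approx((0.3, -0.4))

    def test_symmetric_pair_cancels(self):
        assert phasor_of_mixture([((1, 0), 1.0), ((-1, 0), 1.0)]) == pytest.approx((0, 0))

    def test_weighted_pair(self):
        assert phasor_of_mixture([((1, 0), 3.0), ((0, 1), 1.0)]) == pytest.approx((0.75, 0.25))

    def test_zero_total_intensity_rejected(self):
        with pytest.raises(DomainError):
            phasor_of_mixture([((1, 0), 0.0), ((0, 1), 0.0)])


class TestConcat:
    def test_single_stack_identity(self, small_stacks):
        assert concat_windows([small_stacks[0]]) is small_stacks[0]

    def test_triplex_concatenation_frame_count(self, small_stacks):
        combined = concat_windows(list(small_stacks))
        assert combined.n_frames == sum(s.n_frames for s in small_stacks)
        assert set(combined.axis.window_ids) == {0, 1, 2}

    def test_dimension_mismatch_rejected(self):
        a = make_stack(np.ones((4, 4, 3)))
        b = make_stack(np.ones((5, 5, 3)), wavenumbers=[2400, 2407, 2414])
        with pytest.raises(ValidationError):
            concat_windows([a, b])

    def test_overlapping_windows_rejected(self):
        a = make_stack(np.ones((4, 4, 3)), wavenumbers=[2000, 2007, 2014])
        b = make_stack(np.ones((4, 4, 3)), wavenumbers=[2010, 2017, 2024])
        with pytest.raises(ValidationError):
            concat_windows([a, b])

    def test_concatenated_pixel_spectra_are_unchanged(self, small_stacks):
        combined = concat_windows(list(small_stacks))
        r, c = 32, 32
        expected = np.concatenate([s.intensities[r, c] for s in small_stacks])
        np.testing.assert_array_equal(combined.intensities[r, c], expected)


class TestHistogram:
    def test_counts_conserve_valid_pixels(self, small_stacks):
        field = phasor_transform(concat_windows(list(small_stacks)))
        hist = phasor_histogram(field, bin_count=64)
        assert hist.counts.sum() == field.n_valid

    def test_single_valid_pixel(self):
        arr = np.zeros((2, 2, 4))
        arr[0, 0] = [2, 1, 0, 1]
        field = phasor_transform(make_stack(arr), intensity_threshold=1.0)
        hist = phasor_histogram(field, bin_count=10)
        assert field.n_valid == 1
        assert hist.counts.sum() == 1 and hist.counts.max() == 1

    def test_identical_spectra_land_in_one_bin(self):
        arr = np.tile(np.array([1.0, 2.0, 3.0, 1.0]), (3, 3, 1))
        field = phasor_transform(make_stack(arr), intensity_threshold=0.0)
        hist = phasor_histogram(field, bin_count=32)
        assert hist.counts.max() == 9

    def test_noiseless_triplex_scene_has_separated_modes(self, noiseless_stacks):
        from scipy.ndimage import maximum_filter

        _, stacks = noiseless_stacks
        field = phasor_transform(concat_windows(list(stacks)))
        hist = phasor_histogram(field, bin_count=128)
        smoothed = hist.counts
        peaks = (smoothed == maximum_filter(smoothed, size=5)) & (smoothed > 0)
        assert peaks.sum() >= 3
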