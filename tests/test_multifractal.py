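import numpy as np
import pytest

from mfbrain import (
    BinaryMask,
    MeasureGrid,
    analyze_measure,
    box_partition,
    default_q_grid,
    generalized_dimensions,
    legendre_spectrum,
    mass_exponent,
    measure_from_mask,
)
from mfbrain.synthetic import CascadeSpec, cascade_measure


class TestMeasureFromMask:
    def test_normalization(self):
        mask = BinaryMask(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        m = measure_from_mask(mask)
        np.testing.assert_allclose(m.mass, [[0.5, 0.5], [0.0, 0.0]])

    def test_full_mask_uniform(self):
        m = measure_from_mask(BinaryMask(np.ones((4, 4), dtype=np.uint8)))
        np.testing.assert_allclose(m.mass, 1 / 16)

    def test_point_mass(self):
        px = np.zeros((4, 4), dtype=np.uint8)
        px[1, 2] = 1
        m = measure_from_mask(BinaryMask(px))
        assert m.mass.sum() == 1.0 and m.mass[1, 2] == 1.0


class TestBoxPartition:
    def test_uniform_quarters(self):
        m = MeasureGrid(np.full((8, 8), 1 / 64))
        t = box_partition(m, scales=[4], q_grid=np.array([0.0, 1.0, 2.0]))
        assert t.n_boxes[0] == 4
        # ln sum P^2 with four boxes of 0.25 each
        assert t.log_moments[0, 2] == pytest.approx(np.log(4 * 0.25**2))

    def test_point_mass_moments_vanish(self):
        mass = np.zeros((8, 8))
        mass[3, 3] = 1.0
        t = box_partition(MeasureGrid(mass), scales=[2, 4], q_grid=np.array([-2.0, 0.0, 2.0]))
        assert (t.n_boxes == 1).all()
        np.testing.assert_allclose(t.log_moments, 0.0, atol=1e-12)

    def test_direct_sum_small_case(self):
        m = MeasureGrid(np.array([[0.5, 0.5], [0.0, 0.0]]))
        t = box_partition(m, scales=[1], q_grid=np.array([0.0, 1.0, 2.0]))
        assert t.n_boxes[0] == 2
        assert t.log_moments[0, 2] == pytest.approx(np.log(0.5))

    def test_scale_exceeding_grid_rejected(self, uniform64):
        with pytest.raises(ValueError):
            box_partition(uniform64, scales=[128])

    def test_per_scale_probabilities_sum_to_one(self, cascade7):
        t = box_partition(cascade7, q_grid=np.array([0.0, 1.0]))
        # ln sum P^... at q=0 counts boxes; recompute sum at q=1 via exp of moment at q close to 1
        t2 = box_partition(cascade7, q_grid=np.array([0.9999]))
        np.testing.assert_allclose(np.exp(t2.log_moments[:, 0]), 1.0, atol=1e-3)

    def test_occupied_boxes_non_increasing_in_scale(self, cascade7):
        t = box_partition(cascade7, q_grid=np.array([0.0]))
        assert (np.diff(t.n_boxes) <= 0).all()

    def test_translation_invariance_under_zero_padding(self, cascade7):
        q = np.array([-2.0, 0.0, 2.0])
        scales = [2, 4, 8]
        t0 = box_partition(cascade7, scales=scales, q_grid=q)
        padded = np.pad(cascade7.mass, ((8, 8), (8, 8)))
        t1 = box_partition(MeasureGrid(padded), scales=scales, q_grid=q)
        np.testing.assert_allclose(t1.log_moments, t0.log_moments, atol=1e-9)


class TestGeneralizedDimensions:
    def test_uniform_measure_is_space_filling(self, uniform64):
        gen, _ = analyze_measure(uniform64)
        np.testing.assert_allclose(gen.d_q, 2.0, atol=1e-6)
        assert (gen.r_squared >= 1 - 1e-12).all()

    def test_cascade_matches_closed_form(self, cascade7_spectra, cascade_oracle):
        gen, _ = cascade7_spectra
        assert np.abs(gen.d_q - cascade_oracle["D_q"].to_numpy()).max() < 0.05

    def test_cascade_d1_d2_values(self, cascade7_spectra):
        gen, _ = cascade7_spectra
        p = np.array([0.4, 0.3, 0.2, 0.1])
        assert gen.d2 == pytest.approx(-np.log2(np.sum(p**2)), abs=0.05)
        assert gen.d1 == pytest.approx(-np.sum(p * np.log2(p)), abs=0.05)

    def test_multifractal_ordering(self, cascade7_spectra, uniform64):
        gen, _ = cascade7_spectra
        assert gen.d0 > gen.d1 > gen.d2
        ugen, _ = analyze_measure(uniform64)
        assert abs(ugen.d0 - ugen.d1) < 0.01 and abs(ugen.d1 - ugen.d2) < 0.01

    def test_d_q_non_increasing_in_q(self, cascade7_spectra):
        gen, _ = cascade7_spectra
        assert (np.diff(gen.d_q) <= 0.02).all()

    def test_too_few_scales_rejected(self, cascade7):
        t = box_partition(cascade7, scales=[2, 4], q_grid=np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            generalized_dimensions(t)


class TestSingularitySpectrum:
    def test_monofractal_constant_alpha(self):
        q = default_q_grid()
        tau = 2.0 * (q - 1.0)
        sing = legendre_spectrum(tau, q)
        np.testing.assert_allclose(sing.alpha, 2.0, atol=1e-12)
        np.testing.assert_allclose(sing.f_alpha, 2.0, atol=1e-12)

    def test_tau_identities(self, cascade7_spectra):
        gen, sing = cascade7_spectra
        i1 = np.flatnonzero(gen.q_grid == 1.0)[0]
        i0 = np.flatnonzero(gen.q_grid == 0.0)[0]
        assert abs(sing.tau[i1]) < 1e-9
        assert abs(sing.f_alpha[i0] - gen.d0) < 1e-9
        assert sing.tau[i0] == pytest.approx(-gen.d0)

    def test_alpha_at_zero_matches_closed_form(self, cascade7_spectra):
        _, sing = cascade7_spectra
        p = np.array([0.4, 0.3, 0.2, 0.1])
        alpha0_exact = -np.mean(np.log2(p))
        i0 = np.flatnonzero(sing.q_grid == 0.0)[0]
        assert sing.alpha[i0] == pytest.approx(alpha0_exact, abs=0.05)

    def test_alpha_tracks_closed_form_everywhere(self, cascade7_spectra, cascade_oracle):
        _, sing = cascade7_spectra
        assert np.abs(sing.alpha - cascade_oracle["alpha"].to_numpy()).max() < 0.05

    def test_f_bounded_by_d0_and_peaks_at_q0(self, cascade7_spectra):
        gen, sing = cascade7_spectra
        assert (sing.f_alpha <= gen.d0 + 0.02).all()
        i0 = np.flatnonzero(sing.q_grid == 0.0)[0]
        assert np.argmax(sing.f_alpha) == i0

    def test_nonuniform_grid_rejected(self):
        q = np.array([-2.0, -1.0, 0.0, 1.0, 3.0])
        with pytest.raises(ValueError):
            legendre_spectrum(np.zeros(5), q)


class TestShuffledCascade:
    def test_moment_sums_permutation_invariant(self):
        spec_d = CascadeSpec((0.4, 0.3, 0.2, 0.1), depth=6)
        spec_s = CascadeSpec((0.4, 0.3, 0.2, 0.1), depth=6, shuffle=True)
        q = np.array([-3.0, -1.0, 0.0, 1.0, 2.0, 3.0])
        td = box_partition(cascade_measure(spec_d), q_grid=q)
        ts = box_partition(cascade_measure(spec_s, seed=11), q_grid=q)
        np.testing.assert_allclose(ts.log_moments, td.log_moments, atol=1e-9)


def test_mass_exponent_monofractal_line():
    q = default_q_grid()

    class FakeSpec:
        q_grid = q
        d_q = np.full_like(q, 2.0)

    tau = mass_exponent(FakeSpec())
    np.testing.assert_allclose(tau, 2.0 * (q - 1.0))
    assert tau[q == 0.0][0] == pytest.approx(-2.0)
    assert tau[q == 1.0][0] == 0.0
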