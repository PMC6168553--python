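import numpy as np
import pytest
from scipy.special import jv

from helifil.layerlines import (
    index_spectrum,
    LayerLine,
    PowerSpectrum,
    assign_bessel_order,
    average_power_spectrum,
    detect_layer_lines,
    first_maximum_of_bessel,
    fit_repeat,
    index_symmetry,
)
from helifil.simulate import ImageStack


def make_line_spectrum(heights, box=256, pixel=1.21, width_rows=1):
    """Spectrum with synthetic layer lines at given heights (Å⁻¹)."""
    step = 1.0 / (box * pixel)
    power = np.random.default_rng(0).uniform(0, 1e-3, (box, box))
    o = box // 2
    for h in heights:
        row = o + int(round(h / step))
        power[row - width_rows + 1 : row + width_rows, o - 60 : o + 60] += 10.0
        mate = 2 * o - row
        power[mate - width_rows + 1 : mate + width_rows, o - 60 : o + 60] += 10.0
    power[o, :] = 0
    return PowerSpectrum(power, step, step)


class TestAveragePowerSpectrum:
    def test_constant_image_concentrates_at_origin(self):
        ps = average_power_spectrum(ImageStack(np.ones((1, 64, 64)), 1.0), axial_pad=1)
        off = ps.power.copy()
        off[ps.origin] = 0
        assert off.max() == pytest.approx(0.0, abs=1e-12)
        assert ps.power[ps.origin] > 0

    def test_horizontal_sinusoid_gives_equatorial_peaks(self):
        x = np.arange(100)
        img = np.tile(np.sin(2 * np.pi * x / 10), (100, 1))
        ps = average_power_spectrum(ImageStack(img[None], 1.0))
        oy, ox = ps.origin
        eq = ps.power[oy].copy()
        top2 = np.argsort(eq)[-2:]
        assert sorted(np.abs(top2 - ox)) == [10, 10]  # ±1/10 px⁻¹

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            average_power_spectrum(ImageStack(np.empty((0, 8, 8)), 1.0))

    def test_friedel_symmetry_of_real_image_spectrum(self, noiseless_spectrum):
        p = noiseless_spectrum.power
        inner = p[1:, 1:]
        asym = np.abs(inner - inner[::-1, ::-1]).max() / p.max()
        assert asym < 1e-6

    def test_sampling_from_pixel_size(self, noiseless_spectrum):
        # default two-fold axial zero-padding halves the row spacing
        assert noiseless_spectrum.axial_step == pytest.approx(1 / (2 * 420 * 1.21))
        assert noiseless_spectrum.radial_step == pytest.approx(1 / (420 * 1.21))


class TestDetectLayerLines:
    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(4)
        ps = PowerSpectrum(rng.uniform(0, 1, (128, 128)), 0.01, 0.01)
        assert detect_layer_lines(ps, min_snr=20.0) == []

    def test_constructed_lines_recovered_within_one_row(self):
        ps = make_line_spectrum([1 / 17.3, 1 / 4.87])
        heights = detect_layer_lines(ps, min_snr=8.0)
        assert len(heights) == 2
        for h, truth in zip(heights, [1 / 17.3, 1 / 4.87]):
            assert abs(h - truth) <= ps.axial_step

    def test_projected_filament_shows_rise_line(self, noiseless_spectrum):
        heights = detect_layer_lines(noiseless_spectrum, min_snr=5.0)
        assert any(abs(h - 1 / 4.848) <= noiseless_spectrum.axial_step for h in heights)

    def test_projected_filament_lines_on_repeat_multiples(self, noiseless_spectrum):
        # 3.56 units/turn = 89/25 exactly, so the true repeat is c = 89 * rise
        c = 89 * 4.848314606741573
        heights = detect_layer_lines(noiseless_spectrum, min_snr=5.0)
        assert len(heights) >= 5
        for h in heights:
            assert abs(h - round(h * c) / c) <= noiseless_spectrum.axial_step


class TestFitRepeat:
    def test_exact_multiples(self):
        c, ls = fit_repeat([1 / 10, 2 / 10, 3 / 10], max_l=10)
        assert c == pytest.approx(10.0)
        assert ls == [1, 2, 3]

    def test_study_line_pair(self):
        c, ls = fit_repeat([9 / 155.8, 32 / 155.8], max_l=40)
        assert c == pytest.approx(155.8, rel=1e-9)
        assert ls == [9, 32]

    @pytest.mark.parametrize("seed", [8, 21, 99])
    def test_jittered_heights_recover_repeat_within_2_percent(self, seed):
        rng = np.random.default_rng(seed)
        truth = 155.8
        ls_true = [1, 2, 3, 4, 5, 6]
        heights = [l / truth * (1 + rng.normal(0, 0.01)) for l in ls_true]
        c, ls = fit_repeat(heights, max_l=40)
        assert ls == ls_true
        assert abs(c - truth) / truth < 0.02

    def test_scale_consistency(self):
        heights = [9 / 155.8, 32 / 155.8]
        c1, _ = fit_repeat(heights, max_l=40)
        c2, _ = fit_repeat([2 * h for h in heights], max_l=40)
        assert c2 == pytest.approx(c1 / 2, rel=1e-9)

    def test_inconsistent_heights_rejected(self):
        with pytest.raises(ValueError, match="indexing"):
            fit_repeat([0.1, 0.1234567, 0.155], max_l=3)

    def test_needs_two_heights(self):
        with pytest.raises(ValueError):
            fit_repeat([0.1], max_l=10)


class TestBesselAssignment:
    def test_first_maximum_matches_fine_scan(self):
        for n in range(1, 8):
            x = np.arange(0.01, 40, 1e-4)
            oracle = x[np.argmax(jv(n, x))]
            assert first_maximum_of_bessel(n) == pytest.approx(oracle, abs=2e-3)

    def test_meridional_line_is_order_zero(self):
        line = LayerLine(32, 1 / 4.87, r_first_max=1e-5)
        n, confident = assign_bessel_order(line, 25.0)
        assert n == 0 and confident

    def test_order_one_from_j1_peak_position(self):
        r_first = 1.8412 / (2 * np.pi * 25.0)
        line = LayerLine(9, 1 / 17.3, r_first_max=r_first)
        n, confident = assign_bessel_order(line, 25.0)
        assert n == 1 and confident

    def test_far_peak_clamps_to_n_max_with_low_confidence(self):
        line = LayerLine(1, 0.1, r_first_max=5.0)
        n, confident = assign_bessel_order(line, 25.0, n_max=3)
        assert n == 3 and not confident


class TestIndexSymmetry:
    def test_study_values(self):
        sym, rep = index_symmetry(155.8, 32, 9, "left")
        assert round(sym.rise_ang, 2) == 4.87
        assert round(sym.pitch_ang, 1) == 17.3
        assert round(rep.units_per_turn, 2) == 3.56
        assert (rep.u, rep.t) == (32, 9)
        assert sym.twist_deg < 0

    def test_simple_values(self):
        sym, rep = index_symmetry(20.0, 4, 1)
        assert sym.rise_ang == pytest.approx(5.0)
        assert sym.pitch_ang == pytest.approx(20.0)
        assert rep.units_per_turn == pytest.approx(4.0)

    def test_non_coprime_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reduced"):
            sym, rep = index_symmetry(155.8, 32, 8)
        assert (rep.u, rep.t) == (4, 1)

    def test_round_trip_on_random_symmetries(self):
        """Lines generated from a random (u, t, rise) helix index back to it."""
        rng = np.random.default_rng(17)
        n_cases = 0
        while n_cases < 200:
            u = int(rng.integers(5, 60))
            t = int(rng.integers(2, 12))
            if np.gcd(u, t) != 1 or u <= t:
                continue
            rise = float(rng.uniform(2.0, 10.0))
            c = u * rise
            sym, rep = index_symmetry(c, u, t)
            assert (rep.u, rep.t) == (u, t)
            assert sym.rise_ang == pytest.approx(rise, rel=1e-12)
            assert sym.units_per_turn == pytest.approx(u / t, rel=1e-12)
            n_cases += 1

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            index_symmetry(155.8, 9, 32)


class TestIndexSpectrumChain:
    def test_noiseless_chain_recovers_symmetry(self, noiseless_spectrum):
        """detect -> fit_repeat -> Bessel assignment -> index reproduces the
        generating twist and rise (3.56 = 89/25, so the repeat is 89 subunits
        in 25 turns over ~431.5 Å)."""
        res = index_spectrum(noiseless_spectrum)
        sym = res["symmetry"]
        assert (res["repeat"].u, res["repeat"].t) == (89, 25)
        assert sym.twist_deg == pytest.approx(-101.1236, abs=1e-3)
        assert sym.rise_ang == pytest.approx(4.8483, abs=0.01)

    def test_noisy_chain_within_fourier_pixel(self, paper_symmetry, signal_sigma):
        from helifil.simulate import NoiseModel, project_segments

        stack = project_segments(
            [(25.0, 0.0, 0.0)], paper_symmetry, 400.0, 10,
            noise=NoiseModel(signal_sigma, seed=3),
        )
        ps = average_power_spectrum(stack)
        res = index_spectrum(ps)
        sym = res["symmetry"]
        # one Fourier pixel on the meridional line maps to ~rise²·step in rise
        rise_tol = 4.85**2 * ps.axial_step
        assert abs(sym.rise_ang - paper_symmetry.rise_ang) < rise_tol
        assert abs(sym.twist_deg - paper_symmetry.twist_deg) < 0.5
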