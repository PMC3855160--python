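"""Extremum detection and coarse-to-fine disparity selection."""

import numpy as np
import pytest

from v1stereo import (ChannelSpec, DisparityHypothesisSet, RunConfig,
                      StereoPair, complex_cell_energy, compose_log_gabor,
                      estimate_disparity, find_local_extrema, preprocess,
                      run_coarse_to_fine, scan_disparities,
                      select_first_scale, select_refine)
from v1stereo.filterbank import build_frequency_grid
from v1stereo.search import EnergyStack
from v1stereo.stereogram import make_stereogram


def brute_force_extrema(profile, disp):
    """Independent oracle: strict interior local extrema by triple scan."""
    out = []
    for i in range(1, len(profile) - 1):
        if profile[i] > profile[i - 1] and profile[i] > profile[i + 1]:
            out.append((disp[i], profile[i], "max"))
        elif profile[i] < profile[i - 1] and profile[i] < profile[i + 1]:
            out.append((disp[i], profile[i], "min"))
    return out


def _stack(profiles, hyps):
    """Wrap 1D profiles (one per pixel) into a (K, 1, P) EnergyStack."""
    arr = np.asarray(profiles, dtype=float).T[:, None, :]
    return EnergyStack(energies=arr, hypotheses=hyps,
                       channel=ChannelSpec(0.0, 8.0))


class TestFindLocalExtrema:
    def test_single_peak(self):
        assert find_local_extrema([1, 5, 1]) == [(1.0, 5.0, "max")]

    def test_monotone_profile_has_none(self):
        assert find_local_extrema([1, 2, 3, 4]) == []

    def test_mixed_profile_matches_hand_scan(self):
        disp = np.arange(-2.0, 3.0)
        got = find_local_extrema([3, 1, 4, 1, 5], disp)
        assert got == [(-1.0, 1.0, "min"), (0.0, 4.0, "max"), (1.0, 1.0, "min")]

    def test_plateau_counts_once_at_center(self):
        got = find_local_extrema([0, 2, 2, 2, 1])
        assert got == [(2.0, 2.0, "max")]

    def test_even_plateau_rounds_toward_smaller_disparity(self):
        disp = np.array([-2.0, -1.0, 0.0, 1.0])
        assert find_local_extrema([0, 3, 3, 1], disp) == [(0.0, 3.0, "max")]

    def test_plateau_touching_endpoint_excluded(self):
        assert find_local_extrema([2, 2, 1, 3]) == [(2.0, 1.0, "min")]

    def test_endpoints_never_extrema(self):
        assert find_local_extrema([5, 1, 4]) == [(1.0, 1.0, "min")]

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            find_local_extrema([1, 2])

    def test_agrees_with_brute_force_on_random_profiles(self, rng):
        disp = np.linspace(-5, 5, 21)
        for _ in range(300):
            p = rng.random(21)
            assert find_local_extrema(p, disp) == brute_force_extrema(p, disp)


class TestSelectFirstScale:
    def test_single_peak_profile(self):
        hyps = DisparityHypothesisSet.from_range(-2, 2, 1.0)
        out = select_first_scale(_stack([[1, 2, 9, 2, 1]], hyps))
        assert out.disparity[0, 0] == 0.0
        assert out.response[0, 0] == 9.0

    def test_biggest_magnitude_rule_prefers_deeper_minimum(self):
        # max of +10 at dx=+2 versus min of -12 at dx=-1: the minimum has
        # the larger |response| magnitude and wins
        hyps = DisparityHypothesisSet.from_range(-3, 3, 1.0)
        profile = [-5, -8, -12, -2, 8, 10, 9]
        out = select_first_scale(_stack([profile], hyps))
        assert out.disparity[0, 0] == -1.0
        assert out.response[0, 0] == -12.0

    def test_no_extremum_falls_back_to_global_maximum(self):
        hyps = DisparityHypothesisSet.from_range(-2, 2, 1.0)
        out = select_first_scale(_stack([[1, 2, 3, 4, 5]], hyps))
        assert out.disparity[0, 0] == 2.0

    def test_equal_magnitude_tie_takes_smaller_offset(self):
        hyps = DisparityHypothesisSet.from_range(-3, 3, 1.0)
        out = select_first_scale(_stack([[0, 7, 0, 1, 0, 7, 0]], hyps))
        assert out.disparity[0, 0] == -2.0  # |-2| == |+2|; ascending order wins

    def test_uniform_disparity_rds_coarsest_channel(self):
        """The best-oriented coarsest channel alone recovers a 2 px uniform
        disparity at >= 90 % of interior pixels."""
        grid = build_frequency_grid(200, 200)
        hyps = DisparityHypothesisSet.from_range(-6, 6, 1.0)
        qf = compose_log_gabor(grid, ChannelSpec(90.0, 12.288))
        fracs = []
        for seed in (1, 2, 3):
            sg = make_stereogram("uniform", seed, uniform_disparity_px=2.0)
            pair = StereoPair(preprocess(sg.left), preprocess(sg.right))
            sel = select_first_scale(scan_disparities(pair, qf, grid, hyps))
            fracs.append(np.mean(sel.disparity[13:-13, 13:-13] == 2.0))
        assert np.mean(fracs) >= 0.90


class TestSelectRefine:
    def _stack_with_extrema(self, hyps, peaks):
        """Profile with local maxima exactly at the given disparities."""
        d = hyps.values
        profile = np.full(d.size, 1.0)
        for p in peaks:
            profile += 5.0 * np.exp(-((d - p) ** 2) / 0.08)
        return _stack([profile], hyps)

    def test_nearest_extremum_wins(self):
        hyps = DisparityHypothesisSet.from_range(-5, 5, 0.25)
        st_ = self._stack_with_extrema(hyps, [1.0, 2.75, -4.0])
        out = select_refine(st_, np.full((1, 1), 3.0))
        assert out.disparity[0, 0] == 2.75

    def test_previous_extremum_is_kept(self):
        hyps = DisparityHypothesisSet.from_range(-5, 5, 0.25)
        st_ = self._stack_with_extrema(hyps, [1.0, -2.0])
        out = select_refine(st_, np.full((1, 1), 1.0))
        assert out.disparity[0, 0] == 1.0

    def test_equidistant_tie_takes_smaller_offset(self):
        # maxima at +1 and +3 with the interleaved minimum at +2; from 1.5
        # the maximum at 1 and the minimum at 2 are equidistant -> smaller |dx|
        hyps = DisparityHypothesisSet.from_range(-5, 5, 1.0)
        st_ = self._stack_with_extrema(hyps, [1.0, 3.0])
        out = select_refine(st_, np.full((1, 1), 1.5))
        assert out.disparity[0, 0] == 1.0

    def test_no_extremum_carries_previous_value(self):
        hyps = DisparityHypothesisSet.from_range(-2, 2, 1.0)
        st_ = _stack([[1, 2, 3, 4, 5]], hyps)
        out = select_refine(st_, np.full((1, 1), -1.0))
        assert out.disparity[0, 0] == -1.0

    def test_dimension_mismatch_rejected(self):
        hyps = DisparityHypothesisSet.from_range(-2, 2, 1.0)
        with pytest.raises(ValueError):
            select_refine(_stack([[1, 5, 1, 5, 1]], hyps), np.zeros((3, 3)))

    def test_refinement_locality_against_brute_force(self, rng):
        """select_refine picks exactly the brute-force nearest extremum."""
        hyps = DisparityHypothesisSet.from_range(-5, 5, 0.5)
        d = hyps.values
        for _ in range(300):
            profile = rng.random(d.size)
            prev = float(rng.choice(d))
            out = select_refine(_stack([profile], hyps), np.full((1, 1), prev))
            ext = brute_force_extrema(profile, d)
            if not ext:
                assert out.disparity[0, 0] == prev
            else:
                dist = min(abs(e[0] - prev) for e in ext)
                cand = [e[0] for e in ext if abs(abs(e[0] - prev) - dist) < 1e-12]
                assert out.disparity[0, 0] == min(cand, key=abs)


class TestScanAndPipeline:
    def test_scan_matches_per_hypothesis_energy(self, grid64, spec8, rng):
        """The upsampled fast scan reproduces the direct per-hypothesis
        computation exactly, including fractional shifts."""
        img_l = preprocess(rng.random((64, 64)))
        img_r = preprocess(rng.random((64, 64)))
        pair = StereoPair(img_l, img_r)
        qf = compose_log_gabor(grid64, spec8)
        for step in (1.0, 0.25):
            hyps = DisparityHypothesisSet.from_range(-3, 3, step)
            st_ = scan_disparities(pair, qf, grid64, hyps)
            for i, d in enumerate(hyps.values):
                direct = complex_cell_energy(pair, qf, grid64, d).energy
                np.testing.assert_allclose(st_.energies[i], direct,
                                           rtol=1e-9, atol=1e-9)

    def test_single_hypothesis_stack(self, grid64, spec8, random_pair):
        qf = compose_log_gabor(grid64, spec8)
        st_ = scan_disparities(random_pair, qf, grid64,
                               DisparityHypothesisSet(np.array([1.5]), 1.0))
        assert st_.energies.shape == (1, 64, 64)

    def test_contrast_scaling_is_quadratic(self, grid64, spec8, rng):
        img = preprocess(rng.random((64, 64)))
        hyps = DisparityHypothesisSet.from_range(-2, 2, 1.0)
        qf = compose_log_gabor(grid64, spec8)
        e1 = scan_disparities(StereoPair(img, img), qf, grid64, hyps).energies
        e2 = scan_disparities(StereoPair(2 * img, 2 * img), qf, grid64, hyps).energies
        np.testing.assert_allclose(e2, 4.0 * e1, rtol=1e-10)

    def test_empty_hypotheses_rejected(self, grid64, spec8, random_pair):
        with pytest.raises(ValueError):
            DisparityHypothesisSet(np.array([]), 1.0)

    def test_mirror_orientations_share_energy(self, grid64, random_pair):
        hyps = DisparityHypothesisSet.from_range(-2, 2, 0.5)
        for theta in (30.0, 90.0):
            a = scan_disparities(random_pair,
                                 compose_log_gabor(grid64, ChannelSpec(theta, 6.0)),
                                 grid64, hyps)
            b = scan_disparities(random_pair,
                                 compose_log_gabor(grid64, ChannelSpec(theta + 180.0, 6.0)),
                                 grid64, hyps)
            np.testing.assert_allclose(a.energies, b.energies, rtol=1e-9, atol=1e-12)

    def test_one_map_per_orientation_scale_combination(self):
        sg = make_stereogram("uniform", 0, size=64, uniform_disparity_px=1.0)
        cfg = RunConfig(disparity_min=-3, disparity_max=3)
        _, maps = estimate_disparity(sg.left, sg.right, cfg)
        assert len(maps) == 24
        combos = {(m.channel.orientation_deg, m.channel.wavelength_px) for m in maps}
        assert len(combos) == 24

    def test_single_channel_bank_equals_select_first(self, grid64, random_pair):
        cfg = RunConfig(orientations_deg=(30.0,), n_scales=1,
                        disparity_min=-3, disparity_max=3)
        bank = cfg.make_bank()
        hyps = cfg.hypotheses()
        maps = run_coarse_to_fine(random_pair, bank, grid64, hyps)
        qf = compose_log_gabor(grid64, bank.channels[0])
        direct = select_first_scale(scan_disparities(random_pair, qf, grid64, hyps))
        np.testing.assert_array_equal(maps[0].disparity, direct.disparity)

    def test_estimates_stay_in_hypothesis_set_and_deterministic(self):
        sg = make_stereogram("ramp", 5, size=64)
        cfg = RunConfig(disparity_min=-3, disparity_max=3, disparity_step=0.25)
        final_a, maps_a = estimate_disparity(sg.left, sg.right, cfg)
        final_b, _ = estimate_disparity(sg.left, sg.right, cfg)
        values = cfg.hypotheses().values
        for m in maps_a:
            assert np.isin(m.disparity, values).all()
        np.testing.assert_array_equal(final_a.disparity, final_b.disparity)

    def test_zero_disparity_pair_maps_near_zero(self):
        """Identical dot fields: every channel map is within one step of zero
        almost everywhere, and the pooled map at >= 95 % of interior pixels."""
        sg = make_stereogram("uniform", 9, uniform_disparity_px=0.0)
        final, maps = estimate_disparity(sg.left, sg.right, RunConfig())
        for m in maps:
            frac = np.mean(np.abs(m.disparity[13:-13, 13:-13]) <= 1.0)
            assert frac >= 0.88
        pooled = np.mean(np.abs(final.disparity[13:-13, 13:-13]) <= 1.0)
        assert pooled >= 0.95


    def test_optional_energy_smoothing_flag(self, grid64, spec8, rng):
        """Box smoothing is off by default and, when enabled, averages the
        energy maps without changing their shape or hypothesis grid."""
        from v1stereo import compose_log_gabor
        img_l = preprocess(rng.random((64, 64)))
        img_r = preprocess(rng.random((64, 64)))
        pair = StereoPair(img_l, img_r)
        qf = compose_log_gabor(grid64, spec8)
        hyps = DisparityHypothesisSet.from_range(-2, 2, 1.0)
        plain = scan_disparities(pair, qf, grid64, hyps)
        smoothed = scan_disparities(pair, qf, grid64, hyps, smooth_px=5)
        assert smoothed.energies.shape == plain.energies.shape
        assert not np.allclose(smoothed.energies, plain.energies)
        np.testing.assert_allclose(smoothed.energies.mean(), plain.energies.mean())
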