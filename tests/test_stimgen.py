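"""Stimulus generator: geometry, lifetimes, mirror invariants, foil matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symspeed import stimgen
from symspeed.stimgen import (StimulusParams, advance_frame, assign_directions,
                              assign_speeds, compute_lifetime, frames_to_table,
                              make_symmetric_pattern, make_trial, render_frames)


class TestComputeLifetime:
    @pytest.mark.parametrize(
        "speed, frames, ms, tf",
        [
            (3.33, 30, 352.94, 2.83),
            (6.67, 15, 176.47, 5.67),
            (10.0, 10, 117.65, 8.5),
            (5.9, 17, 200.00, 5.0),  # travel time an exact frame multiple
        ],
    )
    def test_frame_quantized_lifetimes(self, speed, frames, ms, tf):
        info = compute_lifetime(speed, 1.18, 85)
        assert info.frames == frames
        assert info.ms == pytest.approx(ms, abs=0.005)
        assert info.temporal_frequency_hz == pytest.approx(tf, abs=0.005)

    def test_effective_speed_consistent_with_quantized_lifetime(self):
        info = compute_lifetime(10.0, 1.18, 85)
        assert info.effective_speed == pytest.approx(1.18 / (info.frames / 85))
        assert info.effective_speed == pytest.approx(10.03)

    @pytest.mark.parametrize("bad", [(0, 1.18, 85), (3.33, -1, 85), (3.33, 1.18, 0)])
    def test_non_positive_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_lifetime(*bad)

    @given(speed=st.floats(0.5, 20), travel=st.floats(0.5, 3), rate=st.floats(30, 144))
    @settings(max_examples=50, derandomize=True)
    def test_postconditions_hold_generally(self, speed, travel, rate):
        info = compute_lifetime(speed, travel, rate)
        assert info.frames == round(travel / speed * rate)
        assert info.ms == pytest.approx(info.frames / rate * 1000)
        assert info.temporal_frequency_hz == pytest.approx(1000 / info.ms)


class TestGeometry:
    def test_default_dot_density_matches_display(self, default_params):
        assert round(default_params.dot_density, 2) == 0.17

    def test_default_frame_count(self, default_params):
        assert default_params.n_frames == 34

    def test_odd_symmetric_count_rejected(self, default_params, rng):
        with pytest.raises(ValueError):
            make_symmetric_pattern(default_params, 7, rng)

    def test_too_many_symmetric_dots_rejected(self, default_params, rng):
        with pytest.raises(ValueError):
            make_symmetric_pattern(default_params, 34, rng)


class TestPatternConstruction:
    def test_full_symmetry_gives_16_mirrored_pairs(self, default_params, rng):
        pat = make_symmetric_pattern(default_params, 32, rng)
        assert len(np.unique(pat.pair_id)) == 16
        assert pat.check_mirror()

    def test_pure_noise_pattern_balanced_across_halves(self, default_params, rng):
        pat = make_symmetric_pattern(default_params, 0, rng)
        assert (pat.pair_id == -1).all()
        assert (pat.x < 0).sum() == 16

    def test_half_symmetry_composition(self, default_params, rng):
        pat = make_symmetric_pattern(default_params, 16, rng)
        assert len(np.unique(pat.pair_id[pat.pair_id >= 0])) == 8
        noise = pat.pair_id < 0
        assert noise.sum() == 16
        assert (pat.x[noise] < 0).sum() == 8

    def test_pair_members_share_age_and_lifetime(self, default_params, rng):
        pat = make_symmetric_pattern(default_params, 16, rng)
        for pid in range(8):
            i, j = np.flatnonzero(pat.pair_id == pid)
            assert pat.age[i] == pat.age[j]
            assert pat.lifetime[i] == pat.lifetime[j]

    def test_min_separation_flag_enforced(self, rng):
        params = StimulusParams(min_separation=0.24)
        pat = make_symmetric_pattern(params, 16, rng)
        d = np.hypot(pat.x[:, None] - pat.x[None, :], pat.y[:, None] - pat.y[None, :])
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.24


class TestDirections:
    def test_pair_directions_are_mirror_images(self, default_params, rng):
        pat = assign_directions(make_symmetric_pattern(default_params, 32, rng), rng)
        assert pat.check_mirror()

    def test_noise_direction_multisets_mirror_across_halves(self, default_params, rng):
        pat = assign_directions(make_symmetric_pattern(default_params, 0, rng), rng)
        left = np.sort(pat.direction[pat.birth_half < 0])
        right = np.sort((np.pi - pat.direction[pat.birth_half > 0]) % (2 * np.pi))
        np.testing.assert_allclose(np.sort(left % (2 * np.pi)), right, atol=1e-12)

    def test_different_seeds_differ_but_keep_mirror_property(self, default_params):
        pat0 = make_symmetric_pattern(default_params, 16, 0)
        a = assign_directions(pat0, 1)
        b = assign_directions(pat0, 2)
        assert not np.allclose(a.direction, b.direction)
        for pat in (a, b):
            left = np.sort(pat.direction[(pat.pair_id < 0) & (pat.birth_half < 0)])
            right = np.sort((np.pi - pat.direction[(pat.pair_id < 0) & (pat.birth_half > 0)])
                            % (2 * np.pi))
            np.testing.assert_allclose(left % (2 * np.pi), right, atol=1e-12)


class TestSpeeds:
    def _pattern(self, rng):
        params = StimulusParams(speeds=(3.33, 10.0))
        return params, assign_directions(make_symmetric_pattern(params, 16, rng), rng)

    def test_speed_condition_splits_by_symmetry(self, rng):
        params, pat = self._pattern(rng)
        out = assign_speeds(pat, "speed", (3.33, 10.0), rng, params)
        assert (out.speed[out.is_symmetric] == 3.33).all()
        assert (out.speed[~out.is_symmetric] == 10.0).all()

    def test_segregated_condition_randomizes_symmetry_speed(self, rng):
        params, pat = self._pattern(rng)
        chosen = set()
        for seed in range(20):
            out = assign_speeds(pat, "segregated", (3.33, 10.0), seed, params)
            sym_speeds = np.unique(out.speed[out.is_symmetric])
            noise_speeds = np.unique(out.speed[~out.is_symmetric])
            assert sym_speeds.size == 1 and noise_speeds.size == 1
            assert sym_speeds[0] != noise_speeds[0]
            chosen.add(float(sym_speeds[0]))
        assert chosen == {3.33, 10.0}  # both assignments occur across seeds

    def test_non_segregated_condition_splits_half_half(self, rng):
        params, pat = self._pattern(rng)
        out = assign_speeds(pat, "non_segregated", (3.33, 10.0), rng, params)
        sym = out.is_symmetric
        assert (out.speed[sym] == 3.33).sum() == 8
        assert (out.speed[~sym] == 3.33).sum() == 8
        for pid in np.unique(out.pair_id[sym]):
            members = out.pair_id == pid
            assert np.unique(out.speed[members]).size == 1

    def test_equal_speeds_degenerate_to_single_speed(self, rng):
        params, pat = self._pattern(rng)
        out = assign_speeds(pat, "speed", (6.67, 6.67), rng, params)
        assert (out.speed == 6.67).all()

    def test_unknown_condition_rejected(self, rng):
        params, pat = self._pattern(rng)
        with pytest.raises(ValueError):
            assign_speeds(pat, "flicker", (3.33, 10.0), rng, params)


class TestAdvanceFrame:
    def test_single_frame_kinematics(self, rng):
        params = StimulusParams()
        pat = assign_directions(make_symmetric_pattern(params, 0, rng), rng)
        pat.age[:] = 0  # nobody dies this frame
        out = advance_frame(pat, "speed", params, rng)
        step = pat.speed / params.refresh_rate
        fresh = out.age == 1  # exclude dots relocated after leaving the window
        np.testing.assert_allclose(out.x[fresh], (pat.x + step * np.cos(pat.direction))[fresh])
        np.testing.assert_allclose(out.y[fresh], (pat.y + step * np.sin(pat.direction))[fresh])

    def test_static_condition_is_frozen(self, rng):
        params = StimulusParams(condition="static")
        pat = assign_directions(make_symmetric_pattern(params, 16, rng), rng)
        out = advance_frame(pat, "static", params, rng)
        np.testing.assert_array_equal(out.x, pat.x)
        np.testing.assert_array_equal(out.age, pat.age)

    def test_flicker_relocates_without_displacement(self, rng):
        params = StimulusParams(condition="flicker")
        pat = assign_directions(make_symmetric_pattern(params, 16, rng), rng)
        pat.age[:] = 0
        out = advance_frame(pat, "flicker", params, rng)
        np.testing.assert_array_equal(out.x, pat.x)
        assert (out.age == 1).all()

    def test_expiring_pair_relocates_simultaneously(self, rng):
        params = StimulusParams()
        pat = assign_directions(make_symmetric_pattern(params, 16, rng), rng)
        pid = 3
        members = np.flatnonzero(pat.pair_id == pid)
        pat.age[members] = pat.lifetime[members] - 1
        others = pat.pair_id != pid
        pat.age[others] = 0
        out = advance_frame(pat, "speed", params, rng)
        assert (out.age[members] == 0).all()
        assert not np.allclose(out.x[members], pat.x[members])
        assert out.check_mirror()

    def test_mirror_preserved_over_many_frames(self, rng):
        params = StimulusParams(speeds=(3.33, 10.0), condition="non_segregated")
        pat = assign_directions(make_symmetric_pattern(params, 16, rng), rng)
        pat = assign_speeds(pat, "non_segregated", (3.33, 10.0), rng, params)
        for _ in range(3 * params.n_frames):
            pat = advance_frame(pat, "non_segregated", params, rng)
            assert pat.check_mirror()

    def test_dots_never_escape_the_window(self, rng):
        params = StimulusParams(speeds=(10.0,))
        pat = assign_directions(make_symmetric_pattern(params, 16, rng), rng)
        half = params.window_size / 2
        for _ in range(100):
            pat = advance_frame(pat, "speed", params, rng)
            assert np.abs(pat.x).max() <= half + 1e-9
            assert np.abs(pat.y).max() <= half + 1e-9

    def test_travel_distance_between_birth_and_death(self, rng):
        """A dot observed from birth moves travel_distance before relocation."""
        params = StimulusParams(speeds=(6.67,))
        pat = assign_directions(make_symmetric_pattern(params, 0, rng), rng)
        pat.age[:] = 0
        # place dots centrally so nobody dies early at the boundary
        pat.x[:16] = np.linspace(-2, -0.5, 16)
        pat.x[16:] = np.linspace(0.5, 2, 16)
        pat.y[:] = np.linspace(-2, 2, 32)
        start = (pat.x.copy(), pat.y.copy())
        lifetime = int(pat.lifetime[0])
        for _ in range(lifetime - 1):
            pat = advance_frame(pat, "speed", params, rng)
        moved = np.hypot(pat.x - start[0], pat.y - start[1])
        survivors = pat.age == lifetime - 1
        step = params.speeds[0] / params.refresh_rate
        expected = 1.18
        assert np.all(np.abs(moved[survivors] - expected) <= step + 0.05)


class TestMakeTrial:
    def test_per_speed_counts_match_target_and_foil(self, two_speed_params):
        for seed in range(25):
            target, foil = make_trial(two_speed_params, 16, seed)
            for ft, ff in zip(target.frames, foil.frames):
                for s in two_speed_params.speeds:
                    assert (ft.speed == s).sum() == (ff.speed == s).sum()

    def test_foil_has_no_symmetry(self, two_speed_params):
        _, foil = make_trial(two_speed_params, 16, 0)
        assert all((f.pair_id == -1).all() for f in foil.frames)

    def test_zero_symmetry_target_is_pure_noise(self, two_speed_params):
        target, foil = make_trial(two_speed_params, 0, 0)
        assert all((f.pair_id == -1).all() for f in target.frames)

    def test_identical_seed_identical_sequences(self, two_speed_params):
        t1, f1 = make_trial(two_speed_params, 16, 11)
        t2, f2 = make_trial(two_speed_params, 16, 11)
        for a, b in zip(t1.frames + f1.frames, t2.frames + f2.frames):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.direction, b.direction)

    def test_interval_length_is_34_frames(self, two_speed_params):
        target, foil = make_trial(two_speed_params, 16, 0)
        assert target.n_frames == foil.n_frames == 34

    @given(seed=st.integers(0, 10_000), n_pairs=st.integers(0, 8))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mirror_invariant_any_seed_and_symmetry_level(self, seed, n_pairs):
        params = StimulusParams(condition="segregated", speeds=(3.33, 10.0))
        target, _ = make_trial(params, 2 * n_pairs, seed)
        assert all(f.check_mirror() for f in target.frames)


class TestRendering:
    def test_mirrored_pair_renders_mirror_symmetric_image(self, rng):
        params = StimulusParams(condition="static")
        pat = make_symmetric_pattern(params, 32, rng)
        seq = stimgen.FrameSequence([pat], params, 32)
        img = render_frames(seq, pixels_per_degree=8.0)[0]
        mismatch = (img != img[:, ::-1]).mean()
        assert mismatch < 0.02  # rasterization tolerance

    def test_sequence_exports_one_image_per_frame(self, two_speed_params):
        target, _ = make_trial(two_speed_params, 16, 0)
        stack = render_frames(target, pixels_per_degree=4.0)
        assert stack.shape[0] == 34

    def test_table_export_shape(self, two_speed_params):
        target, _ = make_trial(two_speed_params, 16, 0)
        table = frames_to_table(target)
        assert len(table) == 34 * 32
        assert set(table.columns) >= {"frame", "dot_id", "pair_id", "x_deg", "y_deg"}
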