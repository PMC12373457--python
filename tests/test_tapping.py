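"""Circular statistics, phase mapping, and the composite tapping score."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmap.tapping import (
    CircularSummary,
    TappingScorer,
    TapTrial,
    average_repetitions,
    circular_summary,
    composite_score,
    local_ioi,
    rayleigh_p,
    taps_to_phases,
    trim_trial,
)
from rhythmap.synthetic import TapperProfile, simulate_tapper


def make_trial(taps, beats=None, modality="isochronous", guide_end=0.0):
    if beats is None:
        beats = np.arange(60) * 0.6
    return TapTrial(
        participant="p", stimulus="s", repetition=1, tap_times=taps,
        beat_times=beats, modality=modality, guide_end=guide_end,
    )


class TestTrim:
    def test_isochronous_drops_first_two_taps(self):
        taps = np.arange(60) * 0.6 + 0.05
        out = trim_trial(make_trial(taps))
        assert out.tap_times.size == 58
        np.testing.assert_allclose(out.tap_times, taps[2:])

    def test_music_keeps_only_post_guide_taps(self):
        trial = make_trial([10.9, 11.0, 11.1, 20.0], modality="music", guide_end=11.0)
        out = trim_trial(trial)
        # the threshold is strict: a tap exactly at the guide end is discarded
        np.testing.assert_allclose(out.tap_times, [11.1, 20.0])

    def test_music_all_taps_during_guide_is_flagged_empty(self):
        out = trim_trial(make_trial([1.0, 5.0], modality="music", guide_end=11.0))
        assert out.tap_times.size == 0
        assert out.empty_after_trim


class TestPhases:
    def test_tap_on_beat_is_zero_degrees(self):
        assert taps_to_phases([1.2], np.arange(10) * 0.6)[0] == pytest.approx(0.0)

    def test_offset_maps_linearly_to_phase(self):
        # 150 ms late on a 600 ms grid is a quarter cycle
        phase = taps_to_phases([0.15], np.arange(10) * 0.6)
        assert phase[0] == pytest.approx(90.0)

    def test_midpoint_assigned_to_earlier_beat_as_plus_180(self):
        phase = taps_to_phases([0.3], np.arange(10) * 0.6)
        assert phase[0] == pytest.approx(180.0)

    def test_matches_brute_force_nearest_beat_oracle(self):
        rng = np.random.default_rng(3)
        beats = np.cumsum(rng.uniform(0.4, 0.8, 20))
        taps = rng.uniform(beats[0] - 0.5, beats[-1] + 0.5, 100)
        ioi = local_ioi(beats)

        def oracle(tap):
            d = np.abs(beats - tap)
            best = np.flatnonzero(d == d.min()).min()  # ties -> earlier beat
            p = 360.0 * (tap - beats[best]) / ioi[best]
            p = p - 360.0 * np.ceil((p - 180.0) / 360.0)
            return p

        expected = np.array([oracle(t) for t in taps])
        np.testing.assert_allclose(taps_to_phases(taps, beats), expected, atol=1e-9)

    def test_boundary_taps_are_kept_not_dropped(self):
        beats = np.arange(5) * 0.5
        phases = taps_to_phases([-0.1, 2.3], beats)
        assert phases.size == 2

    @given(
        delta=st.floats(-360, 360),
        phases=st.lists(st.floats(-179.9, 180), min_size=2, max_size=30),
    )
    @settings(max_examples=80, deadline=None)
    def test_rotation_equivariance(self, delta, phases):
        """Adding a constant to every phase rotates theta and preserves R."""
        s0 = circular_summary(phases)
        s1 = circular_summary([p + delta for p in phases])
        assert s1.R == pytest.approx(s0.R, abs=1e-9)
        if not s0.theta_undefined and s0.R > 1e-6:
            expected = s0.theta_deg + delta
            diff = (s1.theta_deg - expected + 180) % 360 - 180
            assert abs(diff) < 1e-6


class TestCircularSummary:
    def test_identical_phases_give_unit_vector(self):
        s = circular_summary([0.0, 0.0, 0.0])
        assert s.R == pytest.approx(1.0)
        assert s.theta_deg == pytest.approx(0.0)

    def test_antipodal_phases_cancel(self):
        s = circular_summary([90.0, -90.0])
        assert s.R == pytest.approx(0.0, abs=1e-12)
        assert s.theta_undefined

    def test_two_phase_example_matches_complex_mean_oracle(self):
        # oracle: |(e^{i30} + e^{i60})/2| = cos(15 deg), arg = 45 deg
        s = circular_summary([30.0, 60.0])
        assert s.R == pytest.approx(np.cos(np.deg2rad(15.0)), abs=1e-12)
        assert s.R == pytest.approx(0.966, abs=5e-4)
        assert s.theta_deg == pytest.approx(45.0)

    def test_empty_input_flags_missing(self):
        s = circular_summary([])
        assert s.missing and s.n_taps == 0

    def test_matches_pingouin_circular_stats(self):
        rng = np.random.default_rng(5)
        ph = np.rad2deg(rng.vonmises(0.5, 3.0, 80))
        s = circular_summary(ph)
        assert s.R == pytest.approx(pg.circ_r(np.deg2rad(ph)), abs=1e-10)
        assert np.deg2rad(s.theta_deg) == pytest.approx(
            pg.circ_mean(np.deg2rad(ph)), abs=1e-10
        )
        _, p_pg = pg.circ_rayleigh(np.deg2rad(ph))
        assert s.rayleigh_p == pytest.approx(p_pg, rel=1e-6)

    def test_rayleigh_p_is_one_for_uniform_limit_and_small_for_concentrated(self):
        assert rayleigh_p(0.0, 50) == pytest.approx(1.0)
        assert rayleigh_p(0.9, 50) < 1e-10


class TestAverageRepetitions:
    def test_identical_summaries_unchanged(self):
        s = circular_summary([10.0, 20.0, 30.0])
        avg = average_repetitions(s, s)
        assert avg.R == pytest.approx(s.R)
        assert avg.theta_deg == pytest.approx(s.theta_deg)

    def test_scalar_r_and_circular_theta_averaging(self):
        s1 = CircularSummary(R=0.8, theta_deg=10.0, n_taps=50, rayleigh_p=0.001)
        s2 = CircularSummary(R=0.6, theta_deg=-10.0, n_taps=50, rayleigh_p=0.001)
        avg = average_repetitions(s1, s2)
        assert avg.R == pytest.approx(0.7)
        assert avg.theta_deg == pytest.approx(0.0, abs=1e-10)

    def test_single_usable_repetition_is_returned_with_note(self):
        s1 = circular_summary([5.0, 6.0])
        missing = circular_summary([])
        avg = average_repetitions(s1, missing)
        assert avg.R == pytest.approx(s1.R)
        assert "single" in avg.note

    def test_both_missing_flags_missing(self):
        avg = average_repetitions(circular_summary([]), None)
        assert avg.missing


class TestComposite:
    @staticmethod
    def summaries(R, theta, undefined=False):
        return {
            f"s{i}": CircularSummary(
                R=R, theta_deg=theta, n_taps=58, rayleigh_p=0.01,
                theta_undefined=undefined,
            )
            for i in range(9)
        }

    def test_perfect_tapper_scores_90(self):
        assert composite_score(self.summaries(1.0, 0.0)).value == pytest.approx(90.0)

    def test_chance_tapper_scores_minus_90(self):
        # R=0 with the worst-case angle substitution for undefined theta
        cs = composite_score(self.summaries(0.0, float("nan"), undefined=True))
        assert cs.value == pytest.approx(-90.0)

    def test_intermediate_example(self):
        # (9*90 + 9*(-45)) / 18 = 22.5
        assert composite_score(self.summaries(0.5, -45.0)).value == pytest.approx(22.5)

    def test_wrong_stimulus_count_raises(self):
        s = self.summaries(0.5, 0.0)
        del s["s0"]
        with pytest.raises(ValueError, match="9"):
            composite_score(s)

    def test_missing_stimulus_named_in_error(self):
        s = self.summaries(0.5, 0.0)
        s["s3"] = circular_summary([])
        with pytest.raises(ValueError, match="s3"):
            composite_score(s)

    @given(
        r_lo=st.floats(0, 1), r_hi=st.floats(0, 1),
        theta=st.floats(-180, 180, exclude_min=True),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_R_and_abs_theta(self, r_lo, r_hi, theta):
        lo, hi = sorted([r_lo, r_hi])
        v_lo = composite_score(self.summaries(lo, theta)).value
        v_hi = composite_score(self.summaries(hi, theta)).value
        assert v_hi >= v_lo - 1e-12
        v_worse_angle = composite_score(self.summaries(lo, 179.0)).value
        assert v_worse_angle <= composite_score(self.summaries(lo, 1.0)).value


class TestScorer:
    def test_fifteen_trials_collapse_to_nine_stimuli_and_one_composite(self, stimuli):
        profile = TapperProfile(mean_phase_deg=-20, concentration_kappa=8,
                                participant="p01")
        trials = simulate_tapper(profile, stimuli, seed=1)
        assert len(trials) == 15  # 3 isochronous + 6 music x 2 repetitions
        scorer = TappingScorer().fit(trials)
        assert len(scorer.stimulus_summaries_) == 9
        assert len(scorer.composite_scores_) == 1
        value = scorer.composite_scores_["composite"].iloc[0]
        assert -90 <= value <= 90

    def test_good_tapper_outscores_chance_tapper(self, stimuli):
        good = simulate_tapper(
            TapperProfile(concentration_kappa=12, participant="good"), stimuli, seed=2
        )
        bad = simulate_tapper(
            TapperProfile(is_chance_tapper=True, participant="bad"), stimuli, seed=2
        )
        scores = TappingScorer().fit(good + bad).composite_scores_
        by = scores.set_index("participant")["composite"]
        assert by["good"] > by["bad"] + 50

    def test_params_roundtrip(self):
        sc = TappingScorer(trim=False)
        assert sc.get_params()["trim"] is False
        sc.set_params(trim=True)
        assert sc.trim is True
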