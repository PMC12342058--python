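"""Generator behavior: hypnogram structure, homeostat dynamics, signal
content, artifact injection, arena walks and cohort assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import somnostress as ss
from somnostress.synth import EPOCHS_PER_DAY

from conftest import make_hypnogram


class TestHypnogram:
    def test_one_day_has_8640_epochs(self, day_bundle):
        assert day_bundle["hyp"].n_epochs == EPOCHS_PER_DAY == 8640

    def test_forced_wake_window_has_zero_sleep(self):
        params = ss.SimParams.from_preset("female_susceptible", seed=3)
        sched = ss.ProtocolSchedule(
            days=[ss.DayPlan(0, "sleep_restriction", forced_wake_window=(0.0, 6.0))]
        )
        hyp = ss.simulate_hypnogram(params, sched)
        mins = ss.state_minutes(hyp, (0.0, 6.0))
        assert mins[ss.NREM] == 0.0 and mins[ss.REM] == 0.0
        assert mins[ss.WAKE] == 360.0

    def test_absorbing_nrem_gives_two_bouts(self, one_day_schedule):
        params = ss.SimParams(
            state_dwell={(s, p): 1e12 if s == ss.NREM else 1.0
                         for s in (ss.WAKE, ss.NREM, ss.REM)
                         for p in ("light", "dark")},
            seed=0,
        )
        hyp = ss.simulate_hypnogram(params, one_day_schedule)
        bouts = ss.segment_bouts(hyp)
        assert list(bouts["state"]) == [ss.WAKE, ss.NREM]
        assert bouts["n_epochs"].iloc[0] == 1

    def test_label_closure_and_determinism(self, one_day_schedule):
        params = ss.SimParams.from_preset("male_resilient", seed=9)
        h1 = ss.simulate_hypnogram(params, one_day_schedule)
        h2 = ss.simulate_hypnogram(params, one_day_schedule)
        assert set(h1.states) <= set(ss.STATES)
        assert np.array_equal(h1.states, h2.states)

    def test_rem_only_entered_from_nrem(self, day_bundle):
        states = day_bundle["hyp"].states
        rem_starts = [i for i in range(1, len(states))
                      if states[i] == ss.REM and states[i - 1] != ss.REM]
        assert all(states[i - 1] == ss.NREM for i in rem_starts)

    def test_wake_to_rem_weight_rejected(self):
        with pytest.raises(ValueError, match="REM may only be entered from NREM"):
            ss.SimParams(transition_weights={(ss.WAKE, "light"): {ss.REM: 0.5}})


class TestHomeostat:
    def test_fixed_points_at_bounds(self):
        p = ss.SimParams()
        lo, hi = p.s_bounds
        assert ss.update_homeostat(ss.HomeostatState(hi), ss.WAKE, p).s_value == pytest.approx(hi)
        assert ss.update_homeostat(ss.HomeostatState(lo), ss.NREM, p).s_value == pytest.approx(lo)

    def test_six_hour_wake_matches_closed_form(self):
        p = ss.SimParams()
        lo, hi = p.s_bounds
        tau = p.s_tau_rise_h * 3600.0
        state = ss.HomeostatState(lo)
        for k in range(1, 6 * 360 + 1):
            state = ss.update_homeostat(state, ss.WAKE, p)
            expected = hi - (hi - lo) * math.exp(-k * p.epoch_s / tau)
            assert state.s_value == pytest.approx(expected, rel=1e-9)

    def test_nondecreasing_under_forced_wake(self):
        p = ss.SimParams()
        state = ss.HomeostatState(0.3)
        values = []
        for _ in range(100):
            state = ss.update_homeostat(state, ss.WAKE, p)
            values.append(state.s_value)
        assert np.all(np.diff(values) >= 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.sampled_from(["W", "N", "R", "A"]), min_size=1, max_size=400))
    def test_bounded_for_arbitrary_label_sequences(self, labels):
        p = ss.SimParams()
        lo, hi = p.s_bounds
        hyp = make_hypnogram("".join(labels))
        s = ss.homeostat_trajectory(hyp, p)
        assert np.all((s >= lo - 1e-12) & (s <= hi + 1e-12))


class TestSignals:
    def test_nrem_delta_power_monotone_in_s(self):
        p = ss.SimParams()
        hyp = make_hypnogram("NN")
        rec = ss.synthesize_signals(hyp, [0.3, 0.6], p, seed=5)
        bp = ss.epoch_band_powers(rec.channels["eeg_frontal"], rec.fs)
        assert bp["delta"].iloc[1] > bp["delta"].iloc[0]

    def test_rem_epoch_theta_dominates_delta(self):
        p = ss.SimParams()
        hyp = make_hypnogram("R" * 6)
        rec = ss.synthesize_signals(hyp, [0.5] * 6, p, seed=2)
        bp = ss.epoch_band_powers(rec.channels["eeg_frontal"], rec.fs)
        assert (bp["theta"] / bp["delta"] > 1).all()

    def test_emg_scale_ordering(self, day_bundle, day_features):
        hyp, f = day_bundle["hyp"], day_features
        med = {s: np.median(f["emg_rms"][hyp.mask(s)]) for s in (ss.WAKE, ss.NREM, ss.REM)}
        assert med[ss.WAKE] > med[ss.NREM] > med[ss.REM]

    def test_spectral_fidelity_across_states(self, day_bundle, day_features):
        hyp, f = day_bundle["hyp"], day_features
        assert f["delta"][hyp.mask(ss.NREM)].mean() > f["delta"][hyp.mask(ss.WAKE)].mean()
        ratio = f["theta"] / f["delta"]
        assert ratio[hyp.mask(ss.REM)].mean() > ratio[hyp.mask(ss.NREM)].mean()

    def test_seed_determinism(self):
        p = ss.SimParams()
        hyp = make_hypnogram("WNRW")
        r1 = ss.synthesize_signals(hyp, [0.5] * 4, p, seed=7)
        r2 = ss.synthesize_signals(hyp, [0.5] * 4, p, seed=7)
        for ch in r1.channels:
            assert np.array_equal(r1.channels[ch], r2.channels[ch])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal epoch count"):
            ss.synthesize_signals(make_hypnogram("WN"), [0.5], ss.SimParams())

    def test_truth_band_powers_match_measured(self, day_bundle, day_features):
        truth = ss.truth_band_powers(day_bundle["hyp"], day_bundle["s"],
                                     day_bundle["params"])
        # exact per-epoch rms normalisation: analytic delta ~ measured delta
        rel = (day_features["delta"] - truth["delta"]) / truth["delta"]
        assert np.nanmax(np.abs(rel)) < 0.05


class TestArtifacts:
    def test_fraction_zero_returns_inputs_unchanged(self, day_bundle):
        rec, hyp = ss.inject_artifacts(day_bundle["rec"], day_bundle["hyp"], 0.0)
        assert rec is day_bundle["rec"] and hyp is day_bundle["hyp"]

    @pytest.mark.parametrize("fraction,expected", [(0.06, 518), (1.0, 8640)])
    def test_artifact_epoch_counts(self, day_bundle, fraction, expected):
        _, hyp = ss.inject_artifacts(day_bundle["rec"], day_bundle["hyp"],
                                     fraction, seed=1)
        assert int(np.sum(hyp.mask(ss.ARTIFACT))) == expected

    def test_positions_reproducible_by_seed(self, day_bundle):
        _, h1 = ss.inject_artifacts(day_bundle["rec"], day_bundle["hyp"], 0.02, seed=5)
        _, h2 = ss.inject_artifacts(day_bundle["rec"], day_bundle["hyp"], 0.02, seed=5)
        assert np.array_equal(h1.states, h2.states)


class TestArena:
    def test_zero_bias_is_symmetric(self):
        spec = ss.ArenaSpec()
        tf, te = [], []
        for seed in range(120):
            empty, target = ss.simulate_arena(spec, 0.0, seed=seed)
            te.append(ss.zone_time(empty))
            tf.append(ss.zone_time(target))
        assert np.mean(tf) == pytest.approx(np.mean(te), rel=0.05)
        sirs = np.array(tf) / np.array(te)
        assert 0.9 < np.mean(sirs) < 1.1

    def test_strong_attraction_classified_resilient(self):
        empty, target = ss.simulate_arena(ss.ArenaSpec(), 1.0, seed=0)
        res = ss.score_interaction_test(empty, target)
        assert res["sir"] > 1.1 and res["phenotype"] == "resilient"

    def test_mean_sir_monotone_in_bias(self):
        spec = ss.ArenaSpec()
        means = []
        for bias in (-0.25, 0.0, 0.25):
            sirs = []
            for seed in range(200):
                empty, target = ss.simulate_arena(spec, bias, seed=seed)
                sirs.append(ss.zone_time(target) / ss.zone_time(empty))
            means.append(np.mean(sirs))
        assert means[0] < means[1] < means[2]

    def test_trajectories_stay_inside_arena(self):
        empty, target = ss.simulate_arena(ss.ArenaSpec(), 0.5, seed=3)
        for tr in (empty, target):
            assert tr.x_cm.min() >= 0 and tr.x_cm.max() <= 30
            assert tr.y_cm.min() >= 0 and tr.y_cm.max() <= 30


class TestCohort:
    def test_two_pairs_four_subjects_thirteen_plus_days(self, tmp_path):
        bundle = ss.simulate_cohort(2, seed=4, synthesize=False,
                                    out_dir=tmp_path / "cohort")
        assert len(bundle.design) == 4
        assert bundle.schedule.n_days >= 13
        assert (tmp_path / "cohort" / "manifest.json").exists()

    def test_same_master_seed_byte_identical_manifest(self, tmp_path):
        for d in ("a", "b"):
            ss.simulate_cohort(1, seed=77, synthesize=False, out_dir=tmp_path / d)
        m1 = (tmp_path / "a" / "manifest.json").read_bytes()
        m2 = (tmp_path / "b" / "manifest.json").read_bytes()
        assert m1 == m2
        f1 = sorted((tmp_path / "a").glob("*.csv"))
        for p1 in f1:
            assert p1.read_bytes() == (tmp_path / "b" / p1.name).read_bytes()

    def test_female_susceptible_gains_nrem_after_defeat(self):
        """Post-defeat NREM exceeds baseline NREM in expectation (50 seeds)."""
        sched = ss.ProtocolSchedule(days=[ss.DayPlan(0, "baseline"),
                                         ss.DayPlan(1, "post_defeat")])
        deltas = []
        for seed in range(50):
            p = ss.SimParams.from_preset("female_susceptible", seed=seed)
            hyp = ss.simulate_hypnogram(p, sched)
            base = ss.Hypnogram(hyp.states[:8640])
            post = ss.Hypnogram(hyp.states[8640:])
            deltas.append(ss.state_minutes(post)[ss.NREM]
                          - ss.state_minutes(base)[ss.NREM])
        assert np.mean(deltas) > 0

    def test_preset_for_unknown_subject_rejected(self):
        with pytest.raises(ValueError, match="unknown subjects"):
            ss.simulate_cohort(1, presets={"zz99": "male_resilient"},
                               synthesize=False)
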