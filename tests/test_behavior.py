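"""Lick detection, trial parsing and d-prime."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import photolick as pl
from photolick.behavior import ConsistencyError, TrialTable, loglinear_rates
import pandas as pd


class TestLickingPower:
    def test_pointwise_square(self):
        assert np.array_equal(pl.licking_power(np.array([0.0, 1.0, -2.0])), [0.0, 1.0, 4.0])

    def test_zero_trace(self):
        assert np.all(pl.licking_power(np.zeros(100)) == 0.0)

    def test_sinusoid_mean_power(self):
        t = np.arange(100000) / 1000.0
        p = pl.licking_power(3.0 * np.sin(2 * np.pi * 10 * t))
        assert p.mean() == pytest.approx(9.0 / 2.0, rel=1e-3)


class TestLickDetection:
    def _piezo_with_licks(self, lick_times, fs=1000.0, dur=3.0, amp=1.0, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, noise, int(dur * fs))
        pulse = amp * np.sin(np.pi * np.arange(25) / 24)
        for lt in lick_times:
            i0 = int(lt * fs)
            x[i0 : i0 + 25] += pulse[: max(0, min(25, x.size - i0))]
        return x

    def test_flat_trace_yields_no_licks(self):
        assert pl.detect_lick_onsets(np.zeros(1000)).size == 0

    def test_bout_of_five_licks_at_10hz(self):
        true = [1.0, 1.1, 1.2, 1.3, 1.4]
        x = self._piezo_with_licks(true)
        got = pl.detect_lick_onsets(x)
        assert got.size == 5
        assert np.all(np.abs(got - np.asarray(true)) <= 0.005)

    def test_refractory_merges_close_crossings(self):
        x = self._piezo_with_licks([1.0, 1.02], noise=0.01)
        got = pl.detect_lick_onsets(x, refractory=0.05)
        assert got.size == 1

    def test_detected_onsets_match_simulator_log(self, whisker_session):
        _, events, _ = whisker_session
        got = pl.detect_lick_onsets(events.piezo, fs=events.fs)
        # every logged lick is recovered within 5 ms
        assert got.size == events.lick_times.size
        assert np.max(np.abs(got - events.lick_times)) <= 0.005


def _events(licks=(), stims=(), valves=(), starts=(), aborts=(), t_end=100.0):
    return pl.SessionEvents(
        piezo=np.zeros(10),
        lick_times=np.asarray(licks, dtype=float),
        stim_times=np.asarray(stims, dtype=float),
        valve_times=np.asarray(valves, dtype=float),
        trial_start_times=np.asarray(starts, dtype=float),
        abort_times=np.asarray(aborts, dtype=float),
        session_t_end=t_end,
    )


class TestParseTrials:
    def test_hit_and_fa_and_miss_and_cr(self):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        ev = _events(
            licks=[10.3, 20.4],
            stims=[10.0, 30.0],
            valves=[10.3],
            starts=[10.0, 20.0, 30.0, 40.0],
        )
        trials = pl.parse_trials(ev, cfg)
        assert list(trials.df["type"]) == ["Hit", "FA", "Miss", "CR"]
        assert trials.df.loc[0, "reward_time"] == pytest.approx(10.3)

    def test_delay_period_licks_not_counted_as_reports(self):
        cfg = pl.TaskConfig.for_task("delayed_reward")
        ev = _events(
            licks=[10.3, 10.5, 10.8, 11.2, 11.35],
            stims=[10.0],
            valves=[11.2],
            starts=[10.0],
        )
        trials = pl.parse_trials(ev, cfg)
        assert list(trials.df["type"]) == ["Hit"]
        assert trials.df.loc[0, "first_report_lick_time"] == pytest.approx(11.2)

    def test_report_window_is_half_open(self):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        # lick exactly at window start counts; exactly at window end does not
        ev = _events(licks=[10.0], stims=[10.0], starts=[10.0])
        assert pl.parse_trials(ev, cfg).df.loc[0, "type"] == "Hit"
        ev = _events(licks=[11.0], stims=[10.0], starts=[10.0])
        assert pl.parse_trials(ev, cfg).df.loc[0, "type"] == "Miss"

    def test_orphan_valve_raises_consistency_error(self):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        ev = _events(stims=[10.0], valves=[10.5], starts=[10.0])
        with pytest.raises(ConsistencyError):
            pl.parse_trials(ev, cfg)

    def test_free_licking_labels(self):
        cfg = pl.TaskConfig.for_task("free_licking")
        ev = _events(licks=[10.2, 20.3], valves=[10.2], starts=[10.0, 20.0, 30.0])
        trials = pl.parse_trials(ev, cfg)
        assert list(trials.df["type"]) == ["RewardedLick", "UnrewardedLick", "NoLick"]

    def test_aborts_attributed_to_following_trial(self):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        ev = _events(licks=[5.0, 7.0], aborts=[5.0, 7.0], stims=[10.0], starts=[10.0])
        trials = pl.parse_trials(ev, cfg)
        assert trials.df.loc[0, "aborted_attempt_count"] == 2

    @pytest.mark.parametrize(
        "task,n", [("free_licking", 40), ("whisker_detection", 40),
                   ("delayed_reward", 40), ("reward_omission", 70)]
    )
    def test_roundtrip_agreement_with_simulator(self, task, n, default_params):
        cfg = pl.TaskConfig.for_task(task)
        for seed in range(8):
            events, latent = pl.simulate_behavior(cfg, default_params, n, seed=seed)
            parsed = pl.parse_trials(events, cfg)
            assert list(parsed.df["type"]) == list(latent.df["type"])
            assert np.allclose(
                parsed.df["onset_time"], latent.df["onset_time"], atol=1e-9
            )


def _trials_from_counts(n_hit, n_miss, n_fa, n_cr):
    rows = []
    i = 0
    for ttype, n in [("Hit", n_hit), ("Miss", n_miss), ("FA", n_fa), ("CR", n_cr)]:
        for _ in range(n):
            rows.append(
                {
                    "trial": i, "onset_time": float(10 * i),
                    "stim": ttype in ("Hit", "Miss"), "type": ttype,
                    "first_report_lick_time": np.nan, "reward_time": np.nan,
                    "aborted_attempt_count": 0,
                }
            )
            i += 1
    return TrialTable(pd.DataFrame(rows))


def _inverse_normal_oracle(p: float) -> float:
    """High-precision inverse normal CDF via erf + bracketed root finding."""
    return brentq(lambda x: 0.5 * (1.0 + math.erf(x / math.sqrt(2.0))) - p, -10, 10,
                  xtol=1e-12)


class TestPerformance:
    def test_equal_rates_give_zero_dprime(self):
        perf = pl.performance_metrics(_trials_from_counts(10, 10, 10, 10))
        assert perf.dprime == 0.0

    def test_extreme_session_matches_independent_inverse_normal(self):
        perf = pl.performance_metrics(_trials_from_counts(20, 0, 0, 20))
        h, f = loglinear_rates(20, 20, 0, 20)
        expected = _inverse_normal_oracle(h) - _inverse_normal_oracle(f)
        assert perf.dprime == pytest.approx(expected, abs=1e-9)
        assert perf.dprime == pytest.approx(3.9608, abs=1e-3)

    def test_loglinear_correction_values(self):
        h, f = loglinear_rates(20, 20, 0, 20)
        assert h == pytest.approx(20.5 / 21)
        assert f == pytest.approx(0.5 / 21)

    def test_monotone_in_hits_and_false_alarms(self):
        d_by_hits = [
            pl.performance_metrics(_trials_from_counts(k, 20 - k, 5, 15)).dprime
            for k in range(21)
        ]
        assert np.all(np.diff(d_by_hits) > 0)
        d_by_fas = [
            pl.performance_metrics(_trials_from_counts(15, 5, k, 20 - k)).dprime
            for k in range(21)
        ]
        assert np.all(np.diff(d_by_fas) < 0)

    def test_requires_both_trial_classes(self):
        with pytest.raises(ValueError):
            pl.performance_metrics(_trials_from_counts(5, 5, 0, 0))
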