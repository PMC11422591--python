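"""Simulator: transient kernels, task state machine, fluorescence, modulation."""

import numpy as np
import pytest

import photolick as pl
from photolick.synthetic import InfeasibleParamsError, _draw_stim_sequence


# ---------------------------------------------------------------- kernels
class TestDopamineKernel:
    def test_zero_amplitude_is_identically_zero(self):
        t = np.linspace(-1, 5, 1001)
        assert np.all(pl.dopamine_kernel(t, 0.0, 0.05, 0.35) == 0.0)

    def test_causal_before_event(self):
        t = np.linspace(-2.0, -1e-6, 100)
        assert np.all(pl.dopamine_kernel(t, 3.0, 0.05, 0.35) == 0.0)

    def test_peak_location_and_value_match_dense_grid_search(self):
        # closed-form argmax of the double exponential vs brute-force grid
        tau_r, tau_d, amp = 0.05, 0.35, 2.5
        t = np.arange(0.0, 3.0, 1e-5)
        k = pl.dopamine_kernel(t, amp, tau_r, tau_d)
        t_star = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
        assert t_star == pytest.approx(0.1135, abs=5e-4)
        assert t[np.argmax(k)] == pytest.approx(t_star, abs=2e-5)
        assert k.max() == pytest.approx(amp, abs=1e-6)

    def test_sign_follows_amplitude(self):
        t = np.linspace(0.01, 2, 50)
        assert np.all(pl.dopamine_kernel(t, -1.0, 0.3, 1.5) <= 0.0)

    @pytest.mark.parametrize("tau_r,tau_d", [(0.5, 0.5), (0.6, 0.5), (0.0, 0.5)])
    def test_invalid_time_constants_rejected(self, tau_r, tau_d):
        with pytest.raises(ValueError):
            pl.dopamine_kernel(0.1, 1.0, tau_r, tau_d)


# ------------------------------------------------------ behavior state machine
class TestSimulateBehavior:
    def test_degenerate_probabilities_give_pure_hits_and_crs(self):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        params = pl.BehaviorParams(
            spontaneous_bout_rate=0.0,
            learning=pl.LogisticLearning(p0=1.0, p_max=1.0),
        )
        _, latent = pl.simulate_behavior(cfg, params, 20, seed=0)
        stim = latent.df["stim"]
        assert set(latent.df.loc[stim, "type"]) == {"Hit"}
        assert set(latent.df.loc[~stim, "type"]) == {"CR"}
        assert latent.df["aborted_attempt_count"].sum() == 0

    @pytest.mark.parametrize(
        "task", ["free_licking", "whisker_detection", "delayed_reward", "reward_omission"]
    )
    def test_trial_accounting(self, task, default_params):
        cfg = pl.TaskConfig.for_task(task)
        _, latent = pl.simulate_behavior(cfg, default_params, 40, seed=7)
        assert len(latent) == 40  # aborted attempts never become trials
        n_hit = latent.count("Hit", "HitPlus", "HitMinus")
        n_miss = latent.count("Miss")
        n_fa, n_cr = latent.count("FA"), latent.count("CR")
        if task == "free_licking":
            assert latent.n_stim == 0
        else:
            assert n_hit + n_miss == latent.n_stim
            assert n_fa + n_cr == latent.n_nostim

    def test_sequence_constraint_over_many_seeds(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            stim = _draw_stim_sequence(rng, 100, 0.5, 3)
            run, longest, prev = 0, 0, None
            for s in stim:
                run = run + 1 if s == prev else 1
                prev = s
                longest = max(longest, run)
            assert longest <= 3

    def test_sequence_constraint_long_session(self):
        rng = np.random.default_rng(42)
        stim = _draw_stim_sequence(rng, 10_000, 0.5, 3)
        # exhaustive scan for a run of four identical labels
        s = stim.astype(int)
        runs4 = (s[:-3] == s[1:-2]) & (s[1:-2] == s[2:-1]) & (s[2:-1] == s[3:])
        assert not runs4.any()

    def test_reward_omission_warmup_then_half_rewarded(self):
        cfg = pl.TaskConfig.for_task("reward_omission")
        params = pl.BehaviorParams(
            spontaneous_bout_rate=0.0,
            learning=pl.LogisticLearning(p0=1.0, p_max=1.0),
        )
        _, latent = pl.simulate_behavior(cfg, params, 250, seed=3)
        warm = latent.df.iloc[:50]
        assert set(warm.loc[warm["stim"], "type"]) == {"HitPlus"}
        later = latent.df.iloc[50:]
        hits = later[later["type"].isin(["HitPlus", "HitMinus"])]
        frac = (hits["type"] == "HitPlus").mean()
        n = len(hits)
        assert abs(frac - 0.5) < 3.0 * np.sqrt(0.25 / n)  # binomial 3-sigma

    def test_satiety_schedule_monotone_in_reward_index(self, default_params):
        cfg = pl.TaskConfig.for_task("free_licking")
        _, latent = pl.simulate_behavior(cfg, default_params, 80, seed=11)
        rewarded = latent.df[latent.df["type"] == "RewardedLick"]
        sat = rewarded["satiety"].to_numpy()
        assert len(sat) >= 20
        assert np.all(np.diff(sat) < 0)
        assert sat[:15].mean() > sat[-15:].mean()

    def test_infeasible_spontaneous_rate_raises(self):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        params = pl.BehaviorParams(spontaneous_bout_rate=50.0)
        with pytest.raises(InfeasibleParamsError):
            pl.simulate_behavior(cfg, params, 5, seed=0, max_attempts_per_trial=5)

    def test_aborted_attempts_logged_with_licks(self, default_params):
        cfg = pl.TaskConfig.for_task("whisker_detection")
        events, latent = pl.simulate_behavior(cfg, default_params, 30, seed=21)
        assert events.abort_times.size == latent.df["aborted_attempt_count"].sum()
        # every abort coincides with a logged lick
        for ta in events.abort_times:
            assert np.any(np.abs(events.lick_times - ta) < 1e-9)


# ------------------------------------------------------------- fluorescence
class TestRenderFluorescence:
    def test_silent_kernels_leave_pure_bleach(self, whisker_session):
        _, events, latent = whisker_session
        truth = pl.PhotometryGroundTruth(
            sensory_amp=0.0, reward_amp=1e-12, dip_amp=-1e-12,
            motion_artifact_sd=0.0, noise_sd=0.0,
        )
        traces, _ = pl.render_fluorescence(events, truth, latent, seed=0)
        t = traces.times
        expected = truth.baseline_f465 * np.exp(-t / truth.bleach_tau_465)
        assert np.allclose(traces.f465, expected, rtol=1e-9, atol=1e-9)

    def test_reward_transient_anchored_at_second_contact(self, whisker_session):
        _, events, latent = whisker_session
        truth = pl.PhotometryGroundTruth(
            sensory_amp=0.0, dip_amp=-1e-12, motion_artifact_sd=0.0, noise_sd=0.0,
            bleach_tau_465=1e9, bleach_tau_405=1e9,
        )
        traces, gt = pl.render_fluorescence(events, truth, latent, seed=0)
        rewarded = gt[gt["reward_amp"] > 0]
        assert len(rewarded) > 0
        for row in rewarded.itertuples():
            # the anchor is the first lick after valve opening
            valve_t = latent.df.loc[row.trial, "reward_time"]
            after = events.lick_times[events.lick_times > valve_t]
            assert row.reward_anchor_time == pytest.approx(after[0])
        # peak latency after the anchor matches the kernel's closed form
        row = rewarded.iloc[0]
        dff = traces.f465 / truth.baseline_f465 - 1.0
        sl = slice(int(row.reward_anchor_time * 1000), int(row.reward_anchor_time * 1000) + 1500)
        t_peak_lat = np.argmax(dff[sl]) / 1000.0
        tr, td = truth.reward_tau_rise, truth.reward_tau_decay
        expected_lat = tr * td / (td - tr) * np.log(td / tr)
        assert t_peak_lat == pytest.approx(expected_lat, abs=0.005)

    def test_shared_artifact_correlates_channels(self, whisker_session):
        _, events, latent = whisker_session
        truth = pl.PhotometryGroundTruth(
            sensory_amp=0.0, reward_amp=1e-12, dip_amp=-1e-12,
            motion_artifact_sd=0.01, noise_sd=0.0,
        )
        traces, _ = pl.render_fluorescence(events, truth, latent, seed=5)
        t = traces.times
        r465 = traces.f465 - truth.baseline_f465 * np.exp(-t / truth.bleach_tau_465)
        r405 = traces.f405 - truth.baseline_f405 * np.exp(-t / truth.bleach_tau_405)
        corr = np.corrcoef(r465, r405)[0, 1]
        assert corr > 0.9

    def test_isosbestic_channel_carries_no_kernels(self, rendered_free_session):
        _, events, latent, truth, traces, gt = rendered_free_session
        # regress 405 residual fluctuation on the kernel train: no loading
        t = traces.times
        resid405 = traces.f405 - truth.baseline_f405 * np.exp(-t / truth.bleach_tau_405)
        kern = np.zeros_like(resid405)
        for row in gt.itertuples():
            if row.reward_amp > 0:
                i0 = int(row.reward_anchor_time * 1000)
                kern[i0 : i0 + 1000] += 1.0
        mask = kern > 0
        assert abs(resid405[mask].mean() - resid405[~mask].mean()) < 5e-3


# ----------------------------------------------------------------- modulate
class TestModulate:
    def _const_traces(self, a465, a405, dur=2.0):
        n = int(dur * 1000) + 1
        return pl.ChannelTraces(
            f465=np.full(n, a465, dtype=float), f405=np.full(n, a405, dtype=float)
        )

    def test_single_channel_exact_waveform(self):
        truth = pl.PhotometryGroundTruth(detector_offset=0.0)
        ideal = self._const_traces(3.0, 0.0)
        raw = pl.modulate(ideal, truth)
        t = raw.times
        expected = 3.0 * 0.5 * (1.0 + np.sin(2 * np.pi * truth.carrier_freqs[0] * t))
        assert np.allclose(raw.samples, expected, atol=1e-12)

    def test_zero_channels_give_constant_offset(self):
        truth = pl.PhotometryGroundTruth(detector_offset=0.7)
        raw = pl.modulate(self._const_traces(0.0, 0.0), truth)
        assert np.allclose(raw.samples, 0.7)

    def test_spectral_line_amplitudes_in_ratio(self):
        # constant F465=2, F405=3 -> carrier lines of amplitude 1.0 and 1.5
        truth = pl.PhotometryGroundTruth()
        raw = pl.modulate(self._const_traces(2.0, 3.0, dur=10.0), truth)
        t = raw.times
        amps = []
        for f in truth.carrier_freqs:
            z = np.exp(-2j * np.pi * f * t)
            amps.append(2.0 * np.abs(np.mean(raw.samples * z)))
        assert amps[0] == pytest.approx(2.0 * 0.5, rel=1e-3)
        assert amps[1] == pytest.approx(3.0 * 0.5, rel=1e-3)
        assert amps[0] / amps[1] == pytest.approx(2.0 / 3.0, rel=2e-3)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            pl.PhotometryGroundTruth(fs_acquisition=900.0)
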