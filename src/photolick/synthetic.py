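"""Synthetic session generator with known ground truth.

Generates complete sessions of the four head-fixed licking tasks: the
behavioral event streams (lick bouts at ~10 Hz, trial aborts during the
No-lick period, stimulus sequences with at most three consecutive trials of
the same type, reward valve openings), the piezo lick-sensor voltage, and
the raw modulated two-carrier photometry signal.

The fluorescence model is the simplest one the downstream isosbestic
correction can cancel exactly:

* 465 nm channel: mono-exponential photobleaching times the baseline plus a
  sum of dopamine transients (double-exponential kernels), plus a shared
  additive motion artifact and white noise;
* 405 nm channel: its own bleaching baseline plus the *same* artifact
  (scaled) and independent noise -- the isosbestic channel carries no
  dopamine kernels.

Three kernel families shape the dopamine trace: a fast sensory transient at
whisker-stimulus time whose amplitude can track the learning curve, a reward
transient anchored at the second tongue-spout contact of rewarded bouts
(water only reaches the tongue on lick two), and a slower negative dip on
unrewarded reporting-window licking.  Reward (and dip) amplitudes decay
exponentially with the number of rewards already consumed, emulating
within-session satiety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import SessionEvents, TrialTable, TRIAL_COLUMNS
from .demodulation import ChannelTraces, RawRecording
from .task import TaskConfig

__all__ = [
    "LogisticLearning",
    "BehaviorParams",
    "PhotometryGroundTruth",
    "InfeasibleParamsError",
    "SimulatedSession",
    "dopamine_kernel",
    "simulate_behavior",
    "render_fluorescence",
    "modulate",
    "simulate_session",
]


class InfeasibleParamsError(RuntimeError):
    """Raised when no trial can be initiated under the given parameters."""


@dataclass
class LogisticLearning:
    """Per-stimulus-trial hit probability, logistic in stimulus-trial index.

    ``p_hit(k) = p0 + (p_max - p0) / (1 + exp(-steepness * (k - midpoint)))``
    with ``k`` the 0-based index among stimulus trials.
    """

    p0: float = 0.2
    p_max: float = 0.8
    midpoint_trial: float = 25.0
    steepness: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= self.p_max <= 1.0:
            raise ValueError("need 0 <= p0 <= p_max <= 1")

    def level(self, k: float) -> float:
        """Learning level in [0, 1] at stimulus-trial index k."""
        return 1.0 / (1.0 + math.exp(-self.steepness * (k - self.midpoint_trial)))

    def p_hit(self, k: float) -> float:
        return self.p0 + (self.p_max - self.p0) * self.level(k)


@dataclass
class BehaviorParams:
    """Generative parameters of licking behavior.

    Attributes
    ----------
    spontaneous_bout_rate : float
        Poisson rate (bouts/s) of spontaneous lick-bout initiation; drives
        both No-lick-period aborts and false alarms.
    intra_bout_lick_freq : float
        Lick rhythm within a bout, Hz (~10 in mice).
    bout_length_rewarded, bout_length_unrewarded : float
        Mean number of licks (Poisson) produced at/after the reporting
        window in rewarded vs unrewarded bouts; rewarded bouts are longer.
    free_lick_prob : float
        Free licking only: probability that the (skilled, thirsty) mouse
        initiates licking within a reporting period.
    learning : LogisticLearning
        Hit-probability curve over stimulus trials.
    reaction_time_mode, reaction_time_sigma : float
        Log-normal reaction time from stimulus to bout onset; mode ~0.3 s.
    satiety_tau : float or None
        Trials constant of the exponential motivation decay with consumed
        rewards; ``None`` disables satiety.
    """

    spontaneous_bout_rate: float = 0.22
    intra_bout_lick_freq: float = 10.0
    bout_length_rewarded: float = 8.0
    bout_length_unrewarded: float = 3.0
    free_lick_prob: float = 0.6
    learning: LogisticLearning = field(default_factory=LogisticLearning)
    reaction_time_mode: float = 0.3
    reaction_time_sigma: float = 0.35
    #: sensorimotor floor: licks cannot follow the stimulus faster than this
    reaction_time_min: float = 0.25
    satiety_tau: float | None = 40.0
    # piezo rendering
    lick_pulse_amp: float = 1.0
    lick_pulse_duration: float = 0.025
    piezo_noise_sd: float = 0.02
    # intra-bout timing
    ili_jitter_sd: float = 0.01
    min_ili: float = 0.06

    def __post_init__(self) -> None:
        if self.spontaneous_bout_rate < 0:
            raise ValueError("spontaneous_bout_rate must be >= 0")
        for name in (
            "intra_bout_lick_freq",
            "bout_length_rewarded",
            "bout_length_unrewarded",
            "reaction_time_mode",
            "reaction_time_sigma",
            "lick_pulse_amp",
            "lick_pulse_duration",
            "min_ili",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.satiety_tau is not None and self.satiety_tau <= 0:
            raise ValueError("satiety_tau must be positive or None")
        if not 0.0 <= self.free_lick_prob <= 1.0:
            raise ValueError("free_lick_prob must lie in [0, 1]")

    def satiety(self, n_rewards_consumed: int) -> float:
        if self.satiety_tau is None:
            return 1.0
        return math.exp(-n_rewards_consumed / self.satiety_tau)


@dataclass
class PhotometryGroundTruth:
    """Latent parameters of the fluorescence model.

    Kernel amplitudes are *fractional* (units of dF/F0 relative to the
    bleached baseline); the rendered 465 nm trace is
    ``bleach(t) * baseline * (1 + sum of kernels) + artifact + noise``.
    """

    baseline_f465: float = 2.0
    baseline_f405: float = 1.5
    # fast sensory transient at whisker-stimulus time
    sensory_amp: float = 0.02
    sensory_tau_rise: float = 0.05
    sensory_tau_decay: float = 0.3
    #: "learning" couples sensory amplitude to the hit-probability curve;
    #: "constant" keeps it fixed across trials.
    sensory_coupling: str = "learning"
    # reward transient anchored at the second tongue-spout contact
    reward_amp: float = 0.05
    reward_tau_rise: float = 0.2
    reward_tau_decay: float = 1.0
    # negative dip on unrewarded reporting-window licking
    dip_amp: float = -0.015
    dip_tau_rise: float = 0.3
    dip_tau_decay: float = 1.5
    bleach_tau_465: float = 3600.0
    bleach_tau_405: float = 3600.0
    #: sd of the shared band-limited (<5 Hz) motion term, as a fraction of
    #: each channel's baseline
    motion_artifact_sd: float = 0.005
    artifact_scale_405: float = 1.0
    #: per-channel white-noise sd as a fraction of the channel baseline
    noise_sd: float = 0.003
    carrier_freqs: tuple[float, float] = (208.616, 500.679)
    modulation_depth: float = 1.0
    fs_acquisition: float = 12224.0
    detector_offset: float = 0.1
    detector_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for pre in ("sensory", "reward", "dip"):
            tr = getattr(self, f"{pre}_tau_rise")
            td = getattr(self, f"{pre}_tau_decay")
            if not 0 < tr < td:
                raise ValueError(f"{pre} kernel needs 0 < tau_rise < tau_decay")
        if self.baseline_f465 <= 0 or self.baseline_f405 <= 0:
            raise ValueError("baselines must be positive")
        if self.bleach_tau_465 <= 0 or self.bleach_tau_405 <= 0:
            raise ValueError("bleach time constants must be positive")
        if self.sensory_coupling not in ("learning", "constant"):
            raise ValueError("sensory_coupling must be 'learning' or 'constant'")
        f1, f2 = self.carrier_freqs
        if f1 == f2:
            raise ValueError("carrier frequencies must be distinct")
        if self.fs_acquisition <= 2.0 * max(f1, f2):
            raise ValueError("fs_acquisition must exceed twice the highest carrier")
        if not 0.0 < self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in (0, 1]")
        if self.motion_artifact_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise terms must be non-negative")


def dopamine_kernel(
    t_rel: np.ndarray | float,
    amp: float,
    tau_rise: float,
    tau_decay: float,
) -> np.ndarray | float:
    """Causal double-exponential transient, peak-normalised to ``amp``.

    ``k(t) = amp * (exp(-t/tau_decay) - exp(-t/tau_rise)) / peak`` for
    ``t >= 0`` and 0 before, where the peak occurs at
    ``t* = tau_r * tau_d / (tau_d - tau_r) * ln(tau_d / tau_r)``.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    t = np.asarray(t_rel, dtype=float)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    out = np.where(
        t >= 0.0,
        (np.exp(-np.clip(t, 0, None) / tau_decay) - np.exp(-np.clip(t, 0, None) / tau_rise))
        * (amp / peak),
        0.0,
    )
    return out if out.ndim else float(out)


def _draw_stim_sequence(
    rng: np.random.Generator, n_trials: int, frac: float, max_run: int
) -> np.ndarray:
    """Stimulus/no-stimulus labels with runs capped at ``max_run``.

    The cap only applies to genuinely mixed designs (0 < frac < 1); a
    single-type task such as free licking is one long run by definition.
    """
    stim = np.zeros(n_trials, dtype=bool)
    run_val, run_len = None, 0
    for i in range(n_trials):
        if 0.0 < frac < 1.0 and run_len >= max_run:
            s = not run_val
        else:
            s = bool(rng.random() < frac)
        stim[i] = s
        if s == run_val:
            run_len += 1
        else:
            run_val, run_len = s, 1
    return stim


def _classify(task_kind: str, stim: bool, licked: bool, rewarded: bool) -> str:
    if task_kind == "free_licking":
        if not licked:
            return "NoLick"
        return "RewardedLick" if rewarded else "UnrewardedLick"
    if task_kind == "reward_omission" and stim:
        if not licked:
            return "Miss"
        return "HitPlus" if rewarded else "HitMinus"
    if stim:
        return "Hit" if licked else "Miss"
    return "FA" if licked else "CR"


def simulate_behavior(
    config: TaskConfig,
    params: BehaviorParams,
    n_trials: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts_per_trial: int = 1000,
) -> tuple[SessionEvents, TrialTable]:
    """Run the task state machine and return events plus the latent truth.

    Each trial is preceded by an ITI and a No-lick period; a spontaneous
    lick bout during the No-lick period aborts the attempt (logged as an
    abort event, licks included in the record) and the attempt restarts.
    On completed trials the stimulus sequence, evoked/spontaneous licking,
    and the reward rule of the task determine the outcome, which is written
    to the latent :class:`~photolick.behavior.TrialTable` together with the
    generative hit probability, learning level and satiety factor.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    freq = params.intra_bout_lick_freq
    rate = params.spontaneous_bout_rate
    stim_seq = _draw_stim_sequence(
        rng, n_trials, config.stim_trial_fraction, config.max_consecutive_same_type
    )

    licks: list[float] = []
    stims: list[float] = []
    valves: list[float] = []
    trial_starts: list[float] = []
    aborts: list[float] = []
    rows: list[dict] = []

    def ili() -> float:
        return max(params.min_ili, 1.0 / freq + rng.normal(0.0, params.ili_jitter_sd))

    def spontaneous_wait() -> float:
        return rng.exponential(1.0 / rate) if rate > 0 else math.inf

    t = 0.0
    stim_idx = 0
    n_rewards = 0
    for i in range(n_trials):
        # --- attempt loop: ITI + No-lick period, aborted by licking ---
        attempts = 0
        while True:
            t += rng.uniform(*config.iti_range)
            nolick_dur = rng.uniform(*config.nolick_range)
            wait = spontaneous_wait()
            if wait < nolick_dur:
                t_abort = t + wait
                aborts.append(t_abort)
                n_bout = max(1, int(rng.poisson(params.bout_length_unrewarded)))
                tb = t_abort
                for _ in range(n_bout):
                    licks.append(tb)
                    tb += ili()
                t = tb + 0.05
                attempts += 1
                if attempts >= max_attempts_per_trial:
                    raise InfeasibleParamsError(
                        f"trial {i}: {attempts} aborted attempts; spontaneous "
                        "bout rate is too high for the No-lick period"
                    )
                continue
            t += nolick_dur
            break

        onset = t
        trial_starts.append(onset)
        stim = bool(stim_seq[i])
        if stim:
            stims.append(onset)
        win_start = onset + config.delay
        win_end = win_start + config.report_window

        # --- response: evoked bout (stimulus trials) or spontaneous bout ---
        p_hit = params.learning.p_hit(stim_idx) if stim else math.nan
        level = params.learning.level(stim_idx) if stim else math.nan
        bout_start = None
        if stim and rng.random() < p_hit:
            rt = rng.lognormal(
                math.log(params.reaction_time_mode) + params.reaction_time_sigma**2,
                params.reaction_time_sigma,
            )
            rt = float(
                np.clip(rt, params.reaction_time_min, config.delay + 0.7 * config.report_window)
            )
            bout_start = onset + rt
        elif config.task_kind == "free_licking":
            # engaged licking for the chance of reward, not background licking
            if rng.random() < params.free_lick_prob:
                bout_start = win_start + rng.uniform(0.0, 0.7 * config.report_window)
        else:
            wait = spontaneous_wait()
            if onset + wait < win_end:
                bout_start = onset + wait
        licked = bout_start is not None

        # --- reward rule ---
        rewarded = False
        if licked:
            if config.task_kind == "free_licking":
                rewarded = bool(rng.random() < config.reward_prob_on_lick)
            elif config.task_kind == "reward_omission":
                if stim:
                    rewarded = (
                        True
                        if i < config.n_warmup_trials
                        else bool(rng.random() >= config.omission_prob)
                    )
            else:
                rewarded = stim

        # --- generate the lick bout ---
        first_report = math.nan
        reward_time = math.nan
        if licked:
            n_post = (
                max(2, int(rng.poisson(params.bout_length_rewarded)))
                if rewarded
                else max(1, int(rng.poisson(params.bout_length_unrewarded)))
            )
            tb = bout_start
            n_after = 0
            while True:
                licks.append(tb)
                if tb >= win_start:
                    if n_after == 0:
                        first_report = tb
                    n_after += 1
                    if n_after >= n_post:
                        break
                tb += ili()
            if rewarded:
                reward_time = first_report
                valves.append(first_report)

        satiety = params.satiety(n_rewards)
        if rewarded:
            n_rewards += 1
        rows.append(
            {
                "trial": i,
                "onset_time": onset,
                "stim": stim,
                "type": _classify(config.task_kind, stim, licked, rewarded),
                "first_report_lick_time": first_report,
                "reward_time": reward_time,
                "aborted_attempt_count": attempts,
                "stim_index": stim_idx if stim else -1,
                "p_hit": p_hit,
                "learning_level": level,
                "satiety": satiety,
            }
        )
        if stim:
            stim_idx += 1
        t = max(win_end, (licks[-1] + 0.05) if licked else win_end)

    session_t_end = t + 2.0
    fs = 1000.0
    n_samp = int(round(session_t_end * fs)) + 1
    piezo = rng.normal(0.0, params.piezo_noise_sd, n_samp)
    n_pulse = max(2, int(round(params.lick_pulse_duration * fs)))
    pulse_shape = np.sin(np.pi * np.arange(n_pulse) / (n_pulse - 1))
    for lt in licks:
        i0 = int(round(lt * fs))
        i1 = min(i0 + n_pulse, n_samp)
        piezo[i0:i1] += rng.uniform(0.8, 1.2) * params.lick_pulse_amp * pulse_shape[: i1 - i0]

    events = SessionEvents(
        piezo=piezo,
        lick_times=np.asarray(licks),
        stim_times=np.asarray(stims),
        valve_times=np.asarray(valves),
        trial_start_times=np.asarray(trial_starts),
        abort_times=np.asarray(aborts),
        session_t_end=session_t_end,
        fs=fs,
    )
    latent = TrialTable(pd.DataFrame(rows))
    return events, latent


def _add_kernel(
    target: np.ndarray,
    fs: float,
    t_event: float,
    amp: float,
    tau_rise: float,
    tau_decay: float,
) -> None:
    """Add a double-exponential transient in place, on finite support."""
    if amp == 0.0:
        return
    n = target.size
    i0 = max(0, int(math.ceil(t_event * fs)))
    i1 = min(n, i0 + int(math.ceil(8.0 * tau_decay * fs)))
    if i1 <= i0:
        return
    t_rel = np.arange(i0, i1) / fs - t_event
    target[i0:i1] += dopamine_kernel(t_rel, amp, tau_rise, tau_decay)


def render_fluorescence(
    events: SessionEvents,
    truth: PhotometryGroundTruth,
    latent: TrialTable,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelTraces, pd.DataFrame]:
    """Render ideal 1 kHz F465/F405 traces from the latent trial record.

    The 465 channel receives the dopamine kernels; the 405 isosbestic
    channel only its bleaching baseline, the shared motion artifact and
    noise.  The reward kernel is anchored at the first tongue-spout contact
    *after* valve opening (the second lick of the bout, when water reaches
    the tongue); the dip kernel at the first unrewarded reporting-window
    lick.  Returns the traces and a per-trial ground-truth amplitude table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = 1000.0
    n = int(round(events.session_t_end * fs)) + 1
    t = np.arange(n) / fs

    kernels = np.zeros(n)
    gt_rows = []
    for row in latent.df.itertuples(index=False):
        sensory_amp = 0.0
        sensory_t = math.nan
        reward_amp = 0.0
        reward_t = math.nan
        dip_amp = 0.0
        dip_t = math.nan
        if row.stim:
            scale = row.learning_level if truth.sensory_coupling == "learning" else 1.0
            sensory_amp = truth.sensory_amp * scale
            sensory_t = row.onset_time
            _add_kernel(
                kernels, fs, sensory_t, sensory_amp,
                truth.sensory_tau_rise, truth.sensory_tau_decay,
            )
        if np.isfinite(row.reward_time):
            after = events.lick_times[events.lick_times > row.reward_time]
            reward_t = float(after[0]) if after.size else row.reward_time + 0.1
            reward_amp = truth.reward_amp * row.satiety
            _add_kernel(
                kernels, fs, reward_t, reward_amp,
                truth.reward_tau_rise, truth.reward_tau_decay,
            )
        elif np.isfinite(row.first_report_lick_time):
            dip_t = row.first_report_lick_time
            dip_amp = truth.dip_amp * row.satiety
            _add_kernel(
                kernels, fs, dip_t, dip_amp, truth.dip_tau_rise, truth.dip_tau_decay
            )
        gt_rows.append(
            {
                "trial": row.trial,
                "sensory_amp": sensory_amp,
                "sensory_time": sensory_t,
                "reward_amp": reward_amp,
                "reward_anchor_time": reward_t,
                "dip_amp": dip_amp,
                "dip_time": dip_t,
            }
        )

    if truth.motion_artifact_sd > 0:
        # the artifact is band-limited below 5 Hz, so synthesise it on a
        # 100 Hz grid and interpolate up to the 1 kHz clock
        fs_art = 100.0
        n_art = int(math.ceil(events.session_t_end * fs_art)) + 2
        white = rng.standard_normal(n_art)
        sos = sps.butter(2, 5.0, btype="low", fs=fs_art, output="sos")
        m_art = sps.sosfiltfilt(sos, white)
        m = np.interp(t, np.arange(n_art) / fs_art, m_art)
        m *= truth.motion_artifact_sd / max(m.std(), 1e-12)
    else:
        m = np.zeros(n)

    b465 = np.exp(-t / truth.bleach_tau_465)
    b405 = (
        b465 if truth.bleach_tau_405 == truth.bleach_tau_465
        else np.exp(-t / truth.bleach_tau_405)
    )
    f465 = kernels
    f465 += 1.0
    f465 *= b465
    f465 *= truth.baseline_f465
    f465 += m * truth.baseline_f465
    f405 = b405 * truth.baseline_f405
    f405 += m * (truth.baseline_f405 * truth.artifact_scale_405)
    if truth.noise_sd > 0:
        f465 += rng.normal(0.0, truth.noise_sd * truth.baseline_f465, n)
        f405 += rng.normal(0.0, truth.noise_sd * truth.baseline_f405, n)
    traces = ChannelTraces(f465=f465, f405=f405, fs=fs, t0=0.0)
    return traces, pd.DataFrame(gt_rows)


def modulate(
    ideal: ChannelTraces,
    truth: PhotometryGroundTruth,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RawRecording:
    """Mix the two envelopes onto their excitation carriers.

    ``detector(t) = F465(t) e1(t) + F405(t) e2(t) + offset`` with the
    non-negative excitation ``e_i(t) = 0.5 (1 + depth sin(2 pi f_i t))``,
    sampled at the acquisition rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = truth.fs_acquisition
    f1, f2 = truth.carrier_freqs
    if fs <= 2.0 * max(f1, f2):
        raise ValueError("fs_acquisition must exceed twice the highest carrier")
    t_ideal = ideal.times
    n_acq = int(math.floor((t_ideal[-1] - ideal.t0) * fs)) + 1
    t = ideal.t0 + np.arange(n_acq) / fs
    f465 = np.interp(t, t_ideal, ideal.f465)
    f405 = np.interp(t, t_ideal, ideal.f405)
    d = truth.modulation_depth
    e1 = 0.5 * (1.0 + d * np.sin(2.0 * np.pi * f1 * t))
    e2 = 0.5 * (1.0 + d * np.sin(2.0 * np.pi * f2 * t))
    detector = f465 * e1 + f405 * e2 + truth.detector_offset
    if truth.detector_noise_sd > 0:
        detector = detector + rng.normal(0.0, truth.detector_noise_sd, n_acq)
    return RawRecording(
        samples=detector,
        fs=fs,
        carrier_freqs=(f1, f2),
        t0=ideal.t0,
        modulation_depth=d,
    )


@dataclass
class SimulatedSession:
    """Complete synthetic session with its generative ground truth."""

    config: TaskConfig
    params: BehaviorParams
    truth: PhotometryGroundTruth
    seed: int | None
    events: SessionEvents
    latent: TrialTable
    ideal_traces: ChannelTraces
    raw: RawRecording
    gt_amps: pd.DataFrame


def simulate_session(
    config: TaskConfig,
    params: BehaviorParams,
    truth: PhotometryGroundTruth,
    n_trials: int,
    seed: int | None = None,
) -> SimulatedSession:
    """Generate one full session: behavior, ideal traces, modulated record.

    The seed is split into independent child streams for behavior,
    fluorescence noise, and detector noise, so e.g. the behavioral record
    is reproducible irrespective of photometry noise settings.
    """
    ss = np.random.SeedSequence(seed)
    rng_beh, rng_fluo, rng_mod = (np.random.default_rng(s) for s in ss.spawn(3))
    events, latent = simulate_behavior(config, params, n_trials, rng=rng_beh)
    ideal, gt_amps = render_fluorescence(events, truth, latent, rng=rng_fluo)
    raw = modulate(ideal, truth, rng=rng_mod)
    return SimulatedSession(
        config=config,
        params=params,
        truth=truth,
        seed=seed,
        events=events,
        latent=latent,
        ideal_traces=ideal,
        raw=raw,
        gt_amps=gt_amps,
    )
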