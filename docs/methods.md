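# Methods

This note documents the generative model behind the synthetic sessions,
the analysis conventions of each pipeline stage, the numerically delicate
choices, and what the validation suite does and does not establish about
real recordings.

## Signal model

A single photoreceiver collects fluorescence excited by two LEDs whose
intensities are sinusoidally modulated at distinct carriers,
f₁ = 208.616 Hz for the 465 nm (dopamine-sensitive) excitation and
f₂ = 500.679 Hz for the 405 nm isosbestic excitation. Because LED
intensity cannot be negative, the excitation waveform is taken as
eᵢ(t) = ½(1 + d·sin 2πfᵢt) with modulation depth d ∈ (0, 1] (default 1);
the detector voltage is

    x(t) = F465(t)·e₁(t) + F405(t)·e₂(t) + offset.

The carrier term of channel i then has amplitude Fᵢ·d/2, and the
demodulation scale convention multiplies the recovered quadrature magnitude
by 4/d so that the envelope equals Fᵢ itself.

The rendered 465 nm envelope is

    F465(t) = B465·exp(−t/τ_b)·(1 + Σₖ kₖ(t)) + B465·m(t) + ε465(t),

with B465 the baseline, τ_b the bleaching constant (default 3600 s, i.e.
gentle session-scale bleaching; the steeper 600 s case is used explicitly
in the dF/F₀ stress tests), m(t) a shared band-limited (< 5 Hz) motion
term (s.d. 0.5% of baseline) and ε white sensor noise (s.d. 0.3% of
baseline). The isosbestic channel carries its own baseline and bleach, the
*same* m(t) scaled by its baseline, and independent noise — but no
dopamine kernels. With equal bleach constants and baseline-proportional
artifact loading, a single affine fit of F405 onto F465 cancels both
bleaching and motion exactly; this is deliberately the simplest model the
isosbestic correction can fully cancel, so residuals in dF/F₀ measure the
pipeline rather than model mismatch.

### Dopamine transients

All transients are causal double exponentials, peak-normalised so the
maximum equals the amplitude parameter:

    k(t) = a·(e^{−t/τ_d} − e^{−t/τ_r}) / (e^{−t*/τ_d} − e^{−t*/τ_r}),
    t* = τ_r τ_d/(τ_d − τ_r) · ln(τ_d/τ_r).

Three kernel families (amplitudes are fractions of the bleached baseline,
i.e. dF/F₀ units):

| kernel  | anchor                                    | a (default) | τ_r, τ_d (s) | peak lag |
|---------|-------------------------------------------|------------:|--------------|---------:|
| sensory | whisker stimulus onset                    | 0.02        | 0.05, 0.3    | 0.11 s   |
| reward  | first tongue-spout contact *after* valve  | 0.05        | 0.2, 1.0     | 0.40 s   |
| dip     | first unrewarded reporting-window lick    | −0.015      | 0.3, 1.5     | 0.71 s   |

The reward kernel is anchored at the second lick of a rewarded bout
because the valve opens on the first threshold-crossing lick but the drop
only reaches the tongue on the next protrusion; with the lick rhythm near
10 Hz this places the dopamine peak ≈ 0.5 s after the first contact,
matching the reward-peak quantification window (0.3–0.5 s). Reward and dip
amplitudes are multiplied by the satiety factor exp(−r/τ_s), where r is
the number of rewards already consumed (τ_s = 40 trials by default;
`satiety_tau=None` switches devaluation off). The sensory amplitude either
stays constant or tracks the logistic learning level (below) — the switch
that the learning-dynamics validation toggles.

## Behavioral model

Trials follow the task state machine: ITI (uniform 8–13 s, or 0.5–0.6 s in
free licking), then a No-lick period (4.5–5.5 s / 3.5–4.5 s) during which
any spontaneous lick bout aborts and restarts the attempt, then the trial
onset and a 1 s reporting window, delayed by 1 s in the delayed-reward and
reward-omission tasks. Stimulus/no-stimulus labels are drawn with at most
three consecutive repeats. Reward rules: free licking rewards
reporting-window licks with p = 0.5; whisker detection and delayed reward
reward every Hit; reward omission rewards every Hit in the first 50 trials
(25 stimulus / 25 catch) and with p = 0.5 thereafter (Hit⁺ vs Hit⁻).

Licking is organised in bouts at `intra_bout_lick_freq` ≈ 10 Hz (Gaussian
inter-lick jitter, 60 ms floor). Spontaneous bouts arise as a Poisson
process with rate 0.22 s⁻¹; this single rate produces both the No-lick
aborts and the false alarms (FA probability ≈ 1 − e^{−0.22·1 s} ≈ 0.20 per
catch trial, the day-1 level of trained mice). Stimulus trials evoke a
response with probability given by a logistic learning curve over
stimulus-trial index k,

    p_hit(k) = p₀ + (p_max − p₀)/(1 + e^{−β(k − k₀)}),

defaults p₀ = 0.2, p_max = 0.8, k₀ = 25, β = 0.15. Reaction times are
log-normal with mode 0.3 s and a hard 0.25 s sensorimotor floor. The floor
matters beyond realism: without it, implausibly fast "reactions" put the
second lick — and therefore the reward transient — inside the 0.1–0.3 s
early-sensory window, which mechanically couples the early-window
quantification to hit rate and contaminates the learning-control analysis;
with the floor, the earliest possible reward anchor (floor plus the 60 ms
minimum inter-lick interval) lies past the window end by construction
(see Limitations). Rewarded bouts are longer than unrewarded ones (Poisson
means 8 vs 3 licks at/after the window start, minimum two licks when
rewarded so the water is actually encountered).

Free licking is modelled separately from background licking: a skilled,
thirsty mouse initiates a reporting-window bout with probability
`free_lick_prob` = 0.6. A homogeneous Poisson process cannot reproduce the
near-ceiling engagement of trained mice in this task — raising the rate
enough to make them lick in most windows would make them abort nearly
every attempt first.

Each lick is rendered into the piezo trace as a 25 ms half-sine pulse
(amplitude 1 V ± 20%) on white noise (s.d. 0.02 V). Detection uses an
upward crossing of 4 robust noise s.d. (1.4826·MAD) sustained for at least
3 ms, with a 50 ms refractory period; the sustain requirement exists
because a bare 4σ crossing on white 1 kHz noise fires ~70 spurious onsets
per 20-minute session, while real tongue contacts load the film for tens
of milliseconds.

## Analysis conventions

* **Lock-in**: quadrature multiply, 4th-order Butterworth low-pass at
  25 Hz (dopamine transients live below ~10 Hz; carriers are ≥ 208 Hz and
  their difference ≈ 292 Hz), applied forward–backward so the output is
  zero-phase (reported group delay 0). An independent windowed
  sinusoid-fit demodulator (`sinefit_demodulate`) exists solely as a
  cross-check and is never used by the pipeline. The first/last ~0.5 s of
  a record are filter-settling regions; the isosbestic fit excludes 1 s at
  each end (the trace itself is kept).
* **1 kHz clock**: anti-alias low-pass at 400 Hz, then interpolation onto
  the exact 1 ms grid t₀ + k/1000 — this handles the non-integer 12 224 Hz
  acquisition rate; output length is ⌊(n−1)·1000/fs⌋ + 1.
* **Isosbestic fit**: a·F405 + b with an intercept (detector offsets
  differ between channels), fitted once per session via the closed-form
  normal equations. The fit fails loudly if F405 is constant or the fitted
  baseline is non-positive inside the session.
* **Windows**: all response/baseline windows are half-open [start, end) on
  the 1 ms lag grid; the sample at the event time belongs to lag 0. The
  registry carries both the 0.3–0.5 s reward-peak window and the 0.2–0.4 s
  variant that appears in the within-session devaluation figures; the
  0.3–0.5 s version is the default.
* **Signed-rank test**: zero differences dropped; exact null distribution
  for n ≤ 25 without tied absolute differences, otherwise the normal
  approximation with tie correction and no continuity correction. Exactness
  is verified against full 2ⁿ enumeration for n ≤ 12.
* **Blocks and slopes**: the first 51 whisker trials in 17 blocks of 3;
  the x-coordinate of a block is its centre trial number (2, 5, …, 50);
  sessions with fewer trials are truncated to whole blocks and flagged.
  Learner selection requires Pearson p < 0.05 *and* r > 0 on the per-trial
  hit indicator versus trial number, which selects ~2.5% of stationary
  null sessions (one tail of the 5% criterion).
* **Across-day comparisons**: pairwise Wilcoxon signed-rank at the
  Bonferroni-corrected level α = 0.05/3 ≈ 0.017; mice missing a day are
  dropped pairwise and counted.
* **Normalization provenance**: the per-mouse σ is computed from the
  trial-averaged traces of every trial type available (lick-aligned where
  a report lick exists, onset-aligned otherwise) and recorded in the
  output metadata; whether free-licking sessions enter the pool is the
  caller's choice of inputs.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` validate on: 30–60 s two-carrier
records for demodulation accuracy (both 12 224 and 20 000 Hz); ~10-minute
free-licking sessions with 600 s bleach for dF/F₀ recovery at fractional
amplitudes 0.01/0.05/0.1; 100 behavioral sessions (25 per task) for exact
trial parsing; 50 coupled and 10 × 18 uncoupled whisker sessions of 120
trials for the learning-dynamics recovery; and 100 free-licking sessions of
120 trials per satiety condition. These sizes give the Monte-Carlo
estimates standard errors comfortably inside the asserted margins while
keeping a full run in the minutes range on a single core.

## What the synthetic validation does and does not show

The generator reproduces the statistical structure the analysis assumes:
carrier-modulated two-channel fluorescence, shared low-frequency motion,
mono-exponential bleaching, kernel-shaped transients tied to behavioral
events, logistic learning and satiety decay. Passing tests therefore
demonstrate that the pipeline recovers known ground truth under that
structure — they do not certify performance under real-world deviations
the model omits: hemodynamic or pH artifacts, non-exponential or
wavelength-coupled bleaching, movement artifacts that are not strictly
channel-proportional, electrical interference near the carriers, sensor
nonlinearity/saturation, video-scale body movement signals, or licking
kinematics beyond a stereotyped bout rhythm.

## Known limitations

* Early sensory and reward signals genuinely mix in fast-reaction Hit
  trials; the generator's 0.25 s reaction floor keeps the early window
  clean by construction, so the learning analyses here are best-case in
  that respect. Real Miss-trial analyses (which avoid the confound) are
  supported but not separately validated.
* The isosbestic fit is computed once per session; slow gain drift between
  channels within a session is not modelled and would leak into dF/F₀.
* Aborted attempts produce licks and abort events but no dopamine dip;
  only completed-trial unrewarded reporting bouts carry the dip kernel.
* The uncoupled learning control estimates the mean slope-correlation from
  10 × 18 sessions (s.e. ≈ 0.07); tightening it substantially would need
  an order of magnitude more simulated sessions.
* `select_learners` on a constant hit series is reported "not evaluable"
  rather than non-learner, because the correlation is undefined there.
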