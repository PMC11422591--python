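"""Lock-in recovery of the two excitation envelopes from the modulated detector signal.

A single photoreceiver collects fluorescence excited by two LEDs that are
sinusoidally intensity-modulated at distinct carrier frequencies (208.616 Hz
for the 465 nm dopamine-sensitive channel, 500.679 Hz for the 405 nm
isosbestic channel).  The detector voltage is therefore

    x(t) = F465(t) * e1(t) + F405(t) * e2(t) + offset,

where each excitation waveform is the non-negative
``e_i(t) = 0.5 * (1 + depth * sin(2 pi f_i t))``.  Because LED intensity cannot
be negative, the carrier term carries amplitude ``F * depth / 2``; the
demodulation scale convention compensates this factor so the recovered
envelope equals ``F`` itself.

Two independent algorithms are provided:

* :func:`lockin_demodulate` -- quadrature lock-in (multiply by sin/cos
  references, zero-phase low-pass, magnitude).  This is the pipeline route.
* :func:`sinefit_demodulate` -- windowed least-squares fit of both carrier
  sinusoids plus a DC term.  Slower, but algorithmically unrelated; it serves
  as a cross-check.

All analysis downstream runs on a uniform 1 kHz clock with exact 1 ms
spacing; :func:`downsample_1khz` maps an arbitrary (possibly non-integer
ratio) acquisition rate onto that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "ChannelTraces",
    "lockin_demodulate",
    "sinefit_demodulate",
    "downsample_1khz",
    "demodulate_recording",
]

#: analysis sample rate, Hz
FS_ANALYSIS = 1000.0

#: default lock-in low-pass corner, Hz.  Dopamine transients live below
#: ~10 Hz while the carriers are >= 208 Hz, so 25 Hz keeps signal intact
#: and strongly rejects the cross terms at |f2 - f1| ~ 292 Hz.
DEFAULT_LOWPASS_HZ = 25.0


@dataclass
class RawRecording:
    """Modulated detector voltage with its carrier metadata.

    Parameters
    ----------
    samples : ndarray
        Detector voltage at ``fs``.
    fs : float
        Acquisition rate in Hz; must exceed twice the highest carrier.
    carrier_freqs : tuple of float
        ``(f_465, f_405)`` modulation frequencies in Hz.
    t0 : float
        Time of the first sample, seconds.
    modulation_depth : float
        ``depth`` of the excitation waveform, in (0, 1].
    """

    samples: np.ndarray
    fs: float
    carrier_freqs: tuple[float, float] = (208.616, 500.679)
    t0: float = 0.0
    modulation_depth: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if len(self.carrier_freqs) != 2 or self.carrier_freqs[0] == self.carrier_freqs[1]:
            raise ValueError("carrier_freqs must be two distinct frequencies")
        if self.fs <= 2.0 * max(self.carrier_freqs):
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist for carriers {self.carrier_freqs}"
            )
        if not 0.0 < self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in (0, 1]")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class ChannelTraces:
    """Demodulated F465 / F405 envelopes on a shared clock."""

    f465: np.ndarray
    f405: np.ndarray
    fs: float = FS_ANALYSIS
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if self.f465.shape != self.f405.shape or self.f465.ndim != 1:
            raise ValueError("f465 and f405 must be 1-d arrays of equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.f465.size) / self.fs

    @property
    def duration(self) -> float:
        return self.f465.size / self.fs


def _check_cutoff(carrier_freqs, lowpass_cutoff: float) -> None:
    freqs = np.sort(np.asarray(carrier_freqs, dtype=float))
    seps = [freqs[0]] + list(np.diff(freqs))  # separation from DC and between carriers
    min_sep = min(seps)
    if lowpass_cutoff >= min_sep / 2.0:
        raise ValueError(
            f"lowpass cutoff {lowpass_cutoff} Hz is too high for a minimum "
            f"carrier separation of {min_sep:.1f} Hz (must be < {min_sep / 2:.1f} Hz)"
        )


def lockin_demodulate(
    raw: RawRecording,
    carrier: float,
    lowpass_cutoff: float = DEFAULT_LOWPASS_HZ,
) -> tuple[np.ndarray, float]:
    """Recover one excitation envelope by quadrature lock-in detection.

    The input is multiplied by sine and cosine references at ``carrier``,
    each product is low-passed with a zero-phase 4th-order Butterworth
    filter, and the envelope is ``(4 / depth) * sqrt(I^2 + Q^2)``.  The scale
    factor inverts the 0.5 excitation offset and the 1/2 from the product
    trigonometry, so an input ``A * 0.5 * (1 + depth*sin(2 pi f t))`` returns
    ``A`` in steady state.

    Returns
    -------
    envelope : ndarray
        Envelope at the raw sampling rate.
    group_delay_s : float
        Delay introduced by the filtering.  Zero here: offline forward-
        backward filtering is zero-phase.
    """
    if not any(np.isclose(carrier, f) for f in raw.carrier_freqs):
        raise ValueError(f"carrier {carrier} Hz is not one of {raw.carrier_freqs}")
    _check_cutoff(raw.carrier_freqs, lowpass_cutoff)

    t = raw.times
    w = 2.0 * np.pi * carrier * t
    i_raw = raw.samples * np.sin(w)
    q_raw = raw.samples * np.cos(w)
    sos = sps.butter(4, lowpass_cutoff, btype="low", fs=raw.fs, output="sos")
    i_f = sps.sosfiltfilt(sos, i_raw)
    q_f = sps.sosfiltfilt(sos, q_raw)
    envelope = (4.0 / raw.modulation_depth) * np.hypot(i_f, q_f)
    return envelope, 0.0


def sinefit_demodulate(
    raw: RawRecording,
    window_s: float = 0.05,
    step_s: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Envelope recovery by windowed sinusoidal least squares.

    Within each sliding window the detector voltage is regressed on
    ``[1, sin(2 pi f1 t), cos(2 pi f1 t), sin(2 pi f2 t), cos(2 pi f2 t)]``
    evaluated at absolute time, and each envelope is taken as
    ``(2 / depth) * sqrt(a_i^2 + b_i^2)`` at the window centre (the carrier
    term of channel i has amplitude ``F_i * depth / 2``).

    Returns ``(t_centres, env1, env2)`` where ``env1`` corresponds to
    ``carrier_freqs[0]``.
    """
    n_win = int(round(window_s * raw.fs))
    n_step = max(1, int(round(step_s * raw.fs)))
    if n_win < 8:
        raise ValueError("window too short for a stable sinusoid fit")
    t = raw.times
    f1, f2 = raw.carrier_freqs
    cols = np.column_stack(
        [
            np.ones_like(t),
            np.sin(2 * np.pi * f1 * t),
            np.cos(2 * np.pi * f1 * t),
            np.sin(2 * np.pi * f2 * t),
            np.cos(2 * np.pi * f2 * t),
        ]
    )
    starts = np.arange(0, raw.samples.size - n_win + 1, n_step)
    centres = np.empty(starts.size)
    env1 = np.empty(starts.size)
    env2 = np.empty(starts.size)
    for k, s in enumerate(starts):
        sl = slice(s, s + n_win)
        beta, *_ = np.linalg.lstsq(cols[sl], raw.samples[sl], rcond=None)
        centres[k] = t[s] + 0.5 * (n_win - 1) / raw.fs
        env1[k] = (2.0 / raw.modulation_depth) * np.hypot(beta[1], beta[2])
        env2[k] = (2.0 / raw.modulation_depth) * np.hypot(beta[3], beta[4])
    return centres, env1, env2


def downsample_1khz(trace: np.ndarray, fs_in: float, t0: float = 0.0) -> np.ndarray:
    """Resample a trace onto the exact 1 ms analysis grid.

    An anti-alias zero-phase low-pass (4th-order Butterworth, 400 Hz) is
    applied before interpolation, so any content above the 500 Hz output
    Nyquist is suppressed.  The output grid is ``t0 + k / 1000`` for
    ``k = 0 .. floor((n-1) * 1000 / fs_in)``, i.e. uniform at exactly 1 ms
    spacing regardless of whether ``fs_in / 1000`` is an integer.
    """
    trace = np.asarray(trace, dtype=float)
    if fs_in < FS_ANALYSIS:
        raise ValueError(f"fs_in={fs_in} Hz is below the 1 kHz analysis rate")
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("trace must be a 1-d array with at least 2 samples")
    if np.isclose(fs_in, FS_ANALYSIS):
        return trace.copy()
    sos = sps.butter(4, 400.0, btype="low", fs=fs_in, output="sos")
    filtered = sps.sosfiltfilt(sos, trace)
    t_in = np.arange(trace.size) / fs_in
    n_out = int(np.floor(t_in[-1] * FS_ANALYSIS)) + 1
    t_out = np.arange(n_out) / FS_ANALYSIS
    return np.interp(t_out, t_in, filtered)


def demodulate_recording(
    raw: RawRecording,
    lowpass_cutoff: float = DEFAULT_LOWPASS_HZ,
) -> ChannelTraces:
    """Full demodulation stage: lock-in on both carriers, then 1 kHz resampling.

    ``carrier_freqs[0]`` is the 465 nm (dopamine-sensitive) channel and
    ``carrier_freqs[1]`` the 405 nm isosbestic channel, following the
    acquisition convention.
    """
    env465, _ = lockin_demodulate(raw, raw.carrier_freqs[0], lowpass_cutoff)
    env405, _ = lockin_demodulate(raw, raw.carrier_freqs[1], lowpass_cutoff)
    f465 = downsample_1khz(env465, raw.fs, raw.t0)
    f405 = downsample_1khz(env405, raw.fs, raw.t0)
    return ChannelTraces(f465=f465, f405=f405, fs=FS_ANALYSIS, t0=raw.t0)
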