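"""Isosbestic correction, dF/F0 and per-mouse z-normalization.

The dopamine-insensitive 405 nm channel is least-squares scaled to the
465 nm channel over the whole session, ``fitted405 = a * f405 + b``, which
absorbs photobleaching and channel-shared motion artifacts.  The fractional
fluorescence change is then

    dF/F0 = (F465 - fitted405) / fitted405.

For cross-mouse and cross-day comparability, dF/F0 is divided by a single
per-mouse normalization factor: the standard deviation of the concatenated
trial-averaged traces across all trial types and tasks of that mouse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .demodulation import ChannelTraces

__all__ = [
    "IsosbesticFit",
    "DffTrace",
    "NormalizationFactor",
    "fit_isosbestic",
    "compute_dff",
    "compute_norm_factor",
    "apply_zscore",
    "preprocess_traces",
]


@dataclass
class IsosbesticFit:
    """Affine map of the 405 channel onto the 465 channel."""

    a: float
    b: float
    fitted405: np.ndarray


@dataclass
class DffTrace:
    """Fractional fluorescence change at 1 kHz with its fit provenance."""

    values: np.ndarray
    fit_coeffs: tuple[float, float]
    fs: float = 1000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dF/F0 contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class NormalizationFactor:
    """Single per-mouse z-normalization constant with its provenance."""

    sigma: float
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and positive")


def fit_isosbestic(f465: np.ndarray, f405: np.ndarray) -> IsosbesticFit:
    """Least-squares fit of the 405 nm channel to the 465 nm channel.

    Minimises ``sum((f465 - a*f405 - b)^2)`` over the whole session.  The
    intercept absorbs per-channel detector offsets.  Fails if the 405
    channel is constant (degenerate design) or if the fitted baseline is
    not strictly positive everywhere (it is the dF/F0 denominator).
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f465.shape != f405.shape or f465.ndim != 1:
        raise ValueError("f465 and f405 must be 1-d arrays of equal length")
    if f465.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(f405) == 0.0:
        raise ValueError("f405 is constant: isosbestic fit is degenerate")
    # normal equations of the affine least-squares problem
    m405 = f405.mean()
    m465 = f465.mean()
    d405 = f405 - m405
    a = float(np.dot(d405, f465 - m465) / np.dot(d405, d405))
    b = float(m465 - a * m405)
    fitted405 = a * f405 + b
    nonpos = np.flatnonzero(fitted405 <= 0.0)
    if nonpos.size:
        raise ValueError(
            f"fitted 405 baseline is non-positive at sample {int(nonpos[0])}"
        )
    return IsosbesticFit(a=float(a), b=float(b), fitted405=fitted405)


def compute_dff(
    f465: np.ndarray,
    fitted405: np.ndarray,
    fit_coeffs: tuple[float, float] = (np.nan, np.nan),
    fs: float = 1000.0,
    t0: float = 0.0,
) -> DffTrace:
    """dF/F0 = (F465 - fitted405) / fitted405, pointwise."""
    f465 = np.asarray(f465, dtype=float)
    fitted405 = np.asarray(fitted405, dtype=float)
    if f465.shape != fitted405.shape:
        raise ValueError("f465 and fitted405 must have equal shapes")
    if np.any(fitted405 <= 0.0):
        idx = int(np.flatnonzero(fitted405 <= 0.0)[0])
        raise ValueError(f"fitted405 non-positive at sample {idx}")
    values = (f465 - fitted405) / fitted405
    return DffTrace(values=values, fit_coeffs=tuple(fit_coeffs), fs=fs, t0=t0)


def preprocess_traces(
    channels: ChannelTraces, fit_exclude_edges_s: float = 1.0
) -> DffTrace:
    """Convenience stage: isosbestic fit followed by dF/F0.

    The affine fit is estimated on the session interior, excluding
    ``fit_exclude_edges_s`` seconds at each end where zero-phase filter
    settling can distort demodulated traces; the fitted baseline is then
    applied to the full trace.
    """
    n_edge = int(round(fit_exclude_edges_s * channels.fs))
    sl = slice(n_edge, channels.f465.size - n_edge)
    if sl.stop - sl.start < 2:
        sl = slice(None)
    fit = fit_isosbestic(channels.f465[sl], channels.f405[sl])
    fitted405 = fit.a * channels.f405 + fit.b
    if np.any(fitted405 <= 0):
        # filter settling can push edge samples below zero; clamp to the
        # smallest interior baseline rather than fail on edge artifacts
        floor = fit.fitted405.min()
        if floor <= 0:
            raise ValueError("fitted 405 baseline non-positive inside the session")
        fitted405 = np.maximum(fitted405, floor)
    return compute_dff(
        channels.f465, fitted405, fit_coeffs=(fit.a, fit.b),
        fs=channels.fs, t0=channels.t0,
    )


def compute_norm_factor(
    trial_averaged_traces: Iterable[np.ndarray],
    provenance: Sequence | None = None,
) -> NormalizationFactor:
    """Per-mouse normalization factor from trial-averaged traces.

    ``sigma`` is the standard deviation of all samples of the concatenated
    trial-averaged traces (one trace per trial type and task).  One factor
    per mouse is applied to every session.
    """
    traces = [np.asarray(tr, dtype=float) for tr in trial_averaged_traces]
    if not traces or any(tr.size == 0 for tr in traces):
        raise ValueError("need at least one non-empty trial-averaged trace")
    sigma = float(np.std(np.concatenate(traces)))
    if sigma == 0.0:
        raise ValueError("trial-averaged traces have zero variance")
    return NormalizationFactor(sigma=sigma, provenance=list(provenance or []))


def apply_zscore(dff: DffTrace | np.ndarray, factor: NormalizationFactor) -> np.ndarray:
    """Divide a dF/F0 trace by the per-mouse normalization factor."""
    values = dff.values if isinstance(dff, DffTrace) else np.asarray(dff, dtype=float)
    return values / factor.sigma
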