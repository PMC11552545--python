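"""Quantization of continuous signals into discrete state time series.

A "state" is an amplitude bin: quantizing a sampled signal (e.g., rectified
EMG) into ``n_states`` bins turns it into an integer-valued time series whose
windowed histograms are the probability distributions that the stochastic
dynamic operator (SDO) machinery works on.  This module holds the signal
container, the EMG preprocessing chain (notch / high-pass / moving-RMS, all
zero-phase), and the linear / logarithmic binning schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Signal",
    "Quantizer",
    "StateSeries",
    "FilterConfig",
    "preprocess_emg",
    "build_quantizer",
    "quantize",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled amplitude signal.

    Parameters
    ----------
    samples : ndarray, shape (T,)
        Amplitude per time bin, finite values only.
    fs : float
        Sampling rate in Hz, > 0.
    channel_id : str
        Free-form channel label.
    """

    samples: np.ndarray
    fs: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("signal samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Quantizer:
    """Monotone bin edges mapping amplitude to 1-based states.

    ``edges`` has ``n_states + 1`` strictly increasing entries spanning the
    amplitude range used to build the quantizer.  Bins are half-open
    ``[edge_i, edge_{i+1})`` with the top bin closed, so the observed maximum
    maps to state ``n_states``.  For the ``log`` scheme the edges are equal
    width in the log domain; ``log_offset`` is the positive floor added before
    taking logs when nonpositive values are present.
    """

    edges: np.ndarray
    scheme: str
    n_states: int
    log_offset: float = 0.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if self.n_states < 2:
            raise ValueError("n_states must be at least 2")
        if edges.size != self.n_states + 1:
            raise ValueError("edges must have n_states + 1 entries")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        if self.scheme not in ("linear", "log"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class StateSeries:
    """Discrete-time sequence of integer signal states in ``1..n_states``."""

    states: np.ndarray
    fs: float
    n_states: int

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if not np.issubdtype(states.dtype, np.integer):
            states = states.astype(np.int64)
        object.__setattr__(self, "states", states)
        if states.size and (states.min() < 1 or states.max() > self.n_states):
            raise ValueError("states must lie in [1, n_states]")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class FilterConfig:
    """EMG preprocessing settings.

    Defaults follow common practice for 2 kHz surface/intramuscular EMG:
    mains notch at 60 Hz and its first 8 harmonics, a 4th-order 10 Hz
    Butterworth high-pass, and a 20-point moving root-mean-square stage which
    rectifies and smooths.  All filters are applied forward-backward
    (zero-phase).
    """

    notch_hz: float = 60.0
    notch_harmonics: int = 8
    notch_q: float = 30.0
    hp_hz: float = 10.0
    hp_order: int = 4
    rms_points: int = 20


def preprocess_emg(raw: Signal, cfg: FilterConfig | None = None) -> Signal:
    """Apply the notch → high-pass → moving-RMS chain to a raw EMG signal.

    The output is nonnegative (RMS stage), the same length as the input, and
    zero-phase (no lag between input and output features).

    Raises
    ------
    ValueError
        If the signal is too short for the filters or the sampling rate
        cannot represent the highest notch harmonic.
    """
    cfg = cfg or FilterConfig()
    fs = raw.fs
    highest = cfg.notch_hz * cfg.notch_harmonics
    if fs <= 2.0 * highest:
        raise ValueError(
            f"fs={fs} Hz cannot notch harmonics up to {highest} Hz (need fs > {2 * highest})"
        )
    x = raw.samples.astype(float)
    # filtfilt needs padding longer than 3 * max(len(a), len(b)); the high-pass
    # SOS cascade dominates.
    min_len = 3 * (2 * cfg.hp_order + 1)
    if x.size <= min_len:
        raise ValueError(f"signal of {x.size} samples is shorter than the filter transient")

    for h in range(1, cfg.notch_harmonics + 1):
        b, a = sps.iirnotch(cfg.notch_hz * h, cfg.notch_q, fs=fs)
        x = sps.filtfilt(b, a, x)

    sos = sps.butter(cfg.hp_order, cfg.hp_hz, btype="highpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)

    # Moving RMS: sqrt of the centered moving average of x^2 (zero-phase).
    kernel = np.ones(cfg.rms_points) / cfg.rms_points
    power = np.convolve(x * x, kernel, mode="same")
    x = np.sqrt(np.maximum(power, 0.0))
    return Signal(samples=x, fs=fs, channel_id=raw.channel_id)


def notch_attenuation_db(cfg: FilterConfig, freq_hz: float, fs: float) -> float:
    """Magnitude response (dB) of the full notch cascade at ``freq_hz``.

    Forward-backward application squares the magnitude response, which is
    accounted for here.  Used to verify mains suppression.
    """
    total = 1.0
    for h in range(1, cfg.notch_harmonics + 1):
        b, a = sps.iirnotch(cfg.notch_hz * h, cfg.notch_q, fs=fs)
        _, resp = sps.freqz(b, a, worN=[freq_hz], fs=fs)
        total *= np.abs(resp[0]) ** 2  # zero-phase: applied twice
    return 20.0 * np.log10(max(total, 1e-300))


def build_quantizer(
    samples: np.ndarray,
    n_states: int = 20,
    scheme: str = "linear",
) -> Quantizer:
    """Build amplitude bin edges spanning the observed min..max of ``samples``.

    ``linear`` gives equal-width bins; ``log`` gives equal-width bins of the
    log-transformed amplitude (useful when the amplitude distribution is
    roughly exponential, as for rectified EMG).  If nonpositive values are
    present under the ``log`` scheme, half the smallest positive sample is
    added as a floor offset before the log transform.
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if not hi > lo:
        raise ValueError("degenerate amplitude range: max must exceed min")

    if scheme == "linear":
        edges = np.linspace(lo, hi, n_states + 1)
        return Quantizer(edges=edges, scheme="linear", n_states=n_states)
    if scheme == "log":
        offset = 0.0
        if lo <= 0.0:
            positive = x[x > 0]
            if positive.size == 0:
                raise ValueError("log scheme requires at least one positive sample")
            offset = 0.5 * float(positive.min())
        log_edges = np.linspace(np.log(lo + offset), np.log(hi + offset), n_states + 1)
        edges = np.exp(log_edges) - offset
        # guard fp round-trip so edges still span [lo, hi]
        edges[0], edges[-1] = lo, hi
        return Quantizer(edges=edges, scheme="log", n_states=n_states, log_offset=offset)
    raise ValueError(f"unknown scheme {scheme!r}")


def quantize(sig: Signal, q: Quantizer, warn_out_of_range: bool = True) -> StateSeries:
    """Map a signal to its 1-based state series under quantizer ``q``.

    Values exactly on an interior edge go to the higher bin; values at or
    above the top edge go to state ``n_states``; out-of-range values clamp to
    the end states (with a logged warning, since that indicates the quantizer
    was built on a different amplitude range).
    """
    x = sig.samples
    if np.any(np.isnan(x)):
        raise ValueError("cannot quantize NaN samples")
    below = x < q.edges[0]
    above = x > q.edges[-1]
    n_out = int(below.sum() + above.sum())
    if n_out and warn_out_of_range:
        logger.warning(
            "%d samples outside quantizer range [%g, %g]; clamping to end states",
            n_out,
            q.edges[0],
            q.edges[-1],
        )
    # side='right' implements [edge_i, edge_{i+1}); clip closes the top bin.
    states = np.searchsorted(q.edges, x, side="right")
    states = np.clip(states, 1, q.n_states).astype(np.int32)
    return StateSeries(states=states, fs=sig.fs, n_states=q.n_states)
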