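"""Deterministic signal primitives shared by all detection stages.

Everything here operates on :class:`Signal`, a thin container around a 1-D
sample array with a sampling rate and a start time.  The primitives are the
building blocks of the downstate and spindle detectors: zero-phase Butterworth
band-pass filtering, Hilbert analytic envelopes, unit-sum kernel smoothing
(Gaussian and Tukey-tapered moving averages), and an event-locked
time-frequency average with a surrogate-based significance mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Signal",
    "KernelSpec",
    "bandpass_filter",
    "analytic_envelope",
    "smooth",
    "event_locked_spectrogram",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Sample values (arbitrary units, nominally microvolts).
    rate_hz : float
        Sampling rate in Hz; must be positive.
    t0_s : float
        Time of the first sample in seconds.  Sample ``i`` occurs at
        ``t0_s + i / rate_hz``.
    """

    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if samples.ndim != 1:
            raise ValueError("Signal samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("Signal samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def times(self) -> np.ndarray:
        """Per-sample times in seconds."""
        return self.t0_s + np.arange(self.samples.size) / self.rate_hz

    def index_of(self, t_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped to range)."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.samples.size - 1)

    def with_samples(self, samples: np.ndarray) -> "Signal":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class KernelSpec:
    """A unit-sum smoothing kernel: moving average with a taper.

    ``gaussian`` uses a Gaussian of width ``sigma_s`` truncated to
    ``window_s`` of support.  ``tukey_avg`` is a Tukey-tapered moving average
    (a flat window with cosine-tapered edges); ``taper`` is the Tukey shape
    parameter in [0, 1] (0 = boxcar, 1 = Hann).
    Either way the kernel weights are non-negative and sum to one, so
    smoothing preserves constants.
    """

    kind: Literal["gaussian", "tukey_avg"]
    window_s: float
    sigma_s: float | None = None
    taper: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.kind == "gaussian":
            if self.sigma_s is None or self.sigma_s <= 0:
                raise ValueError("gaussian kernel requires sigma_s > 0")
        elif self.kind == "tukey_avg":
            if not 0.0 <= self.taper <= 1.0:
                raise ValueError("taper must lie in [0, 1]")
        else:
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    def weights(self, rate_hz: float) -> np.ndarray:
        """Kernel weights at a sampling rate, normalized to unit sum."""
        n = max(int(round(self.window_s * rate_hz)), 1)
        if n % 2 == 0:
            n += 1  # odd length keeps the kernel centered
        if self.kind == "gaussian":
            w = sps.windows.gaussian(n, std=self.sigma_s * rate_hz)
        else:
            w = sps.windows.tukey(n, alpha=self.taper)
        return w / w.sum()


def _reflect_pad_apply(x: np.ndarray, func, pad: int) -> np.ndarray:
    """Apply ``func`` to a reflection-padded copy of ``x``, then crop."""
    pad = min(pad, x.size - 1)
    if pad <= 0:
        return func(x)
    xp = np.pad(x, pad, mode="reflect")
    return func(xp)[pad:-pad]


def bandpass_filter(
    x: Signal,
    low_hz: float,
    high_hz: float,
    order: int = 4,
    zero_phase: bool = True,
) -> Signal:
    """Butterworth band-pass filter, zero-phase by default.

    Zero-phase filtering is implemented as forward-backward application of
    the order-``order`` filter (scipy ``sosfiltfilt``), giving no group delay
    at the cost of a squared magnitude response.  Edges are handled by
    reflection padding.

    Raises
    ------
    ValueError
        If the band edges are not ``0 < low < high < rate/2`` or ``order < 1``.
    """
    nyq = x.rate_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    if x.samples.size == 0:
        return x
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=x.rate_hz, output="sos")
    pad = min(x.samples.size - 1, int(3 * x.rate_hz / low_hz))
    if zero_phase:
        y = _reflect_pad_apply(x.samples, lambda v: sps.sosfiltfilt(sos, v, padtype=None), pad)
    else:
        y = _reflect_pad_apply(x.samples, lambda v: sps.sosfilt(sos, v), pad)
    return x.with_samples(y)


def analytic_envelope(x: Signal) -> Signal:
    """Instantaneous amplitude: modulus of the Hilbert analytic signal."""
    if x.samples.size < 4:
        raise ValueError("analytic_envelope requires at least 4 samples")
    pad = min(x.samples.size - 1, int(x.rate_hz))
    env = _reflect_pad_apply(x.samples, lambda v: np.abs(sps.hilbert(v)), pad)
    return x.with_samples(env)


def smooth(x: Signal, k: KernelSpec) -> Signal:
    """Convolve with a unit-sum kernel; reflection padding keeps the length.

    Because the kernel sums to one, a constant input maps to the same
    constant and the interior sample sum is conserved.
    """
    w = k.weights(x.rate_hz)
    if w.size >= x.samples.size:
        raise ValueError(
            f"kernel support ({w.size} samples) must be shorter than the signal "
            f"({x.samples.size} samples)"
        )
    half = w.size // 2
    y = _reflect_pad_apply(x.samples, lambda v: np.convolve(v, w, mode="same"), half)
    return x.with_samples(y)


@dataclass
class SpectrogramResult:
    """Event-locked average time-frequency power with a significance mask."""

    times_s: np.ndarray            # epoch time axis (s, relative to event)
    freqs_hz: np.ndarray
    power_db: np.ndarray           # (freq, time), baseline-corrected dB
    significant: np.ndarray        # boolean (freq, time)
    n_events: int
    n_surrogates: int


def _epoch_power(
    x: np.ndarray,
    rate_hz: float,
    centers: np.ndarray,
    n_before: int,
    n_after: int,
    nperseg: int,
    f_lo: float,
    f_hi: float,
):
    """Mean short-time power over epochs centred at sample indices."""
    stack = None
    count = 0
    for c in centers:
        seg = x[c - n_before : c + n_after]
        f, t, sxx = sps.spectrogram(
            seg,
            fs=rate_hz,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg - max(int(round(0.025 * rate_hz)), 1),
            mode="psd",
        )
        if stack is None:
            sel = (f >= f_lo) & (f <= f_hi)
            stack = np.zeros((sel.sum(), t.size))
            fsel, tgrid = f[sel], t
        stack += sxx[sel]
        count += 1
    return fsel, tgrid, stack / count


def event_locked_spectrogram(
    x: Signal,
    event_times_s: Sequence[float],
    window_s: tuple[float, float] = (-1.0, 1.0),
    f_range_hz: tuple[float, float] = (2.0, 100.0),
    alpha: float = 0.01,
    n_surrogates: int = 200,
    seed: int | None = None,
) -> SpectrogramResult:
    """Average event-locked spectrogram with a surrogate significance mask.

    Power is averaged over epochs around each event, converted to dB and
    baseline-corrected by the epoch-wide mean per frequency.  Significance
    (uncorrected, two-sided at ``alpha``) is assessed per (frequency, time)
    cell against ``n_surrogates`` surrogate averages computed at circularly
    shifted event times.
    """
    events = np.asarray(list(event_times_s), dtype=float)
    if events.size == 0:
        raise ValueError("event_locked_spectrogram requires at least one event")
    if events.size < 10:
        raise ValueError("need >= 10 events for a stable spectrogram estimate")
    rate = x.rate_hz
    n_before = int(round(-window_s[0] * rate))
    n_after = int(round(window_s[1] * rate))
    centers = np.array([x.index_of(t) for t in events])
    ok = (centers >= n_before) & (centers + n_after <= x.samples.size)
    if not np.all(ok):
        raise ValueError("all epochs must fit within the recording")
    nperseg = max(int(round(0.5 * rate)), 8)

    f, t, mean_p = _epoch_power(
        x.samples, rate, centers, n_before, n_after, nperseg, *f_range_hz
    )
    power_db = 10 * np.log10(mean_p + np.finfo(float).tiny)
    power_db -= power_db.mean(axis=1, keepdims=True)  # epoch-wide baseline

    rng = np.random.default_rng(seed)
    lo, hi = n_before, x.samples.size - n_after
    sur = np.empty((n_surrogates,) + power_db.shape)
    for s in range(n_surrogates):
        shift = rng.integers(0, x.samples.size)
        sc = (centers + shift) % x.samples.size
        sc = np.clip(sc, lo, hi - 1)
        _, _, sp = _epoch_power(x.samples, rate, sc, n_before, n_after, nperseg, *f_range_hz)
        spdb = 10 * np.log10(sp + np.finfo(float).tiny)
        sur[s] = spdb - spdb.mean(axis=1, keepdims=True)
    lo_q = np.quantile(sur, alpha / 2, axis=0)
    hi_q = np.quantile(sur, 1 - alpha / 2, axis=0)
    significant = (power_db < lo_q) | (power_db > hi_q)
    if alpha >= 1.0:
        significant = np.ones_like(significant, dtype=bool)
    return SpectrogramResult(
        times_s=t + window_s[0],
        freqs_hz=f,
        power_db=power_db,
        significant=significant,
        n_events=int(events.size),
        n_surrogates=n_surrogates,
    )
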