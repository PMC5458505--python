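"""Temporal coordination statistics for downstates and spindles.

Peri-event histograms (50 ms bins), exact binomial tests of temporal order
over +/-500 ms with Bonferroni correction, conditional thalamic-DS
probabilities given multi-channel cortical DSs, cortico-thalamic DS delay
from event-locked average waveforms, DS onset latency from the inflections
of a degree-20 polynomial fit, per-trough high-gamma peak delays between
structures, and the enrichment-factor / coupling-proportion / overlap
summaries used to quantify DS-spindle coordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import interpolate, stats

from .recording import CORTEX, THALAMUS
from .signal_core import Signal, analytic_envelope, bandpass_filter

__all__ = [
    "EventHistogram",
    "OrderTestResult",
    "DelayEstimate",
    "EnrichmentResult",
    "event_histogram",
    "binomial_order_test",
    "bonferroni_level",
    "conditional_ds_probability",
    "corticothalamic_ds_delay",
    "ds_onset_latency",
    "histogram_peak_latency",
    "gamma_trough_delay",
    "enrichment_factor",
    "proportion_spindles_with_ds",
    "overlap_fraction",
]


@dataclass
class EventHistogram:
    """Counts of target-event lags relative to reference events, 50 ms bins."""

    ref_channel: str
    target_channel: str
    ref_type: str
    target_type: str
    bin_s: float
    edges_s: np.ndarray
    counts: np.ndarray

    @property
    def centers_s(self) -> np.ndarray:
        return (self.edges_s[:-1] + self.edges_s[1:]) / 2


def event_histogram(
    ref_times: Sequence[float],
    target_times: Sequence[float],
    bin_s: float = 0.05,
    window_s: float = 2.0,
    ref_channel: str = "",
    target_channel: str = "",
    ref_type: str = "",
    target_type: str = "",
) -> EventHistogram:
    """Histogram of all (reference, target) lags within +/-``window_s``.

    Bin edges sit at integer multiples of ``bin_s``; every pair whose lag
    falls inside the window is counted (not just nearest events).
    """
    ref = np.asarray(ref_times, dtype=float)
    tgt = np.asarray(target_times, dtype=float)
    n_bins = int(round(window_s / bin_s))
    edges = bin_s * np.arange(-n_bins, n_bins + 1)
    counts = np.zeros(edges.size - 1, dtype=int)
    if ref.size == 0:
        warnings.warn("empty reference event list; returning all-zero histogram")
    elif tgt.size:
        tgt = np.sort(tgt)
        for r in ref:
            lags = tgt[np.searchsorted(tgt, r - window_s) : np.searchsorted(tgt, r + window_s)] - r
            counts += np.histogram(lags, bins=edges)[0]
    return EventHistogram(
        ref_channel=ref_channel, target_channel=target_channel,
        ref_type=ref_type, target_type=target_type,
        bin_s=bin_s, edges_s=edges, counts=counts,
    )


@dataclass
class OrderTestResult:
    n_before: int
    n_after: int
    p_two_sided: float
    alpha_adjusted: float
    significant: bool
    direction: str               # "ref-leads" | "target-leads" | "none"


def _paired_lags(
    ref: np.ndarray, tgt: np.ndarray, window_s: float, mode: str
) -> np.ndarray:
    tgt = np.sort(tgt)
    lags = []
    for r in ref:
        sel = tgt[np.searchsorted(tgt, r - window_s) : np.searchsorted(tgt, r + window_s)] - r
        if mode == "all":
            lags.extend(sel)
        elif sel.size:
            lags.append(sel[np.argmin(np.abs(sel))])
    return np.asarray(lags, dtype=float)


def binomial_order_test(
    ref_times: Sequence[float],
    target_times: Sequence[float],
    window_s: float = 0.5,
    alpha_adjusted: float = 0.05,
    pairing: str = "all",
) -> OrderTestResult:
    """Exact two-sided binomial test of temporal order over +/-500 ms.

    Counts target events before versus after each reference event (zero lags
    excluded) and tests the counts against a fair coin.  ``pairing="all"``
    counts every pair inside the window (mirroring the peri-event
    histogram); ``"nearest"`` counts only each reference's nearest target.
    """
    ref = np.asarray(ref_times, dtype=float)
    tgt = np.asarray(target_times, dtype=float)
    lags = _paired_lags(ref, tgt, window_s, pairing)
    n_before = int(np.sum(lags < 0))
    n_after = int(np.sum(lags > 0))
    n = n_before + n_after
    if n == 0:
        raise ValueError("no counted pairs inside the window; order test undefined")
    p = float(stats.binomtest(n_after, n, 0.5).pvalue)
    significant = p < alpha_adjusted
    if not significant:
        direction = "none"
    else:
        direction = "ref-leads" if n_after > n_before else "target-leads"
    return OrderTestResult(n_before, n_after, p, alpha_adjusted, significant, direction)


def bonferroni_level(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ConditionalDsProbability:
    """P(thalamic DS soon after a cortical DS), alone and jointly."""

    cortical_channels: list[str]
    thalamic_channel: str
    probability: np.ndarray      # (n_ctx, n_ctx); diag: single-channel
    n_conditioning: np.ndarray   # events entering each cell
    p_chi2: np.ndarray           # off-diagonal cells vs their row's diagonal
    alpha_adjusted: float
    significant: np.ndarray


def conditional_ds_probability(
    cortical_events: dict[str, Sequence[float]],
    thalamic_events: Sequence[float],
    window_s: float = 0.5,
    alpha: float = 0.05,
) -> ConditionalDsProbability:
    """Probability of a thalamic DS within 500 ms after a cortical DS.

    Cell (i, i) conditions on a DS in cortical channel i alone; cell (i, j)
    additionally requires a DS in channel j within the same window after the
    channel-i DS.  Each off-diagonal cell is tested by a chi-square test of
    proportions against the *disjoint* complement (channel-i DSs with no
    channel-j DS in the window) — the joint events are a subset of the
    single-channel events, so testing against the diagonal itself would be
    conservative.  Bonferroni correction runs over the tested cells; cells
    with no conditioning events are NaN.
    """
    names = list(cortical_events)
    thal = np.sort(np.asarray(thalamic_events, dtype=float))
    n = len(names)
    prob = np.full((n, n), np.nan)
    ncond = np.zeros((n, n), dtype=int)
    hits = np.zeros((n, n), dtype=int)
    ncond_not = np.zeros((n, n), dtype=int)   # channel-i DSs without channel-j
    hits_not = np.zeros((n, n), dtype=int)

    def thal_follows(t: float) -> bool:
        i = np.searchsorted(thal, t)
        return i < thal.size and thal[i] - t <= window_s

    sorted_events = {c: np.sort(np.asarray(v, dtype=float)) for c, v in cortical_events.items()}
    for i, ci in enumerate(names):
        for t in sorted_events[ci]:
            followed = thal_follows(t)
            ncond[i, i] += 1
            hits[i, i] += followed
            for j, cj in enumerate(names):
                if j == i:
                    continue
                other = sorted_events[cj]
                k = np.searchsorted(other, t)
                if k < other.size and other[k] - t <= window_s:
                    ncond[i, j] += 1
                    hits[i, j] += followed
                else:
                    ncond_not[i, j] += 1
                    hits_not[i, j] += followed
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(ncond > 0, hits / np.maximum(ncond, 1), np.nan)

    p_chi2 = np.full((n, n), np.nan)
    n_tests = max(int(np.sum((ncond > 0) & ~np.eye(n, dtype=bool))), 1)
    adj = bonferroni_level(alpha, n_tests)
    for i in range(n):
        for j in range(n):
            if i == j or ncond[i, j] == 0 or ncond_not[i, j] == 0:
                continue
            table = np.array([
                [hits[i, j], ncond[i, j] - hits[i, j]],
                [hits_not[i, j], ncond_not[i, j] - hits_not[i, j]],
            ])
            if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
                continue
            p_chi2[i, j] = stats.chi2_contingency(table, correction=False)[1]
    significant = np.where(np.isnan(p_chi2), False, p_chi2 < adj)
    return ConditionalDsProbability(
        cortical_channels=names, thalamic_channel="",
        probability=prob, n_conditioning=ncond, p_chi2=p_chi2,
        alpha_adjusted=adj, significant=significant,
    )


@dataclass
class DelayEstimate:
    kind: str
    value_s: float
    per_pair_s: dict = field(default_factory=dict)
    statistic: float | None = None
    p_value: float | None = None
    n: int = 0


def corticothalamic_ds_delay(
    pairs: Sequence[tuple[str, str]],
    signals: dict[str, Signal],
    ds_events: dict[str, Sequence[float]],
    window_s: float = 0.5,
    band_hz: tuple[float, float] = (0.1, 4.0),
    min_events: int = 10,
) -> DelayEstimate:
    """Cortical-to-thalamic DS peak delay from event-locked waveforms.

    For each (cortex, thalamus) pair, thalamic DS peaks preceded by a
    cortical DS within 500 ms are collected; the 0.1-4 Hz cortical signal is
    averaged locked to those thalamic peaks and the pair's latency is the
    time of the waveform minimum in [-0.5, 0] s.  The overall value averages
    the per-pair latencies (it is negative: cortex leads).
    """
    per_pair: dict[tuple[str, str], float] = {}
    for ctx, thal in pairs:
        sig = signals[ctx]
        filt = bandpass_filter(sig, *band_hz)
        ctx_peaks = np.sort(np.asarray(ds_events[ctx], dtype=float))
        thal_peaks = np.asarray(ds_events[thal], dtype=float)
        qualifying = []
        for t in thal_peaks:
            i = np.searchsorted(ctx_peaks, t) - 1
            if i >= 0 and 0.0 < t - ctx_peaks[i] <= window_s:
                qualifying.append(t)
        if len(qualifying) < min_events:
            warnings.warn(f"pair {ctx}->{thal}: only {len(qualifying)} qualifying events; skipped")
            continue
        half = int(round(window_s * sig.rate_hz))
        segs = []
        for t in qualifying:
            c = sig.index_of(t)
            if c - half < 0 or c + half + 1 > filt.samples.size:
                continue
            segs.append(filt.samples[c - half : c + half + 1])
        if not segs:
            continue
        avg = np.mean(segs, axis=0)
        lags = (np.arange(avg.size) - half) / sig.rate_hz
        pre = lags <= 0
        per_pair[(ctx, thal)] = float(lags[pre][np.argmin(avg[pre])])
    if not per_pair:
        raise ValueError("no pair had enough qualifying events")
    vals = np.array(list(per_pair.values()))
    return DelayEstimate(
        kind="ct_ds_delay", value_s=float(vals.mean()),
        per_pair_s={f"{a}->{b}": v for (a, b), v in per_pair.items()},
        n=len(per_pair),
    )


def ds_onset_latency(avg_waveform: Signal, guess_s: float) -> float:
    """DS onset as the polynomial-inflection time closest to a visual guess.

    A degree-20 polynomial is fitted to the average waveform on a time axis
    normalized to [-1, 1] (for conditioning); the real roots of its second
    derivative inside the window are the inflection candidates, and the one
    closest to ``guess_s`` is returned (earlier wins ties).
    """
    t = avg_waveform.times()
    x = 2.0 * (t - t[0]) / (t[-1] - t[0]) - 1.0
    poly = np.polynomial.Polynomial.fit(x, avg_waveform.samples, deg=20, domain=[-1, 1])
    roots = poly.deriv(2).roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real >= -1.0) & (real <= 1.0)]
    if real.size == 0:
        raise ValueError("polynomial fit has no real inflection inside the window")
    times = t[0] + (real + 1.0) / 2.0 * (t[-1] - t[0])
    order = np.lexsort((times, np.abs(times - guess_s)))
    return float(times[order[0]])


def histogram_peak_latency(h: EventHistogram) -> float:
    """Centre of the maximal histogram bin (ties: nearest zero, then earlier)."""
    if not np.any(h.counts):
        raise ValueError("all-zero histogram has no peak")
    centers = h.centers_s
    maxima = np.nonzero(h.counts == h.counts.max())[0]
    order = np.lexsort((centers[maxima], np.abs(centers[maxima])))
    return float(centers[maxima[order[0]]])


def gamma_trough_delay(
    x_thal: Signal,
    x_cort: Signal,
    thal_spindle_troughs: Sequence[float],
    subset_size: int = 500,
    search_s: float = 0.035,
    band_hz: tuple[float, float] = (55.0, 100.0),
    upsample: int = 8,
) -> DelayEstimate:
    """Thalamo-cortical delay of spindle-trough-locked high-gamma peaks.

    The 55-100 Hz analytic amplitude of each structure is spline-interpolated
    and, for every thalamic spindle trough, the nearest local maximum within
    +/-35 ms is located in each structure; the delay is the cortical minus
    the thalamic peak time.  Troughs lacking a peak in either structure are
    excluded.  Consecutive blocks of ``subset_size`` troughs give per-subset
    mean latencies, compared by a two-tailed paired t-test.
    """
    troughs = np.asarray(thal_spindle_troughs, dtype=float)
    if troughs.size == 0:
        raise ValueError("no spindle troughs supplied")

    from scipy.signal import find_peaks

    def peak_times(sig: Signal) -> tuple[np.ndarray, np.ndarray]:
        env = analytic_envelope(bandpass_filter(sig, *band_hz))
        t = env.times()
        fine_t = np.linspace(t[0], t[-1], (t.size - 1) * upsample + 1)
        spline = interpolate.CubicSpline(t, env.samples)
        fine = spline(fine_t)
        # prominence floor: a qualifying peak must be a clear gamma burst
        # (prominence at least twice the typical envelope level), not a
        # micro-maximum of the noise envelope; troughs without such a peak
        # in either structure are excluded and counted
        pk, _ = find_peaks(fine, prominence=2.0 * float(np.median(fine)))
        return fine_t[pk], fine[pk]

    thal_pk, _ = peak_times(x_thal)
    cort_pk, _ = peak_times(x_cort)

    def nearest(peaks: np.ndarray, t: float) -> float | None:
        i = np.searchsorted(peaks, t)
        best = None
        for j in (i - 1, i):
            if 0 <= j < peaks.size and abs(peaks[j] - t) <= search_s:
                if best is None or abs(peaks[j] - t) < abs(best - t):
                    best = peaks[j]
        return best

    lat_thal, lat_cort = [], []
    n_excluded = 0
    for t in np.sort(troughs):
        pt, pc = nearest(thal_pk, t), nearest(cort_pk, t)
        if pt is None or pc is None:
            n_excluded += 1
            continue
        lat_thal.append(pt - t)
        lat_cort.append(pc - t)
    lat_thal = np.asarray(lat_thal)
    lat_cort = np.asarray(lat_cort)
    if lat_thal.size == 0:
        raise ValueError("no troughs had gamma peaks in both structures")
    delays = lat_cort - lat_thal
    value = float(delays.mean())
    n_sub = lat_thal.size // subset_size
    stat = pval = None
    if n_sub >= 2:
        sub_c = np.array([lat_cort[i * subset_size:(i + 1) * subset_size].mean() for i in range(n_sub)])
        sub_t = np.array([lat_thal[i * subset_size:(i + 1) * subset_size].mean() for i in range(n_sub)])
        stat, pval = stats.ttest_rel(sub_c, sub_t)
        stat, pval = float(stat), float(pval)
    else:
        warnings.warn(
            f"only {lat_thal.size} usable troughs (< 2 subsets of {subset_size}); "
            "single-group estimate, no test"
        )
    est = DelayEstimate(
        kind="gamma_trough", value_s=value, statistic=stat, p_value=pval, n=int(lat_thal.size)
    )
    est.per_pair_s["n_excluded"] = n_excluded
    return est


@dataclass
class EnrichmentResult:
    peak_density_per_min: float
    overall_density_per_min: float
    factor: float
    peak_bin_center_s: float
    n_spindles: int
    n_ds: int


def enrichment_factor(
    spindle_onsets: Sequence[float],
    ds_peaks: Sequence[float],
    total_minutes: float,
    bin_s: float = 0.05,
    window_s: float = 0.5,
) -> EnrichmentResult:
    """Peak DS-locked spindle density relative to the overall spindle density.

    Peak density per minute is (20 * 60 * count in the tallest 50 ms bin
    within +/-500 ms of DS peaks) / n_DS; the factor divides it by the
    overall density n_spindles / total_minutes.
    """
    if total_minutes <= 0:
        raise ValueError("total_minutes must be positive")
    ds = np.asarray(ds_peaks, dtype=float)
    sp = np.asarray(spindle_onsets, dtype=float)
    if ds.size == 0:
        raise ValueError("enrichment_factor requires at least one DS")
    if sp.size == 0:
        return EnrichmentResult(0.0, 0.0, 0.0, np.nan, 0, int(ds.size))
    h = event_histogram(ds, sp, bin_s=bin_s, window_s=window_s)
    tallest = int(h.counts.max())
    # with 50 ms bins this is the printed (20 * 60 * tallest) / n_DS
    peak_density = (1.0 / bin_s) * 60.0 * tallest / ds.size
    peak_center = histogram_peak_latency(h) if tallest > 0 else np.nan
    overall = sp.size / total_minutes
    return EnrichmentResult(
        peak_density_per_min=peak_density,
        overall_density_per_min=overall,
        factor=peak_density / overall if overall > 0 else 0.0,
        peak_bin_center_s=peak_center,
        n_spindles=int(sp.size),
        n_ds=int(ds.size),
    )


def proportion_spindles_with_ds(
    spindle_onsets: Sequence[float],
    ds_peaks: Sequence[float],
    region: str,
    ds_counts_in_subject: Sequence[int],
) -> float:
    """Normalized proportion of spindles starting in a DS coupling window.

    Cortical spindles count as coupled when they begin within [0, +750] ms
    after a DS peak; thalamic spindles within [-500, +250] ms of a DS peak.
    The raw proportion is normalized by (channel DS count / largest DS count
    in the subject).
    """
    sp = np.asarray(spindle_onsets, dtype=float)
    ds = np.sort(np.asarray(ds_peaks, dtype=float))
    if sp.size == 0:
        raise ValueError("at least one spindle is required")
    if len(ds_counts_in_subject) == 0:
        raise ValueError("ds_counts_in_subject must be non-empty")
    if ds.size == 0:
        raise ValueError("channel has no DSs; proportion undefined")
    lo, hi = (0.0, 0.75) if region == CORTEX else (-0.5, 0.25)
    coupled = 0
    for t in sp:
        i = np.searchsorted(ds, t - hi)
        j = np.searchsorted(ds, t - lo, side="right")
        if j > i:
            coupled += 1
    raw = coupled / sp.size
    denom = ds.size / max(ds_counts_in_subject)
    return raw / denom


def overlap_fraction(
    events_a: Sequence[tuple[float, float]],
    events_b: Sequence[tuple[float, float]],
) -> tuple[float, list[tuple[int, int]]]:
    """Fraction of a-events intersecting any b-event (touching counts).

    Returns the proportion and the matched (i, j) index pairs.
    """
    matched: list[tuple[int, int]] = []
    hit = np.zeros(len(events_a), dtype=bool)
    for i, (a0, a1) in enumerate(events_a):
        for j, (b0, b1) in enumerate(events_b):
            if a0 <= b1 and b0 <= a1:
                matched.append((i, j))
                hit[i] = True
    frac = float(hit.mean()) if len(events_a) else 0.0
    return frac, matched
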