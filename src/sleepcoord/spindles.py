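"""Spindle detection: envelope-threshold and classifier-based methods.

Two detectors are implemented.

The *previous* method thresholds the Gaussian-smoothed Hilbert envelope of
the 10-16 Hz band-passed signal at mean + 3 SD (cortex) or mean + 1.5 SD
(thalamus), with event boundaries at the mean + 1 SD crossings and durations
restricted to 0.3-2 s.

The *current* method works in two steps.  Candidate epochs are located at
peaks of a doubly smoothed spindle-band envelope exceeding a per-channel
threshold derived from manually marked spindles, with onsets/offsets where a
singly smoothed "edge" envelope exceeds 45% of its matched peak.  A
per-channel logistic regression over 15 epoch metrics then decides which
candidates are spindles: predictors are screened for collinearity by
iterative VIF removal, selected by bidirectional stepwise AIC, checked for
stability by a bootstrap of the selection, and the probability cutoff is set
where leave-one-out false-positive and false-negative rates are equal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal as sps

from .recording import CORTEX, Recording
from .signal_core import KernelSpec, Signal, analytic_envelope, bandpass_filter, smooth

__all__ = [
    "FEATURE_NAMES",
    "CandidateEpoch",
    "SpindleEvent",
    "SpindleClassifier",
    "SpindleClassifierModel",
    "SpindleClassifierResults",
    "previous_method_detect",
    "compute_envelopes",
    "candidate_threshold_from_marks",
    "find_candidate_epochs",
    "extract_features",
    "FeatureExtractor",
    "prune_collinear_vif",
    "stepwise_select_aic",
    "bootstrap_stability",
    "choose_probability_threshold",
    "apply_classifier",
    "train_spindle_classifier",
    "detect_spindles",
]

SPINDLE_BAND = (10.0, 16.0)
LOW_BAND = (4.0, 8.0)
HIGH_BAND = (18.0, 25.0)
NONSPINDLE_FFT_BAND = (5.0, 8.0)
MIN_EPOCH_S = 0.3

FEATURE_NAMES = [
    "amp", "dur", "spindle_power", "nonspindle_power", "f_ratio",
    "spindle_freq", "sband_amp", "lband_amp", "hband_amp", "stage",
    "npeaks", "peakrate", "peak_intv_mean", "peak_intv_std", "pr",
]


@dataclass
class CandidateEpoch:
    """A potential spindle located at an amplitude-envelope peak."""

    channel: str
    onset_s: float
    offset_s: float
    peak_s: float              # location of the amplitude-envelope maximum
    amp_env_peak: float
    edge_amp: float
    label: int | None = None   # 1 spindle, 0 non-spindle, None unlabelled
    probability: float | None = None

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def spindle_class(freq_hz: float) -> str:
    """Slow (>10, <=12 Hz) versus fast (>12, <16 Hz) spindle classing."""
    return "slow" if freq_hz <= 12.0 else "fast"


@dataclass
class SpindleEvent:
    channel: str
    onset_s: float
    offset_s: float
    peak_amp: float
    spindle_freq: float
    probability: float | None = None
    method: str = "current"

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def freq_class(self) -> str:
        return spindle_class(self.spindle_freq)


# ---------------------------------------------------------------------------
# previous (envelope threshold) method


def previous_method_detect(
    x: Signal,
    region: str,
    sd_detect: float | None = None,
    channel: str = "",
) -> list[SpindleEvent]:
    """Threshold detector on the smoothed spindle-band Hilbert envelope.

    Detection requires the envelope to exceed mean + 3 SD (cortex) or
    mean + 1.5 SD (thalamus); start/stop are the mean + 1 SD crossings, and
    only events lasting 0.3-2 s are kept.
    """
    if sd_detect is None:
        sd_detect = 3.0 if region == CORTEX else 1.5
    bp = bandpass_filter(x, *SPINDLE_BAND)
    env = smooth(analytic_envelope(bp), KernelSpec("gaussian", window_s=0.3, sigma_s=0.04))
    e = env.samples
    mu, sd = float(e.mean()), float(e.std())
    thr_hi, thr_lo = mu + sd_detect * sd, mu + 1.0 * sd
    above = e > thr_lo
    events: list[SpindleEvent] = []
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    for a, b in zip(starts, ends):
        seg = e[a:b]
        if seg.max(initial=-np.inf) < thr_hi:
            continue
        dur = (b - a) / x.rate_hz
        if not (0.3 <= dur <= 2.0):
            continue
        onset = x.t0_s + a / x.rate_hz
        offset = x.t0_s + b / x.rate_hz
        events.append(SpindleEvent(
            channel=channel, onset_s=onset, offset_s=offset,
            peak_amp=float(seg.max()),
            spindle_freq=_segment_peak_freq(x, onset, offset),
            method="previous",
        ))
    return events


def _segment_peak_freq(x: Signal, onset: float, offset: float) -> float:
    i0, i1 = x.index_of(onset), x.index_of(offset)
    seg = x.samples[i0:i1]
    if seg.size < 8:
        return float("nan")
    spec, freqs = _amplitude_spectrum(seg, x.rate_hz)
    sel = (freqs >= SPINDLE_BAND[0]) & (freqs <= SPINDLE_BAND[1])
    return float(freqs[sel][np.argmax(spec[sel])])


# ---------------------------------------------------------------------------
# current method, step 1: envelopes and candidate epochs


def compute_envelopes(x: Signal) -> tuple[Signal, Signal]:
    """Edge and amplitude envelopes of the spindle band.

    The edge envelope is the rectified 10-16 Hz band-passed signal convolved
    with a unit-sum 400 ms Tukey window (used for candidate boundaries); the
    amplitude envelope applies a further 600 ms Tukey average (used to locate
    candidates).
    """
    if x.duration_s <= 1.0:
        raise ValueError("compute_envelopes needs more than 1 s of signal")
    bp = bandpass_filter(x, *SPINDLE_BAND)
    edge = smooth(bp.with_samples(np.abs(bp.samples)), KernelSpec("tukey_avg", window_s=0.4))
    amp = smooth(edge, KernelSpec("tukey_avg", window_s=0.6))
    return edge, amp


def candidate_threshold_from_marks(
    amplitude_env: Signal,
    marks: Sequence[tuple[float, float]],
) -> float:
    """Smallest over marks of each mark's largest amplitude-envelope peak."""
    if not marks:
        raise ValueError("at least one manual mark is required to set the threshold")
    peaks, _ = sps.find_peaks(amplitude_env.samples)
    peak_t = amplitude_env.t0_s + peaks / amplitude_env.rate_hz
    manual_amps = []
    for a, b in marks:
        inside = peaks[(peak_t >= a) & (peak_t <= b)]
        if inside.size == 0:
            warnings.warn(f"mark [{a:.2f}, {b:.2f}] s contains no envelope peak; skipped")
            continue
        manual_amps.append(float(amplitude_env.samples[inside].max()))
    if not manual_amps:
        raise ValueError("no mark contained an amplitude-envelope local maximum")
    return min(manual_amps)


def find_candidate_epochs(
    edge_env: Signal,
    amplitude_env: Signal,
    threshold: float,
    channel: str = "",
) -> list[CandidateEpoch]:
    """Candidate epochs around supra-threshold amplitude-envelope peaks.

    For each peak, the matched edge amplitude is the nearest edge-envelope
    local maximum; the epoch spans the contiguous region around it where the
    edge envelope stays >= 0.45 x edge amplitude.  Epochs shorter than
    300 ms are discarded and overlapping epochs are merged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rate = edge_env.rate_hz
    amp_peaks, _ = sps.find_peaks(amplitude_env.samples)
    amp_peaks = amp_peaks[amplitude_env.samples[amp_peaks] >= threshold]
    edge_peaks, _ = sps.find_peaks(edge_env.samples)
    if amp_peaks.size == 0 or edge_peaks.size == 0:
        return []
    e = edge_env.samples
    raw_epochs: list[tuple[int, int, int, float]] = []
    for pk in amp_peaks:
        ek = edge_peaks[np.argmin(np.abs(edge_peaks - pk))]
        edge_amp = float(e[ek])
        lim = 0.45 * edge_amp
        a = ek
        while a > 0 and e[a - 1] >= lim:
            a -= 1
        b = ek
        while b < e.size - 1 and e[b + 1] >= lim:
            b += 1
        if (b - a + 1) / rate < MIN_EPOCH_S:
            continue
        raw_epochs.append((a, b, pk, edge_amp))
    raw_epochs.sort()
    merged: list[list] = []
    for a, b, pk, ea in raw_epochs:
        if merged and a <= merged[-1][1]:
            m = merged[-1]
            m[1] = max(m[1], b)
            if amplitude_env.samples[pk] > amplitude_env.samples[m[2]]:
                m[2], m[3] = pk, ea
        else:
            merged.append([a, b, pk, ea])
    t0 = edge_env.t0_s
    return [
        CandidateEpoch(
            channel=channel,
            onset_s=t0 + a / rate,
            offset_s=t0 + b / rate,
            peak_s=t0 + pk / rate,
            amp_env_peak=float(amplitude_env.samples[pk]),
            edge_amp=ea,
        )
        for a, b, pk, ea in merged
    ]


# ---------------------------------------------------------------------------
# current method, step 2: features


def _amplitude_spectrum(seg: np.ndarray, rate: float, pad_s: float = 4.0):
    seg = seg - seg.mean()
    n = max(int(round(pad_s * rate)), seg.size)
    spec = np.abs(np.fft.rfft(seg, n=n))
    return spec, np.fft.rfftfreq(n, d=1.0 / rate)


class FeatureExtractor:
    """Per-channel feature computation with envelopes precomputed once.

    The 15 per-candidate metrics: amplitude-envelope peak (amp), duration,
    FFT amplitudes in the spindle (10-16 Hz) and non-spindle (5-8 Hz) bands
    and their ratio, the spindle peak frequency, band-envelope maxima for the
    spindle (sband), 4-8 Hz (lband) and 18-25 Hz (hband) bands, the sleep
    stage (N3=1), the number of spindle-band peaks, their rate, the mean and
    SD of inter-peak intervals, and a flag (pr) for the peak rate lying in
    the 10-16 /s spindle range.
    """

    def __init__(self, raw: Signal, rec: Recording | None = None, channel: str = ""):
        self.raw = raw
        self.rec = rec
        self.channel = channel
        self.bp = bandpass_filter(raw, *SPINDLE_BAND)
        self.bp_env = analytic_envelope(self.bp)
        tukey400 = KernelSpec("tukey_avg", window_s=0.4)
        self.sband = smooth(self.bp.with_samples(np.abs(self.bp.samples)), tukey400)
        lbp = bandpass_filter(raw, *LOW_BAND)
        self.lband = smooth(lbp.with_samples(np.abs(lbp.samples)), tukey400)
        hbp = bandpass_filter(raw, *HIGH_BAND)
        self.hband = smooth(hbp.with_samples(np.abs(hbp.samples)), tukey400)
        _, self.amplitude_env = compute_envelopes(raw)

    def _stage_flag(self, t: float) -> float:
        if self.rec is None:
            return 0.0
        return 1.0 if self.rec.stage_at(t) == "N3" else 0.0

    def features(self, c: CandidateEpoch) -> dict[str, float]:
        raw = self.raw
        i0, i1 = raw.index_of(c.onset_s), raw.index_of(c.offset_s)
        if i1 - i0 < 2 * raw.rate_hz / SPINDLE_BAND[0]:
            raise ValueError("epoch shorter than two cycles at 10 Hz")
        dur = c.offset_s - c.onset_s
        spec, freqs = _amplitude_spectrum(raw.samples[i0:i1], raw.rate_hz)
        sp_sel = (freqs >= SPINDLE_BAND[0]) & (freqs <= SPINDLE_BAND[1])
        ns_sel = (freqs >= NONSPINDLE_FFT_BAND[0]) & (freqs <= NONSPINDLE_FFT_BAND[1])
        spindle_power = float(spec[sp_sel].max())
        nonspindle_power = float(spec[ns_sel].max())
        spindle_freq = float(freqs[sp_sel][np.argmax(spec[sp_sel])])
        seg_bp = self.bp.samples[i0:i1]
        prominence = 0.1 * float(self.bp_env.samples[i0:i1].max())
        pk, _ = sps.find_peaks(seg_bp, prominence=prominence)
        npeaks = int(pk.size)
        intervals = np.diff(pk) / raw.rate_hz
        peakrate = npeaks / dur
        return dict(
            amp=float(self.amplitude_env.samples[i0:i1].max()),
            dur=dur,
            spindle_power=spindle_power,
            nonspindle_power=nonspindle_power,
            f_ratio=spindle_power / max(nonspindle_power, 1e-300),
            spindle_freq=spindle_freq,
            sband_amp=float(self.sband.samples[i0:i1].max()),
            lband_amp=float(self.lband.samples[i0:i1].max()),
            hband_amp=float(self.hband.samples[i0:i1].max()),
            stage=self._stage_flag(c.onset_s),
            npeaks=float(npeaks),
            peakrate=peakrate,
            peak_intv_mean=float(intervals.mean()) if intervals.size else 0.0,
            peak_intv_std=float(intervals.std()) if intervals.size > 1 else 0.0,
            pr=1.0 if SPINDLE_BAND[0] <= peakrate <= SPINDLE_BAND[1] else 0.0,
        )

    def feature_frame(self, candidates: Sequence[CandidateEpoch]) -> pd.DataFrame:
        return pd.DataFrame([self.features(c) for c in candidates], columns=FEATURE_NAMES)


def extract_features(
    c: CandidateEpoch,
    raw: Signal,
    stage_label: str | None = None,
    rec: Recording | None = None,
) -> dict[str, float]:
    """Feature vector for one candidate epoch (convenience wrapper)."""
    ex = FeatureExtractor(raw, rec=rec, channel=c.channel)
    out = ex.features(c)
    if stage_label is not None:
        out["stage"] = 1.0 if stage_label == "N3" else 0.0
    return out


# ---------------------------------------------------------------------------
# model selection


def prune_collinear_vif(X: pd.DataFrame, max_vif: float = 10.0) -> list[str]:
    """Iteratively drop the feature with the largest VIF while it exceeds 10.

    The VIF of feature j is 1/(1-R^2) from an OLS regression of j on the
    remaining features (with intercept).  Ties — including joint infinite
    VIFs from perfect collinearity — are broken by removing the feature with
    the larger column index first.  Zero-variance columns are dropped up
    front (their VIF is undefined and they carry no information).
    """
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than features + 1 for VIF screening")
    cols = [c for c in X.columns if np.nanstd(X[c].to_numpy(dtype=float)) > 0]
    while len(cols) > 1:
        arr = X[cols].to_numpy(dtype=float)
        vifs = np.empty(len(cols))
        for j in range(len(cols)):
            others = sm.add_constant(np.delete(arr, j, axis=1))
            r2 = sm.OLS(arr[:, j], others).fit().rsquared
            vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(j for j in range(len(cols)) if vifs[j] == np.nanmax(vifs))
        if vifs[worst] <= max_vif:
            break
        cols.pop(worst)
    return cols


@dataclass
class FittedLogit:
    """A fitted logistic model: intercept-first parameters over named features."""

    feature_names: list[str]
    params: np.ndarray          # [intercept, coef_1, ...]
    llf: float
    regularized: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.params.size - 2.0 * self.llf

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        z = self.params[0] + (
            X[self.feature_names].to_numpy(dtype=float) @ self.params[1:]
            if self.feature_names else 0.0
        )
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _irls_logit(design: np.ndarray, y: np.ndarray, alpha: float = 0.0,
                maxiter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Newton/IRLS maximum-likelihood logistic fit (optionally ridge-penalized).

    Standardizing columns is unnecessary at these problem sizes; the ridge
    penalty (on all terms but the intercept) only enters as the separation
    fallback.  Returns (parameters, converged).
    """
    n, k = design.shape
    beta = np.zeros(k)
    pen = np.full(k, alpha)
    pen[0] = 0.0  # never penalize the intercept
    for _ in range(maxiter):
        z = np.clip(design @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-z))
        w = p * (1.0 - p)
        grad = design.T @ (y - p) - pen * beta
        hess = (design * w[:, None]).T @ design + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, features: Sequence[str], ridge_alpha: float = 1.0
) -> FittedLogit:
    """Maximum-likelihood logistic fit with a ridge fallback on separation.

    Features are standardized internally (the returned coefficients are on
    the original scale), so the fallback penalty ``ridge_alpha`` refers to
    z-scored predictors and keeps fitted probabilities away from exact 0/1
    under complete separation.
    """
    features = list(features)
    arr = X[features].to_numpy(dtype=float) if features else np.empty((len(X), 0))
    mu = arr.mean(axis=0) if arr.size else np.zeros(0)
    sd = arr.std(axis=0) if arr.size else np.zeros(0)
    sd = np.where(sd > 0, sd, 1.0)
    design = np.column_stack([np.ones(len(X)), (arr - mu) / sd])
    y = np.asarray(y, dtype=float)
    params, converged = _irls_logit(design, y)
    ok = converged and np.all(np.abs(params) < 1e3)
    if not ok:
        # (quasi-)complete separation or non-convergence: small L2 penalty
        warnings.warn("logistic fit did not converge; refitting with a small ridge penalty")
        params, _ = _irls_logit(design, y, alpha=ridge_alpha, maxiter=200)
    p = 1.0 / (1.0 + np.exp(-np.clip(design @ params, -500, 500)))
    llf = _log_likelihood(y, p)
    beta = params[1:] / sd
    intercept = params[0] - float(np.sum(params[1:] * mu / sd))
    return FittedLogit(features, np.r_[intercept, beta], llf, regularized=not ok)


def stepwise_select_aic(
    X: pd.DataFrame, y: np.ndarray
) -> tuple[list[str], FittedLogit]:
    """Bidirectional stepwise AIC minimization, starting from the full model.

    At each step every single-feature removal and addition is scored by AIC
    and the best strictly improving move is taken; the procedure is
    deterministic given the data.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    all_feats = list(X.columns)
    current = list(all_feats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best = fit_logistic(X, y, current)
        while True:
            moves: list[tuple[float, list[str]]] = []
            for f in current:
                cand = [c for c in current if c != f]
                moves.append((fit_logistic(X, y, cand).aic, cand))
            for f in all_feats:
                if f not in current:
                    moves.append((fit_logistic(X, y, current + [f]).aic, current + [f]))
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], len(m[1])))
            if moves[0][0] < best.aic - 1e-9:
                current = moves[0][1]
                best = fit_logistic(X, y, current)
            else:
                break
    if best.regularized:
        warnings.warn("selected model fitted with a small ridge penalty (separation)")
    return current, best


def bootstrap_stability(
    X: pd.DataFrame,
    y: np.ndarray,
    n_boot: int = 50,
    seed: int | None = 0,
) -> dict[str, float]:
    """Per-feature selection frequency over stepwise fits on bootstrap resamples."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in X.columns}
    n = len(y)
    for _ in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample in 100 tries")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, _ = stepwise_select_aic(X.iloc[idx].reset_index(drop=True), y[idx])
        for f in selected:
            counts[f] += 1
    return {c: counts[c] / n_boot for c in X.columns}


def _rates(tp: int, fp: int, fn: int, tn: int, convention: str) -> tuple[float, float]:
    if convention == "paper":
        fpr = fp / (fp + fn) if (fp + fn) > 0 else 0.0
    elif convention == "standard":
        fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    else:
        raise ValueError("fpr_convention must be 'paper' or 'standard'")
    fnr = fn / (tp + fn) if (tp + fn) > 0 else 0.0
    return fpr, fnr


def choose_probability_threshold(
    X: pd.DataFrame,
    y: np.ndarray,
    features: Sequence[str],
    grid_step: float = 0.005,
    fpr_convention: str = "paper",
    loo_probs: np.ndarray | None = None,
) -> float:
    """Probability cutoff equalizing leave-one-out FPR and FNR.

    Leave-one-out predicted probabilities are scanned over a 0-100% grid
    (0.5% steps); the returned threshold minimizes |FPR - FNR|, with ties
    broken toward the lower threshold.  The FPR definition defaults to the
    printed convention FP/(FP+FN) (``fpr_convention="paper"``); the textbook
    FP/(FP+TN) is available as ``"standard"``.
    """
    y = np.asarray(y, dtype=float)
    if loo_probs is None:
        loo_probs = np.empty(len(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(y)):
                keep = np.ones(len(y), dtype=bool)
                keep[i] = False
                if len(np.unique(y[keep])) < 2:
                    loo_probs[i] = y[keep].mean()
                    continue
                m = fit_logistic(X.iloc[keep].reset_index(drop=True), y[keep], features)
                loo_probs[i] = m.predict(X.iloc[[i]])[0]
    if np.allclose(loo_probs, loo_probs[0]):
        warnings.warn("degenerate leave-one-out probabilities; returning 0.5")
        return 0.5
    best_t, best_diff = 0.0, np.inf
    for t in np.arange(0.0, 1.0 + grid_step / 2, grid_step):
        pred = loo_probs >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        fpr, fnr = _rates(tp, fp, fn, tn, fpr_convention)
        diff = abs(fpr - fnr)
        if diff < best_diff - 1e-12:
            best_diff, best_t = diff, float(t)
    return best_t


# ---------------------------------------------------------------------------
# classifier container and the fit/apply pipeline


@dataclass
class SpindleClassifier:
    """Serializable per-channel spindle classifier."""

    channel: str
    candidate_threshold: float
    selected_features: list[str]
    coefficients: dict[str, float]        # includes "intercept"
    prob_threshold: float
    bootstrap_selection_freq: dict[str, float]
    fpr_convention: str = "paper"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must lie in (0, 1)")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        params = np.array(
            [self.coefficients["intercept"]]
            + [self.coefficients[f] for f in self.selected_features]
        )
        return FittedLogit(self.selected_features, params, np.nan).predict(X)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SpindleClassifier":
        with open(path) as fh:
            return cls(**json.load(fh))


class SpindleClassifierModel:
    """Logistic spindle/non-spindle model for one channel's candidate epochs.

    Statsmodels-style: build the model from a feature matrix and labels,
    call :meth:`fit`, and read estimates off the returned results object.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[int],
        channel: str = "",
        candidate_threshold: float = np.nan,
        fpr_convention: str = "paper",
    ):
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y must have the same length")
        self.channel = channel
        self.candidate_threshold = candidate_threshold
        self.fpr_convention = fpr_convention

    def fit(self, n_boot: int = 50, seed: int | None = 0) -> "SpindleClassifierResults":
        surviving = prune_collinear_vif(self.X)
        Xs = self.X[surviving]
        selected, model = stepwise_select_aic(Xs, self.y)
        boot_freq = bootstrap_stability(Xs, self.y, n_boot=n_boot, seed=seed)
        prob_thr = choose_probability_threshold(
            Xs, self.y, selected, fpr_convention=self.fpr_convention
        )
        prob_thr = min(max(prob_thr, 1e-6), 1 - 1e-6)
        coeffs = {"intercept": float(model.params[0])}
        coeffs.update({f: float(b) for f, b in zip(model.feature_names, model.params[1:])})
        clf = SpindleClassifier(
            channel=self.channel,
            candidate_threshold=float(self.candidate_threshold),
            selected_features=selected,
            coefficients=coeffs,
            prob_threshold=prob_thr,
            bootstrap_selection_freq=boot_freq,
            fpr_convention=self.fpr_convention,
            seed=seed,
        )
        return SpindleClassifierResults(self, clf, model, surviving)


@dataclass
class SpindleClassifierResults:
    """Results of fitting a :class:`SpindleClassifierModel`."""

    model: SpindleClassifierModel
    classifier: SpindleClassifier
    fitted: FittedLogit
    vif_surviving: list[str]

    @property
    def selected_features(self) -> list[str]:
        return self.classifier.selected_features

    @property
    def params(self) -> dict[str, float]:
        return self.classifier.coefficients

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classifier.predict_proba(X)

    def summary(self) -> str:
        lines = [
            f"Spindle classifier for channel {self.classifier.channel!r}",
            f"  candidates: {len(self.model.y)} "
            f"({int(self.model.y.sum())} spindles, "
            f"{int((1 - self.model.y).sum())} non-spindles)",
            f"  candidate amplitude threshold: {self.classifier.candidate_threshold:.4g}",
            f"  VIF-surviving features: {', '.join(self.vif_surviving)}",
            f"  probability threshold (LOO, {self.classifier.fpr_convention} FPR): "
            f"{self.classifier.prob_threshold:.3f}",
            "  term              coef        boot.freq",
        ]
        freq = self.classifier.bootstrap_selection_freq
        lines.append(f"  intercept     {self.params['intercept']:>10.4f}            -")
        for f in self.selected_features:
            lines.append(f"  {f:<13} {self.params[f]:>10.4f}        {freq.get(f, np.nan):>6.2f}")
        return "\n".join(lines)


def apply_classifier(
    clf: SpindleClassifier,
    candidates: Sequence[CandidateEpoch],
    X: pd.DataFrame,
    rec: Recording,
    diff_threshold: float | None = None,
) -> list[SpindleEvent]:
    """Turn supra-threshold candidates into events, with post hoc cleanup.

    Candidates with predicted probability >= the classifier's threshold
    become events; events outside N2/N3 or touching an exclusion interval
    are removed, then artifact rejection runs on a -2/+4 s epoch around each
    onset.
    """
    from .downstates import reject_artifact_events  # local import, no cycle at module load

    probs = clf.predict_proba(X)
    events: list[SpindleEvent] = []
    for c, p, (_, feats) in zip(candidates, probs, X.iterrows()):
        c.probability = float(p)
        if p < clf.prob_threshold:
            continue
        events.append(SpindleEvent(
            channel=c.channel, onset_s=c.onset_s, offset_s=c.offset_s,
            peak_amp=c.amp_env_peak, spindle_freq=float(feats["spindle_freq"]),
            probability=float(p), method="current",
        ))
    kept = []
    for e in events:
        if not rec.in_analysis(e.onset_s):
            continue
        if any(e.onset_s < b and e.offset_s > a for a, b in rec.exclusions):
            continue
        kept.append(e)
    raw = rec.signals[clf.channel]
    return reject_artifact_events(
        kept, raw, diff_threshold=diff_threshold, sd_mult=7.0, epoch_s=(-2.0, 4.0)
    )


def train_spindle_classifier(
    rec: Recording,
    channel: str,
    marks: Sequence[tuple[float, float]],
    mark_periods: Sequence[tuple[float, float]],
    n_boot: int = 50,
    seed: int | None = 0,
    fpr_convention: str = "paper",
) -> tuple[SpindleClassifierResults, list[CandidateEpoch], pd.DataFrame]:
    """End-to-end training on manually marked periods of one channel.

    Candidates overlapping a manual mark become class 1; candidates inside
    the marked periods matching no mark become class 0; candidates outside
    the marked periods stay unlabelled and do not enter the fit.
    """
    raw = rec.signals[channel]
    ex = FeatureExtractor(raw, rec=rec, channel=channel)
    edge, amp_env = compute_envelopes(raw)
    threshold = candidate_threshold_from_marks(amp_env, marks)
    candidates = find_candidate_epochs(edge, amp_env, threshold, channel=channel)
    for c in candidates:
        overlaps_mark = any(c.onset_s <= b and c.offset_s >= a for a, b in marks)
        in_period = any(c.onset_s >= a and c.offset_s <= b for a, b in mark_periods)
        c.label = 1 if overlaps_mark else (0 if in_period else None)
    labelled = [c for c in candidates if c.label is not None]
    if not labelled or len({c.label for c in labelled}) < 2:
        raise ValueError("training requires labelled candidates of both classes")
    X = ex.feature_frame(labelled)
    y = np.array([c.label for c in labelled])
    model = SpindleClassifierModel(
        X, y, channel=channel, candidate_threshold=threshold,
        fpr_convention=fpr_convention,
    )
    results = model.fit(n_boot=n_boot, seed=seed)
    return results, candidates, X


def detect_spindles(
    rec: Recording,
    clf: SpindleClassifier,
    diff_threshold: float | None = None,
) -> tuple[list[SpindleEvent], list[CandidateEpoch]]:
    """Detect spindles on a whole channel with a trained classifier."""
    raw = rec.signals[clf.channel]
    ex = FeatureExtractor(raw, rec=rec, channel=clf.channel)
    edge, amp_env = compute_envelopes(raw)
    candidates = find_candidate_epochs(edge, amp_env, clf.candidate_threshold, channel=clf.channel)
    if not candidates:
        return [], []
    X = ex.feature_frame(candidates)
    events = apply_classifier(clf, candidates, X, rec, diff_threshold=diff_threshold)
    return events, candidates
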