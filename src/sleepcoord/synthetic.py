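"""Synthetic SEEG generator with a scheduled cortico-thalamo-cortical sequence.

The generator emulates the event sequence observed in simultaneous bipolar
cortical/thalamic sleep recordings:

1. clusters of cortical downstates (DSs) occur as a renewal process, with a
   variable number ``k`` of cortical channels participating in each cluster;
2. a thalamic DS follows a cluster with a probability that increases with
   ``k``, lagging the cortical DS peak by ~218 +/- 66 ms;
3. a thalamic spindle starts at the thalamic DS peak;
4. the spindle is projected back to the participating cortical channels with
   a short (~15 ms) thalamocortical lag, so cortical spindle onsets land
   ~250 ms after the cortical DS peak, on the down-to-upstate transition.

Signals are rendered as 1/f^a background noise plus a negative half-sine DS
template (with an upstate rebound), Tukey-windowed spindle oscillations, and
band-limited high-gamma whose amplitude is suppressed during cortical DS
troughs, boosted on thalamic down-to-upstate transitions, and phase-locked
(as short bursts) to individual spindle troughs.

Every scheduled event is returned as ground truth, including the coupling
graph (which thalamic DS descends from which cortical cluster, which spindle
from which DS), so downstream detectors and coordination statistics can be
validated without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import binom

from .recording import CORTEX, THALAMUS, Recording
from .signal_core import Signal

__all__ = ["SimConfig", "GroundTruth", "build_event_schedule", "synthesize_signals", "simulate"]

_EDGE_MARGIN_S = 4.0  # keep scheduled events away from recording edges
_DS_HALF_S = 0.25     # DS half-sine half-width: template is 500 ms wide
_DS_REBOUND_FRAC = 0.6   # upstate rebound amplitude fraction (area-balanced with 1.5x width)
_CLUSTER_JITTER_S = 0.02
_DS_REFRACTORY_S = 1.25  # per-channel minimum DS spacing (slow-oscillation cycle)
_SCHEDULE_LOSS = 0.74    # fraction of nominal events surviving refractory/edge thinning


def _region_value(v, region: str) -> float:
    return float(v[region]) if isinstance(v, dict) else float(v)


@dataclass
class SimConfig:
    """Configuration of the synthetic cortico-thalamic recording.

    Rates and delays default to the values characterising the emulated
    recordings: DS densities 16.3 (cortex) and 11.5 (thalamus) per minute,
    spindle densities 5 and 7.1 per minute, a cortical-to-thalamic DS peak
    lag of 218 +/- 66 ms, thalamic spindle onset at the thalamic DS peak and
    a 15 ms thalamo-cortical spindle lag.  Event and background amplitudes
    are free parameters of the generator (the source recordings report none);
    the defaults are chosen so that background slow-wave statistics resemble
    N2/N3 sleep, with the thalamic background lower-amplitude and steeper
    (less slow activity) than the cortical one.
    """

    rate_hz: float = 256.0
    duration_s: float = 600.0
    channels: tuple[tuple[str, str], ...] = (
        ("C1", CORTEX), ("C2", CORTEX), ("C3", CORTEX), ("C4", CORTEX),
        ("T1", THALAMUS), ("T2", THALAMUS),
    )
    ds_rate_per_min: dict = field(default_factory=lambda: {CORTEX: 16.3, THALAMUS: 11.5})
    spindle_rate_per_min: dict = field(default_factory=lambda: {CORTEX: 5.0, THALAMUS: 7.1})
    cluster_rate_per_min: float = 30.0
    ct_ds_delay_s: tuple[float, float] = (0.218, 0.066)
    p_thal_ds_given_k: dict = field(
        default_factory=lambda: {1: 0.20, 2: 0.38, 3: 0.53, 4: 0.64}
    )
    thal_spindle_onset_rel_ds_s: float = 0.0
    tc_spindle_lag_s: float = 0.015
    cortical_spindle_rel_ds_s: float = 0.25
    spindle_dur_s: tuple[float, float] = (0.4, 1.6)
    spindle_freq_hz: tuple[float, float] = (10.0, 16.0)
    ds_amp: dict = field(default_factory=lambda: {CORTEX: 200.0, THALAMUS: 90.0})
    ds_amp_cv: float = 0.2
    spindle_amp: dict = field(default_factory=lambda: {CORTEX: 40.0, THALAMUS: 30.0})
    spindle_amp_sigma: float = 0.4
    gamma_amp: dict = field(default_factory=lambda: {CORTEX: 5.0, THALAMUS: 2.0})
    gamma_mod_depth: float = 0.8
    gamma_spindle_mod: float = 3.0
    noise_rms: dict = field(default_factory=lambda: {CORTEX: 15.0, THALAMUS: 7.0})
    noise_exponent: dict = field(default_factory=lambda: {CORTEX: 0.8, THALAMUS: 2.8})
    delta_bump_gain: dict = field(default_factory=lambda: {CORTEX: 4.0, THALAMUS: 2.0})
    distractor_rate_per_min: float = 6.0
    distractor_dur_s: tuple[float, float] = (0.15, 0.28)
    distractor_amp_scale: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate_hz and duration_s must be positive")
        for region in (CORTEX, THALAMUS):
            if _region_value(self.ds_rate_per_min, region) < 0:
                raise ValueError("ds_rate_per_min must be >= 0")
            if _region_value(self.spindle_rate_per_min, region) < 0:
                raise ValueError("spindle_rate_per_min must be >= 0")
        if self.cluster_rate_per_min < 0:
            raise ValueError("cluster_rate_per_min must be >= 0")
        if not all(0.0 <= p <= 1.0 for p in self.p_thal_ds_given_k.values()):
            raise ValueError("p_thal_ds_given_k values must lie in [0, 1]")
        ks = sorted(self.p_thal_ds_given_k)
        ps = [self.p_thal_ds_given_k[k] for k in ks]
        if any(b < a for a, b in zip(ps, ps[1:])):
            raise ValueError("p_thal_ds_given_k must be monotone increasing in k")
        lo, hi = self.spindle_dur_s
        if not (0.3 <= lo <= hi <= 2.0):
            raise ValueError("spindle_dur_s range must lie within [0.3, 2] s")
        if not math.isfinite(self.ct_ds_delay_s[0]) or self.ct_ds_delay_s[1] < 0:
            raise ValueError("ct_ds_delay_s must be (finite mean, sd >= 0)")

    @property
    def cortical_channels(self) -> list[str]:
        return [c for c, r in self.channels if r == CORTEX]

    @property
    def thalamic_channels(self) -> list[str]:
        return [c for c, r in self.channels if r == THALAMUS]

    def region_of(self, channel: str) -> str:
        return dict(self.channels)[channel]

    # -- derived coupling probabilities -------------------------------------
    def _p_thal(self, k: int) -> float:
        if not self.p_thal_ds_given_k or k < 1:
            return 0.0
        kmax = max(self.p_thal_ds_given_k)
        return self.p_thal_ds_given_k[min(k, kmax)]

    def participation_prob(self) -> float:
        """Per-cluster probability that a cortical channel joins a DS."""
        if self.cluster_rate_per_min <= 0:
            return 0.0
        q = _region_value(self.ds_rate_per_min, CORTEX) / (
            self.cluster_rate_per_min * _SCHEDULE_LOSS
        )
        if q > 1.0:
            raise ValueError(
                "cluster_rate_per_min too low for the cortical ds_rate_per_min "
                "after refractory thinning"
            )
        return q

    def expected_thal_ds_rate(self) -> float:
        """Analytic thalamic DS rate (per min) implied by the coupling."""
        q, n = self.participation_prob(), len(self.cortical_channels)
        if n == 0:
            return 0.0
        pk = binom.pmf(np.arange(n + 1), n, q)
        return self.cluster_rate_per_min * _SCHEDULE_LOSS * sum(
            pk[k] * self._p_thal(k) for k in range(1, n + 1)
        )

    def p_spindle_given_thal_ds(self) -> float:
        r = self.expected_thal_ds_rate()
        if r <= 0:
            return 0.0
        return min(1.0, _region_value(self.spindle_rate_per_min, THALAMUS) / r)

    def p_project_to_cortex(self) -> float:
        """Per-(thalamic spindle, participating cortical channel) projection prob."""
        q, n = self.participation_prob(), len(self.cortical_channels)
        n_thal = len(self.thalamic_channels)
        if q <= 0 or n == 0 or n_thal == 0:
            return 0.0
        # E[p_thal(1+k')] with k' ~ Binom(n-1, q): cluster size given that a
        # fixed cortical channel participates.
        pk = binom.pmf(np.arange(n), n - 1, q)
        e_p = sum(pk[k] * self._p_thal(1 + k) for k in range(n))
        per_min = (
            self.cluster_rate_per_min * _SCHEDULE_LOSS * q * e_p * n_thal
            * self.p_spindle_given_thal_ds()
        )
        if per_min <= 0:
            return 0.0
        return min(1.0, _region_value(self.spindle_rate_per_min, CORTEX) / per_min)


_EVENT_COLUMNS = [
    "id", "channel", "region", "type", "onset_s", "offset_s", "peak_s",
    "amplitude", "freq_hz", "parent_id", "cluster_id",
]


@dataclass
class GroundTruth:
    """The scheduled events and realized coupling graph of one simulation."""

    events: pd.DataFrame
    config: SimConfig

    def _sel(self, channel: str, etype: str) -> pd.DataFrame:
        e = self.events
        return e[(e["channel"] == channel) & (e["type"] == etype)]

    def ds_peaks(self, channel: str) -> np.ndarray:
        return np.sort(self._sel(channel, "ds")["peak_s"].to_numpy())

    def spindles(self, channel: str) -> pd.DataFrame:
        return self._sel(channel, "spindle").sort_values("onset_s")

    def spindle_onsets(self, channel: str) -> np.ndarray:
        return self.spindles(channel)["onset_s"].to_numpy()

    def spindle_intervals(self, channel: str) -> list[tuple[float, float]]:
        sp = self.spindles(channel)
        return list(zip(sp["onset_s"], sp["offset_s"]))

    def spindle_troughs(self, channel: str) -> np.ndarray:
        """Analytic trough times of every scheduled spindle on a channel."""
        out = []
        for _, row in self.spindles(channel).iterrows():
            out.append(_spindle_trough_times(row["onset_s"], row["offset_s"], row["freq_hz"]))
        return np.sort(np.concatenate(out)) if out else np.array([])

    def projected_troughs(self, thal_channel: str, cort_channel: str) -> np.ndarray:
        """Troughs of thalamic spindles that project to a cortical channel.

        This is the connected-pair selection used for trough-locked gamma
        delay analysis: only spindles whose projection actually reached the
        cortical channel carry a cortical gamma burst.
        """
        thal = self.spindles(thal_channel)
        cort = self._sel(cort_channel, "spindle")
        projected_parents = set(cort["parent_id"])
        out = []
        for _, row in thal.iterrows():
            if row["id"] in projected_parents:
                out.append(
                    _spindle_trough_times(row["onset_s"], row["offset_s"], row["freq_hz"])
                )
        return np.sort(np.concatenate(out)) if out else np.array([])


def _spindle_trough_times(onset: float, offset: float, freq: float) -> np.ndarray:
    """Times where sin(2*pi*f*(t-onset)) == -1, inside the taper plateau."""
    dur = offset - onset
    ks = np.arange(0, int(freq * dur) + 1)
    tau = (0.75 + ks) / freq
    tau = tau[(tau >= 0.15 * dur) & (tau <= 0.85 * dur)]
    return onset + tau


def build_event_schedule(cfg: SimConfig) -> GroundTruth:
    """Draw the full event schedule (no signals) from a :class:`SimConfig`."""
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    next_id = [0]

    def add(channel, etype, onset, offset, peak, amp, freq=np.nan,
            parent=-1, cluster=-1) -> int:
        i = next_id[0]
        next_id[0] += 1
        rows.append(dict(
            id=i, channel=channel, region=cfg.region_of(channel), type=etype,
            onset_s=onset, offset_s=offset, peak_s=peak, amplitude=amp,
            freq_hz=freq, parent_id=parent, cluster_id=cluster,
        ))
        return i

    q = cfg.participation_prob()
    p_spindle = cfg.p_spindle_given_thal_ds()
    p_proj = cfg.p_project_to_cortex()
    lam = cfg.cluster_rate_per_min / 60.0

    # cluster times: gamma(shape=2) renewal process, mean interval 1/lam
    t = _EDGE_MARGIN_S
    cluster_id = 0
    last_peak: dict[str, float] = {}
    lo_t, hi_t = _EDGE_MARGIN_S, cfg.duration_s - _EDGE_MARGIN_S
    while lam > 0 and q > 0:
        t += rng.gamma(2.0, 1.0 / (2.0 * lam))
        if t >= hi_t:
            break
        # cortical participation; channels still inside the slow-oscillation
        # refractory period of their previous DS sit the cluster out
        members = [
            c for c in cfg.cortical_channels
            if rng.random() < q and t - last_peak.get(c, -np.inf) >= _DS_REFRACTORY_S
        ]
        if not members:
            continue
        peaks = {}
        for c in members:
            peak = t + rng.normal(0.0, _CLUSTER_JITTER_S)
            last_peak[c] = peak
            amp = _region_value(cfg.ds_amp, CORTEX)
            amp *= float(np.clip(rng.normal(1.0, cfg.ds_amp_cv), 0.6, 1.4))
            peaks[c] = add(c, "ds", peak - _DS_HALF_S, peak + 3 * _DS_HALF_S,
                           peak, amp, cluster=cluster_id)
        k = len(members)
        ref = float(np.mean([rows[i]["peak_s"] for i in peaks.values()]))

        # thalamic DS + spindle cascade
        for tc in cfg.thalamic_channels:
            if rng.random() >= cfg._p_thal(k):
                continue
            tpeak = ref + rng.normal(*cfg.ct_ds_delay_s)
            if not lo_t <= tpeak <= hi_t:
                continue
            if tpeak - last_peak.get(tc, -np.inf) < _DS_REFRACTORY_S:
                continue
            last_peak[tc] = tpeak
            tamp = _region_value(cfg.ds_amp, THALAMUS)
            tamp *= float(np.clip(rng.normal(1.0, cfg.ds_amp_cv), 0.6, 1.4))
            tds = add(tc, "ds", tpeak - _DS_HALF_S, tpeak + 3 * _DS_HALF_S,
                      tpeak, tamp, parent=peaks[members[0]], cluster=cluster_id)
            if rng.random() >= p_spindle:
                continue
            onset = tpeak + cfg.thal_spindle_onset_rel_ds_s
            dur = rng.uniform(*cfg.spindle_dur_s)
            freq = rng.uniform(*cfg.spindle_freq_hz)
            samp = _region_value(cfg.spindle_amp, THALAMUS)
            samp *= float(np.clip(rng.lognormal(0.0, cfg.spindle_amp_sigma), 0.45, 2.2))
            if not lo_t <= onset + dur <= cfg.duration_s - 1.0:
                continue
            tsp = add(tc, "spindle", onset, onset + dur, onset + dur / 2,
                      samp, freq, parent=tds, cluster=cluster_id)
            # projection back to the cortical members of the cluster
            for c in members:
                if rng.random() >= p_proj:
                    continue
                c_on = onset + cfg.tc_spindle_lag_s
                camp = _region_value(cfg.spindle_amp, CORTEX)
                camp *= float(np.clip(rng.lognormal(0.0, cfg.spindle_amp_sigma), 0.45, 2.2))
                add(c, "spindle", c_on, c_on + dur, c_on + dur / 2,
                    camp, freq, parent=tsp, cluster=cluster_id)
        cluster_id += 1

    # no thalamus: hang cortical spindles directly off cortical DSs so that
    # purely cortical configurations still express the DS->spindle coupling
    if not cfg.thalamic_channels and rows:
        target = _region_value(cfg.spindle_rate_per_min, CORTEX)
        rate_ds = _region_value(cfg.ds_rate_per_min, CORTEX)
        p_direct = min(1.0, target / rate_ds) if rate_ds > 0 else 0.0
        for r in [r for r in rows if r["type"] == "ds"]:
            if rng.random() >= p_direct:
                continue
            onset = r["peak_s"] + cfg.cortical_spindle_rel_ds_s
            dur = rng.uniform(*cfg.spindle_dur_s)
            if onset + dur > cfg.duration_s - 1.0:
                continue
            amp = _region_value(cfg.spindle_amp, CORTEX)
            amp *= float(np.clip(rng.lognormal(0.0, cfg.spindle_amp_sigma), 0.45, 2.2))
            add(r["channel"], "spindle", onset, onset + dur, onset + dur / 2,
                amp, rng.uniform(*cfg.spindle_freq_hz), parent=r["id"],
                cluster=r["cluster_id"])

    # spindle-band distractors: brief oscillatory transients that are not
    # spindles (too short / too few cycles); they provide the non-spindle
    # candidate epochs a classifier must learn to reject
    if cfg.distractor_rate_per_min > 0:
        lam_d = cfg.distractor_rate_per_min / 60.0
        for ch, region in cfg.channels:
            t = lo_t
            while True:
                t += rng.exponential(1.0 / lam_d)
                if t >= hi_t:
                    break
                dur = rng.uniform(*cfg.distractor_dur_s)
                amp = cfg.distractor_amp_scale * _region_value(cfg.spindle_amp, region)
                amp *= float(np.clip(rng.lognormal(0.0, cfg.spindle_amp_sigma), 0.45, 2.2))
                add(ch, "distractor", t, t + dur, t + dur / 2, amp,
                    rng.uniform(*cfg.spindle_freq_hz))

    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    # drop cortical spindles that overlap an earlier one on the same channel
    # (two thalamic channels may project the same cluster's spindle)
    drop: list[int] = []
    for ch, grp in events[events["type"] == "spindle"].groupby("channel"):
        grp = grp.sort_values("onset_s")
        last_off = -np.inf
        for _, row in grp.iterrows():
            if row["onset_s"] < last_off:
                drop.append(row["id"])
            else:
                last_off = row["offset_s"]
    events = events[~events["id"].isin(drop)].reset_index(drop=True)
    return GroundTruth(events=events, config=cfg)


# ---------------------------------------------------------------------------
# rendering


def _one_over_f_noise(
    n: int,
    exponent: float,
    rms: float,
    rng: np.random.Generator,
    rate_hz: float = 256.0,
    hp_hz: float = 0.16,
    delta_bump_gain: float = 0.0,
) -> np.ndarray:
    """1/f^a Gaussian noise shaped by an acquisition high-pass.

    Clinical SEEG amplifiers band-pass at acquisition (0.16-0.33 Hz high-pass),
    so the background carries no ultra-slow drift; without this the
    normalisation to ``rms`` would be dominated by sub-0.1 Hz power that the
    detectors never see.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    with np.errstate(divide="ignore"):
        shape = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
        shape *= np.where(f > 0, 1.0 / np.sqrt(1.0 + (hp_hz / np.maximum(f, 1e-12)) ** 8), 0.0)
        if delta_bump_gain > 0:
            # ongoing sub-threshold delta activity characteristic of N2/N3
            shape *= np.sqrt(1.0 + delta_bump_gain * np.exp(-((f - 1.1) ** 2) / (2 * 0.4 ** 2)))
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _bandlimited_noise(n: int, rate: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_window(buf: np.ndarray, rate: float, start_s: float, values: np.ndarray) -> None:
    i0 = int(round(start_s * rate))
    i1 = i0 + values.size
    a, b = max(i0, 0), min(i1, buf.size)
    if a < b:
        buf[a:b] += values[a - i0 : b - i0]


def _mult_window(buf: np.ndarray, rate: float, start_s: float, values: np.ndarray) -> None:
    i0 = int(round(start_s * rate))
    i1 = i0 + values.size
    a, b = max(i0, 0), min(i1, buf.size)
    if a < b:
        buf[a:b] *= values[a - i0 : b - i0]


def synthesize_signals(cfg: SimConfig, gt: GroundTruth) -> Recording:
    """Render the scheduled events into a multichannel :class:`Recording`."""
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    depth = cfg.gamma_mod_depth

    signals: dict[str, Signal] = {}
    for ch, region in cfg.channels:
        y = _one_over_f_noise(
            n, _region_value(cfg.noise_exponent, region),
            _region_value(cfg.noise_rms, region), rng, rate_hz=rate,
            delta_bump_gain=_region_value(cfg.delta_bump_gain, region),
        )
        gamma_env = np.full(n, 1.0 if region == CORTEX else 0.3)
        ev = gt.events[gt.events["channel"] == ch]

        for _, row in ev[ev["type"] == "ds"].iterrows():
            peak, amp = row["peak_s"], row["amplitude"]
            m = int(round(2 * _DS_HALF_S * rate))
            tau = np.arange(m) / rate
            half_sine = np.sin(np.pi * tau / (2 * _DS_HALF_S))
            _add_window(y, rate, peak - _DS_HALF_S, -amp * half_sine)
            # area-balanced upstate rebound (0.6 amplitude x 1.5 width), so
            # the high-passed event train stays zero-mean and the template
            # footprint (1 s) fits inside the slow-oscillation refractory
            m_up = int(round(1.5 * m))
            up = np.sin(np.pi * np.arange(m_up) / m_up)
            _add_window(y, rate, peak + _DS_HALF_S, _DS_REBOUND_FRAC * amp * up)
            if region == CORTEX:
                # high gamma suppressed around the DS trough, mildly elevated
                # on the following upstate
                m2 = int(round(0.5 * rate))
                _mult_window(gamma_env, rate, peak - 0.25,
                             np.full(m2, 1.0 - depth))
                _mult_window(gamma_env, rate, peak + 0.25,
                             np.full(int(round(1.0 * rate)), 1.0 + 0.5 * depth))
            else:
                # thalamic high gamma rises on the down-to-upstate transition
                m2 = int(round(0.4 * rate))
                _mult_window(gamma_env, rate, peak + 0.1,
                             np.full(m2, 1.0 + 8.0 * depth))

        for _, row in ev[ev["type"].isin(["spindle", "distractor"])].iterrows():
            onset, dur = row["onset_s"], row["offset_s"] - row["onset_s"]
            m = int(round(dur * rate))
            tau = np.arange(m) / rate
            # fast waxing (12.5% taper each side): the envelope reaches
            # detection level within roughly one cycle of the scheduled onset
            wave = row["amplitude"] * sps.windows.tukey(m, alpha=0.25) * np.sin(
                2 * np.pi * row["freq_hz"] * tau
            )
            _add_window(y, rate, onset, wave)
            if row["type"] != "spindle":
                continue  # distractors carry no gamma coupling
            # gamma bursts phase-locked to individual spindle troughs
            troughs = _spindle_trough_times(row["onset_s"], row["offset_s"], row["freq_hz"])
            if troughs.size and cfg.gamma_spindle_mod > 0:
                pad = 0.05
                mm = int(round((dur + 2 * pad) * rate))
                tt = row["onset_s"] - pad + np.arange(mm) / rate
                bumps = np.zeros(mm)
                for tr in troughs:
                    bumps += np.exp(-0.5 * ((tt - tr) / 0.008) ** 2)
                _mult_window(gamma_env, rate, row["onset_s"] - pad,
                             1.0 + cfg.gamma_spindle_mod * bumps)

        gamma = _bandlimited_noise(n, rate, 60.0, min(100.0, rate / 2 - 1), rng)
        y = y + _region_value(cfg.gamma_amp, region) * gamma_env * gamma
        signals[ch] = Signal(y, rate_hz=rate, t0_s=0.0)

    # alternate N2/N3 in 5-minute blocks
    stages = []
    t = 0.0
    block, idx = 300.0, 0
    while t < cfg.duration_s:
        stages.append((t, min(t + block, cfg.duration_s), "N2" if idx % 2 == 0 else "N3"))
        t += block
        idx += 1
    return Recording(
        signals=signals,
        regions=dict(cfg.channels),
        stages=stages,
        exclusions=[],
    )


def simulate(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Schedule events and render signals in one call."""
    gt = build_event_schedule(cfg)
    return synthesize_signals(cfg, gt), gt
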