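"""Container for a multichannel recording with sleep-stage annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import Signal

CORTEX = "cortex"
THALAMUS = "thalamus"

__all__ = ["Recording", "CORTEX", "THALAMUS"]


@dataclass
class Recording:
    """Continuous multichannel signal plus region labels and annotations.

    Parameters
    ----------
    signals : dict
        Channel name -> :class:`Signal`; all channels share one sampling rate.
    regions : dict
        Channel name -> ``"cortex"`` or ``"thalamus"``.
    stages : list of (start_s, end_s, stage)
        Sleep-stage intervals; stages are free strings, ``"N2"``/``"N3"``
        are the ones the pipeline analyses.
    exclusions : list of (start_s, end_s)
        Time intervals to exclude from analysis (for example suspected
        epileptiform activity).
    """

    signals: dict[str, Signal]
    regions: dict[str, str]
    stages: list[tuple[float, float, str]] = field(default_factory=list)
    exclusions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signals:
            raise ValueError("Recording needs at least one channel")
        rates = {s.rate_hz for s in self.signals.values()}
        if len(rates) != 1:
            raise ValueError(f"channels must share one sampling rate, got {rates}")
        for name in self.signals:
            if self.regions.get(name) not in (CORTEX, THALAMUS):
                raise ValueError(
                    f"channel {name!r} must be labelled 'cortex' or 'thalamus'"
                )

    @property
    def rate_hz(self) -> float:
        return next(iter(self.signals.values())).rate_hz

    @property
    def duration_s(self) -> float:
        return max(s.duration_s for s in self.signals.values())

    @property
    def channel_names(self) -> list[str]:
        return list(self.signals)

    def channels_in(self, region: str) -> list[str]:
        return [c for c in self.signals if self.regions[c] == region]

    def analysis_intervals(self, stages: tuple[str, ...] = ("N2", "N3")) -> list[tuple[float, float]]:
        """Stage intervals restricted to the requested stages."""
        if not self.stages:  # unannotated recordings analysed in full
            return [(0.0, self.duration_s)]
        return [(a, b) for a, b, s in self.stages if s in stages]

    def analysis_mask(self, channel: str, stages: tuple[str, ...] = ("N2", "N3")) -> np.ndarray:
        """Boolean per-sample mask: inside an analysed stage, outside exclusions."""
        sig = self.signals[channel]
        t = sig.times()
        mask = np.zeros(t.size, dtype=bool)
        for a, b in self.analysis_intervals(stages):
            mask |= (t >= a) & (t < b)
        for a, b in self.exclusions:
            mask &= ~((t >= a) & (t < b))
        return mask

    def stage_at(self, t_s: float) -> str | None:
        for a, b, s in self.stages:
            if a <= t_s < b:
                return s
        return None

    def in_analysis(self, t_s: float, stages: tuple[str, ...] = ("N2", "N3")) -> bool:
        if any(a <= t_s < b for a, b in self.exclusions):
            return False
        return any(a <= t_s < b for a, b in self.analysis_intervals(stages))

    def total_analysis_minutes(self, stages: tuple[str, ...] = ("N2", "N3")) -> float:
        total = sum(b - a for a, b in self.analysis_intervals(stages))
        excluded = sum(
            max(0.0, min(b, eb) - max(a, ea))
            for a, b in self.analysis_intervals(stages)
            for ea, eb in self.exclusions
        )
        return (total - excluded) / 60.0
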