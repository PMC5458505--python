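"""Scoring of detected events against manual or ground-truth marks.

Detections are matched one-to-one to truth intervals by greedy
largest-overlap matching, and the resulting confusion counts are summarised
with signal-detection-theory indices: hit rate, false-alarm rate,
discriminability d' and bias C, with the log-linear (add 0.5 to every cell)
correction when a rate hits 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = ["DetectionScore", "match_detections", "match_point_events", "sdt_scores"]


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int
    tn: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    corrected: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else np.nan

    @property
    def sensitivity(self) -> float:
        return self.hit_rate


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return min(a[1], b[1]) - max(a[0], b[0])


def match_detections(
    detected: Sequence[tuple[float, float]],
    truth: Sequence[tuple[float, float]],
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one interval matching by largest temporal overlap.

    Each truth interval is credited to at most one detection (and vice
    versa); matched truths are TPs, unmatched truths FNs, unmatched
    detections FPs.  Returns ``(tp, fp, fn, matching)`` with the matching as
    (detected index, truth index) pairs.
    """
    cand = [
        (_overlap(d, t), i, j)
        for i, d in enumerate(detected)
        for j, t in enumerate(truth)
        if _overlap(d, t) > 0
    ]
    cand.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    matching: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matching.append((i, j))
    tp = len(matching)
    return tp, len(detected) - tp, len(truth) - tp, matching


def match_point_events(
    detected_times: Sequence[float],
    truth_times: Sequence[float],
    tolerance_s: float = 0.1,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one matching of point events within a time tolerance."""
    cand = [
        (abs(d - t), i, j)
        for i, d in enumerate(detected_times)
        for j, t in enumerate(truth_times)
        if abs(d - t) <= tolerance_s
    ]
    cand.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matching = []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matching.append((i, j))
    tp = len(matching)
    return tp, len(detected_times) - tp, len(truth_times) - tp, matching


def sdt_scores(tp: int, fp: int, fn: int, tn: int) -> DetectionScore:
    """Signal-detection indices from a confusion table.

    hit = TP/(TP+FN), fa = FP/(FP+TN), d' = z(hit) - z(fa),
    C = -(z(hit) + z(fa))/2.  When any rate is exactly 0 or 1, 0.5 is added
    to every cell (log-linear correction) before computing the rates.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("undefined rates: need tp+fn > 0 and fp+tn > 0")
    hit = tp / (tp + fn)
    fa = fp / (fp + tn)
    corrected = hit in (0.0, 1.0) or fa in (0.0, 1.0)
    if corrected:
        hit = (tp + 0.5) / (tp + fn + 1.0)
        fa = (fp + 0.5) / (fp + tn + 1.0)
    zh, zf = norm.ppf(hit), norm.ppf(fa)
    return DetectionScore(
        tp=tp, fp=fp, fn=fn, tn=tn,
        hit_rate=hit, fa_rate=fa,
        d_prime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2.0),
        corrected=corrected,
    )
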