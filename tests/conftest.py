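"""Shared fixtures: one synthetic recording reused across the suite.

The 30-minute default-configuration simulation and the detections computed
from it are expensive, so they are session-scoped; tests treat them as
read-only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import sleepcoord as sc


@pytest.fixture(scope="session")
def sim30():
    """30-minute default-configuration simulation (recording, ground truth)."""
    cfg = sc.SimConfig(duration_s=1800.0, seed=2)
    rec, gt = sc.simulate(cfg)
    return rec, gt


@pytest.fixture(scope="session")
def ds_result(sim30):
    rec, _ = sim30
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.detect_downstates(rec)


@pytest.fixture(scope="session")
def trained_spindles(sim30):
    """Classifiers trained on the first 10 minutes of marks, plus detections.

    Returns {channel: dict(results, events, candidates, truth_intervals)} for
    one cortical and one thalamic channel per region plus the remaining
    channels needed by the acceptance checks.
    """
    rec, gt = sim30
    out = {}
    periods = [(0.0, 600.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ch in rec.channel_names:
            truth = gt.spindle_intervals(ch)
            marks = [m for m in truth if m[1] <= 600.0]
            results, cands, X = sc.train_spindle_classifier(
                rec, ch, marks, periods, n_boot=10, seed=0
            )
            events, cands_all = sc.detect_spindles(rec, results.classifier)
            out[ch] = dict(
                results=results,
                events=events,
                candidates=cands_all,
                truth_intervals=truth,
            )
    return out
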