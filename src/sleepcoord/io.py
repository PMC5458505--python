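"""Recording and event-table I/O.

Recordings are read from EDF(+) (through MNE) or from a plain CSV numeric
matrix with a ``time_s`` column.  A minimal EDF writer (16-bit, 1 s data
records) is included so simulations can round-trip through the standard
format.  Bipolar re-referencing (medial minus lateral contact) is applied
from a montage table on request.  Event tables, stage/exclusion interval
lists and ground-truth schedules are plain CSV with fixed column orders.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording
from .signal_core import Signal

__all__ = [
    "read_recording",
    "write_edf",
    "write_csv_matrix",
    "apply_bipolar_montage",
    "read_intervals_csv",
    "write_intervals_csv",
    "read_stages_csv",
    "write_stages_csv",
    "write_event_table",
    "read_event_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
]

DS_EVENT_COLUMNS = ["channel", "zc_start_s", "peak_s", "zc_end_s", "peak_amp", "mode"]
SPINDLE_EVENT_COLUMNS = [
    "channel", "onset_s", "offset_s", "peak_amp", "spindle_freq",
    "class", "probability", "method",
]
GROUND_TRUTH_COLUMNS = [
    "channel", "type", "onset_s", "offset_s", "peak_s",
    "amplitude", "freq_hz", "parent_id",
]


# ---------------------------------------------------------------------------
# recordings


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path) -> None:
    """Write the recording as 16-bit EDF with 1-second data records.

    Requires an integer sampling rate.  The last partial second is dropped.
    Physical units are microvolts; scaling is per channel, symmetric around
    zero.
    """
    rate = rec.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    names = rec.channel_names
    ns = len(names)
    n_records = min(s.samples.size for s in rec.signals.values()) // rate
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data, pmin, pmax = [], [], []
    for ch in names:
        x = rec.signals[ch].samples[: n_records * rate]
        amp = max(float(np.abs(x).max()), 1e-6)
        pmin.append(-amp)
        pmax.append(amp)
        data.append(np.clip(np.round(x / amp * 32767), -32768, 32767).astype("<i2"))

    header = b"".join([
        _fixed("0", 8),
        _fixed("X X X X", 80),
        _fixed("Startdate X X X X", 80),
        _fixed("01.01.00", 8),
        _fixed("00.00.00", 8),
        _fixed(str(256 * (ns + 1)), 8),
        _fixed("", 44),
        _fixed(str(n_records), 8),
        _fixed("1", 8),
        _fixed(str(ns), 4),
    ])
    fields = [
        [_fixed(ch, 16) for ch in names],
        [_fixed(rec.regions[ch], 80) for ch in names],
        [_fixed("uV", 8) for _ in names],
        [_fixed(f"{v:.6g}"[:8], 8) for v in pmin],
        [_fixed(f"{v:.6g}"[:8], 8) for v in pmax],
        [_fixed("-32768", 8) for _ in names],
        [_fixed("32767", 8) for _ in names],
        [_fixed("", 80) for _ in names],
        [_fixed(str(rate), 8) for _ in names],
        [_fixed("", 32) for _ in names],
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(b"".join(f))
        for r in range(n_records):
            for d in data:
                fh.write(d[r * rate : (r + 1) * rate].tobytes())


def write_csv_matrix(rec: Recording, path) -> None:
    """Write the signals as a CSV matrix with a leading ``time_s`` column."""
    n = min(s.samples.size for s in rec.signals.values())
    t = next(iter(rec.signals.values())).times()[:n]
    df = pd.DataFrame({"time_s": t})
    for ch in rec.channel_names:
        df[ch] = rec.signals[ch].samples[:n]
    df.to_csv(path, index=False)


def _read_edf_signals(path) -> tuple[dict[str, Signal], dict[str, str]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rate = float(raw.info["sfreq"])
    data = raw.get_data(units="uV")
    signals, transducers = {}, {}
    for i, ch in enumerate(raw.ch_names):
        signals[ch] = Signal(data[i], rate_hz=rate, t0_s=0.0)
    return signals, transducers


def _read_csv_signals(path) -> dict[str, Signal]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("CSV matrix must contain a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("CSV matrix needs at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    return {
        ch: Signal(df[ch].to_numpy(dtype=float), rate_hz=rate, t0_s=float(t[0]))
        for ch in df.columns
        if ch != "time_s"
    }


def apply_bipolar_montage(
    signals: dict[str, Signal], montage: pd.DataFrame
) -> dict[str, Signal]:
    """Derive bipolar channels: medial contact minus lateral contact.

    ``montage`` needs columns ``name``, ``medial``, ``lateral``.
    """
    out: dict[str, Signal] = {}
    for _, row in montage.iterrows():
        for col in ("medial", "lateral"):
            if row[col] not in signals:
                raise KeyError(f"montage references missing contact {row[col]!r}")
        m, l = signals[row["medial"]], signals[row["lateral"]]
        out[row["name"]] = m.with_samples(m.samples - l.samples)
    return out


def read_recording(
    path,
    fmt: str = "auto",
    regions: dict[str, str] | None = None,
    regions_csv=None,
    stages_csv=None,
    exclusions_csv=None,
    montage_csv=None,
) -> Recording:
    """Read an EDF or CSV-matrix recording into a :class:`Recording`.

    Region labels come either from ``regions`` (channel -> region) or from a
    two-column CSV (``channel,region``).  Optional stage, exclusion and
    bipolar-montage tables are applied when given.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv-matrix"
    if fmt == "edf":
        signals, _ = _read_edf_signals(path)
    elif fmt == "csv-matrix":
        signals = _read_csv_signals(path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if montage_csv is not None:
        signals = apply_bipolar_montage(signals, pd.read_csv(montage_csv))
    if regions is None:
        if regions_csv is None:
            raise ValueError("region labels are required (regions= or regions_csv=)")
        rdf = pd.read_csv(regions_csv)
        regions = dict(zip(rdf["channel"], rdf["region"]))
    regions = {ch: regions[ch] for ch in signals}
    stages = read_stages_csv(stages_csv) if stages_csv is not None else []
    exclusions = read_intervals_csv(exclusions_csv) if exclusions_csv is not None else []
    return Recording(signals=signals, regions=regions, stages=stages, exclusions=exclusions)


# ---------------------------------------------------------------------------
# interval / event tables


def read_intervals_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(a), float(b)) for a, b in zip(df["start_s"], df["end_s"])]


def write_intervals_csv(intervals, path) -> None:
    pd.DataFrame(intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_stages_csv(path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    return [
        (float(a), float(b), str(s))
        for a, b, s in zip(df["start_s"], df["end_s"], df["stage"])
    ]


def write_stages_csv(stages, path) -> None:
    pd.DataFrame(stages, columns=["start_s", "end_s", "stage"]).to_csv(path, index=False)


def write_event_table(events: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write an event table as CSV in a fixed, documented column order."""
    if columns is not None:
        events = events.reindex(columns=columns)
    events.to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(gt, path) -> None:
    write_event_table(gt.events, path, columns=GROUND_TRUTH_COLUMNS)


def read_ground_truth(path) -> pd.DataFrame:
    return read_event_table(path)


def write_manifest(path, **entries) -> None:
    """JSON run manifest (parameters, seeds, versions) for reproducibility."""
    import sleepcoord

    manifest = {"sleepcoord_version": sleepcoord.__version__}
    manifest.update(entries)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)
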