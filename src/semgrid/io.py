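"""Reading and writing signals, feature tables and pattern tables.

Two signal formats: delimited text (human-inspectable, exact
round-trip) and EDF (the standard electrophysiology exchange format,
16-bit quantized). The text dialect is a comma-separated table with a
header row: a ``time_s`` column, one column per channel (μV), and an
optional trailing ``label`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import edf as _edf
from .features import FeatureSeries
from .records import SignalRecord

_TIME_COL = "time_s"
_LABEL_COL = "label"


def _infer_format(path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    return "edf" if suffix == ".edf" else "delimited_text"


def write_signal(record: SignalRecord, path, format: str | None = None) -> None:
    """Write a record as delimited text or EDF (inferred from extension)."""
    fmt = _infer_format(path, format)
    if record.n_samples == 0:
        raise ValueError("refusing to write an empty record")
    if fmt == "edf":
        _edf.write_edf(record, path)
        return
    if fmt != "delimited_text":
        raise ValueError(f"unknown signal format {fmt!r}")
    cols: dict = {_TIME_COL: record.times}
    for i, name in enumerate(record.channel_names):
        cols[name] = record.samples[:, i]
    if record.labels is not None:
        cols[_LABEL_COL] = record.labels
    # default float repr is shortest-exact, so the round-trip is lossless
    pd.DataFrame(cols).to_csv(path, index=False)


def read_signal(path, format: str | None = None) -> SignalRecord:
    """Read a signal file; sampling rate is inferred from the time column
    (text, must be uniform to 1e−6 relative) or taken from the EDF header."""
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _edf.read_edf(path)
    if fmt != "delimited_text":
        raise ValueError(f"unknown signal format {fmt!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if _TIME_COL not in df.columns:
        raise ValueError(f"missing {_TIME_COL!r} header column in {path}")
    t = df[_TIME_COL].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("signal file must contain at least 2 samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    bad = np.nonzero(np.abs(dt - dt0) > 1e-6 * max(abs(dt0), 1e-12))[0]
    if bad.size:
        row = int(bad[0]) + 2  # +1 for header line, +1 for diff offset
        raise ValueError(
            f"non-uniform sampling: interval at data row {row} is {dt[bad[0]]:.9g} s, "
            f"expected {dt0:.9g} s"
        )
    fs = (len(t) - 1) / (t[-1] - t[0])
    channel_names = [c for c in df.columns if c not in (_TIME_COL, _LABEL_COL)]
    labels = df[_LABEL_COL].to_numpy() if _LABEL_COL in df.columns else None
    return SignalRecord(
        samples=df[channel_names].to_numpy(dtype=float),
        sampling_rate=fs,
        channel_names=channel_names,
        labels=labels,
        start_time=float(t[0]),
    )


def write_features(features: FeatureSeries, path) -> None:
    """Feature table: time_s, one RMS column per channel, optional label."""
    cols: dict = {_TIME_COL: features.window_end_times}
    for i, name in enumerate(features.channel_names):
        cols[name] = features.values[:, i]
    if features.labels is not None:
        cols[_LABEL_COL] = features.labels
    with open(path, "w") as fh:
        fh.write(f"# window_ms={features.window_ms:g} step_ms={features.step_ms:g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_features(path) -> FeatureSeries:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = float(v)
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    if _TIME_COL not in df.columns:
        raise ValueError(f"missing {_TIME_COL!r} header column in {path}")
    channel_names = [c for c in df.columns if c not in (_TIME_COL, _LABEL_COL)]
    return FeatureSeries(
        values=df[channel_names].to_numpy(dtype=float),
        window_ms=meta.get("window_ms", float("nan")),
        step_ms=meta.get("step_ms", float("nan")),
        window_end_times=df[_TIME_COL].to_numpy(dtype=float),
        channel_names=channel_names,
        labels=df[_LABEL_COL].to_numpy() if _LABEL_COL in df.columns else None,
    )


def write_patterns(index_rows: np.ndarray, times: np.ndarray, K: int, path,
                   channel_names: list[str] | None = None,
                   labels: np.ndarray | None = None) -> None:
    """Pattern table: one row per window — time, per-channel cluster index."""
    index_rows = np.atleast_2d(np.asarray(index_rows, dtype=int))
    n_ch = index_rows.shape[1]
    channel_names = channel_names or [f"ch{i+1:02d}" for i in range(n_ch)]
    cols: dict = {_TIME_COL: times}
    for i, name in enumerate(channel_names):
        cols[name] = index_rows[:, i]
    if labels is not None:
        cols[_LABEL_COL] = labels
    with open(path, "w") as fh:
        fh.write(f"# K={K}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_patterns(path) -> tuple[np.ndarray, np.ndarray, int, list[str], np.ndarray | None]:
    """Inverse of :func:`write_patterns`:
    returns (index_rows, times, K, channel_names, labels-or-None)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# K="):
            raise ValueError(f"pattern file {path} missing '# K=' header line")
        K = int(first.strip().split("=")[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    channel_names = [c for c in df.columns if c not in (_TIME_COL, _LABEL_COL)]
    labels = df[_LABEL_COL].to_numpy() if _LABEL_COL in df.columns else None
    return (
        df[channel_names].to_numpy(dtype=int),
        df[_TIME_COL].to_numpy(dtype=float),
        K,
        channel_names,
        labels,
    )
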