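"""Minimal EDF (European Data Format) reader and writer.

EDF stores multichannel physiological time series as a plain ASCII
header followed by 16-bit little-endian integer data records; physical
values are recovered by the linear digital→physical map declared per
signal in the header. This module implements the subset needed to
exchange uniformly sampled sEMG recordings: equal sampling rate across
signals, one continuous recording, no annotations. Quantization to 16
bits bounds the round-trip error by half a quantization step,
``(physical_max − physical_min) / (2^16 − 2) / 2`` per channel.

Motion labels are not representable in plain EDF and are dropped on
write; the delimited-text format preserves them.
"""

from __future__ import annotations

import numpy as np

from .records import SignalRecord

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _format_number(x: float, width: int) -> str:
    """Decimal representation of x fitting the field width."""
    for fmt in ("%g", "%.6g", "%.4g", "%.3g", "%.2g"):
        s = fmt % x
        if len(s) <= width:
            return s
    raise ValueError(f"cannot represent {x} in {width} chars")


def write_edf(record: SignalRecord, path) -> None:
    """Write a record as EDF; physical range ±(1.05 × max|sample|) per channel."""
    if record.n_samples == 0:
        raise ValueError("refusing to write an empty record")
    fs = record.sampling_rate
    n = record.n_samples

    fs_int = int(round(fs))
    if abs(fs - fs_int) < 1e-9 and n % fs_int == 0:
        samples_per_record, n_records, rec_dur = fs_int, n // fs_int, "1"
    else:
        # single data record holding the whole signal
        samples_per_record, n_records = n, 1
        rec_dur = _format_number(n / fs, 8)
        if abs(float(rec_dur) * fs - n) > 1e-6:
            raise ValueError(
                f"record duration {n / fs} s not representable in an EDF header; "
                "use a whole-second recording or the text format"
            )

    ns = record.n_channels
    pmax = np.maximum(1.05 * np.max(np.abs(record.samples), axis=0), 1e-3)
    pmin = -pmax

    header = b"".join([
        _field("0", 8), _field("X", 80), _field("X", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(str(256 * (ns + 1)), 8), _field("", 44),
        _field(str(n_records), 8), _field(rec_dur, 8), _field(str(ns), 4),
    ])
    per_sig = [
        b"".join(_field(name[:16], 16) for name in record.channel_names),
        b"".join(_field("", 80) for _ in range(ns)),
        b"".join(_field("uV", 8) for _ in range(ns)),
        b"".join(_field(_format_number(lo, 8), 8) for lo in pmin),
        b"".join(_field(_format_number(hi, 8), 8) for hi in pmax),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_field("", 80) for _ in range(ns)),
        b"".join(_field(str(samples_per_record), 8) for _ in range(ns)),
        b"".join(_field("", 32) for _ in range(ns)),
    ]

    # header-declared ranges are re-parsed for the scaling so that
    # writer and any conforming reader use identical maps
    pmin_h = np.array([float(_format_number(lo, 8)) for lo in pmin])
    pmax_h = np.array([float(_format_number(hi, 8)) for hi in pmax])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax_h - pmin_h)
    digital = np.rint((record.samples - pmin_h) * scale + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_sig:
            fh.write(block)
        # records: for each record, each signal's chunk contiguously
        for r in range(n_records):
            chunk = digital[r * samples_per_record : (r + 1) * samples_per_record]
            fh.write(np.ascontiguousarray(chunk.T).tobytes())


def read_edf(path) -> SignalRecord:
    """Read an EDF file written by :func:`write_edf` (or any single-rate EDF)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        n_records = int(head[236:244].decode("ascii"))
        rec_dur = float(head[244:252].decode("ascii"))
        ns = int(head[252:256].decode("ascii"))
        sig = fh.read(256 * ns)

        # field offsets within the per-signal block, in bytes:
        # 0 label(16*ns), 16ns transducer(80*ns), 96ns unit(8*ns),
        # 104ns pmin(8*ns), 112ns pmax(8*ns), 120ns dmin(8*ns),
        # 128ns dmax(8*ns), 136ns prefilter(80*ns), 216ns spr(8*ns)
        def block(start: int, width: int) -> list[str]:
            return [
                sig[start * ns + i * width : start * ns + (i + 1) * width]
                .decode("ascii").strip()
                for i in range(ns)
            ]

        labels = block(0, 16)
        units = block(96, 8)
        pmin = np.array([float(v) for v in block(104, 8)])
        pmax = np.array([float(v) for v in block(112, 8)])
        dmin = np.array([float(v) for v in block(120, 8)])
        dmax = np.array([float(v) for v in block(128, 8)])
        spr = [int(v) for v in block(216, 8)]
        if len(set(spr)) != 1:
            raise ValueError(f"mixed per-signal sampling rates {sorted(set(spr))} unsupported")
        samples_per_record = spr[0]

        raw = np.frombuffer(
            fh.read(2 * ns * samples_per_record * n_records), dtype="<i2"
        )

    expected = ns * samples_per_record * n_records
    if raw.size != expected:
        raise ValueError(f"EDF data truncated: {raw.size} values, expected {expected}")
    # (record, signal, sample) -> (record*sample, signal)
    data = raw.reshape(n_records, ns, samples_per_record)
    data = np.transpose(data, (0, 2, 1)).reshape(-1, ns).astype(np.float64)

    scale = (pmax - pmin) / (dmax - dmin)
    physical = (data - dmin) * scale + pmin

    # normalize units to μV
    for i, u in enumerate(units):
        ul = u.lower()
        if ul in ("uv", "µv", ""):
            pass
        elif ul == "mv":
            physical[:, i] *= 1e3
        elif ul == "v":
            physical[:, i] *= 1e6
        else:
            raise ValueError(f"channel {labels[i]!r} has unsupported unit {u!r}")

    fs = samples_per_record / rec_dur
    return SignalRecord(samples=physical, sampling_rate=fs, channel_names=labels)


def quantization_step(record: SignalRecord) -> np.ndarray:
    """Per-channel physical value of one 16-bit step at write time."""
    pmax = np.maximum(1.05 * np.max(np.abs(record.samples), axis=0), 1e-3)
    return 2 * pmax / (_DIG_MAX - _DIG_MIN)
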