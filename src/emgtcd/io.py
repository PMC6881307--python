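"""Readers and writers for trunk sEMG recordings.

Two on-disk formats are supported:

``delimited``
    A TSV (or CSV) with one column per channel, a header row of muscle
    codes, sample values in microvolts, plus a JSON sidecar
    (``<file>.json``) carrying the sampling rate and trial metadata.
    Values survive a round-trip to better than 1e-6 microvolt.

``edf``
    European Data Format, 16-bit, physical dimension "uV", one data
    record. Trial metadata (task/label/side/subject) is packed into the
    EDF recording-identification header field.  EDF quantizes to 16 bits
    over the recording's amplitude range, so round-trip precision is the
    quantization step, not the delimited format's near-exactness.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CANONICAL_ORDER, channels_for_codes, check_pairs_complete
from .errors import FormatError
from .recording import EmgRecording

__all__ = ["read_recording", "write_recording"]


# --------------------------------------------------------------------------
# delimited format

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_delimited(rec: EmgRecording, path: Path) -> None:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(rec.samples.T, columns=rec.codes)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    meta = {
        "fs": rec.fs,
        "channels": rec.codes,
        "task": rec.task,
        "label": rec.label,
        "affected_side": rec.affected_side,
        "subject_id": rec.subject_id,
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_delimited(path: Path) -> EmgRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    codes = list(df.columns)
    if codes != list(meta.get("channels", codes)):
        raise FormatError("sidecar channel list disagrees with data header")
    for c in codes:
        if c not in CANONICAL_ORDER:
            raise FormatError(f"unknown muscle code {c!r} in {path.name}")
    check_pairs_complete(codes)
    rec = EmgRecording(
        samples=df.to_numpy().T,
        fs=float(meta["fs"]),
        channels=channels_for_codes(codes),
        task=meta.get("task", "T1"),
        label=meta.get("label", "NC"),
        subject_id=meta.get("subject_id", ""),
        affected_side=meta.get("affected_side", "none"),
    )
    return rec.canonicalized()


# --------------------------------------------------------------------------
# EDF format (16-bit, single data record)

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def _write_edf(rec: EmgRecording, path: Path) -> None:
    ns = len(rec.channels)
    n = rec.n_samples
    header_bytes = 256 + 256 * ns
    duration = n / rec.fs
    recording_id = (
        f"task={rec.task} label={rec.label} side={rec.affected_side} "
        f"subject={rec.subject_id}"
    )
    head = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad(recording_id, 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(header_bytes), 8),
        _pad("", 44),
        _pad("1", 8),
        _pad(f"{duration:.6g}", 8),
        _pad(str(ns), 4),
    ])
    # per-channel physical scaling over the observed range
    pmins, pmaxs = [], []
    digital = np.empty((ns, n), dtype="<i2")
    for i, row in enumerate(rec.samples):
        lo, hi = float(row.min()), float(row.max())
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        scaled = (row - lo) / (hi - lo) * 65535.0 - 32768.0
        digital[i] = np.clip(np.round(scaled), -32768, 32767).astype("<i2")
    fields = []
    for getter in (
        lambda i: _pad(rec.channels[i].code, 16),
        lambda i: _pad("", 80),
        lambda i: _pad("uV", 8),
        lambda i: _pad(f"{pmins[i]:.7g}"[:8], 8),
        lambda i: _pad(f"{pmaxs[i]:.7g}"[:8], 8),
        lambda i: _pad("-32768", 8),
        lambda i: _pad("32767", 8),
        lambda i: _pad("", 80),
        lambda i: _pad(str(n), 8),
        lambda i: _pad("", 32),
    ):
        fields.extend(getter(i) for i in range(ns))
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(b"".join(fields))
        fh.write(digital.tobytes())


def _ascii(b: bytes) -> str:
    return b.decode("ascii", "replace").strip()


def _read_edf(path: Path) -> EmgRecording:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FormatError(f"{path.name}: truncated EDF header")
    recording_id = _ascii(raw[88:168])
    n_records = int(_ascii(raw[236:244]))
    record_duration = float(_ascii(raw[244:252]))
    ns = int(_ascii(raw[252:256]))
    off = 256

    def field(width: int) -> list[str]:
        nonlocal off
        out = [_ascii(raw[off + i * width: off + (i + 1) * width]) for i in range(ns)]
        off += ns * width
        return out

    labels = field(16)
    field(80)  # transducer
    dims = field(8)
    pmin = [float(v) for v in field(8)]
    pmax = [float(v) for v in field(8)]
    dmin = [int(v) for v in field(8)]
    dmax = [int(v) for v in field(8)]
    field(80)  # prefiltering
    nsamp = [int(v) for v in field(8)]
    field(32)  # reserved

    for d in dims:
        if d not in ("uV", "mV"):
            raise FormatError(f"unsupported physical dimension {d!r}")
    data = np.frombuffer(raw[off:], dtype="<i2")
    per_record = sum(nsamp)
    if data.size != per_record * n_records:
        raise FormatError(f"{path.name}: data section size mismatch")
    data = data.reshape(n_records, per_record)
    channels = []
    starts = np.concatenate([[0], np.cumsum(nsamp)])
    for i in range(ns):
        dig = data[:, starts[i]: starts[i + 1]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = pmin[i] + (dig - dmin[i]) * gain
        if dims[i] == "mV":
            phys *= 1000.0
        channels.append(phys)
    n_total = nsamp[0] * n_records
    fs = n_total / (record_duration * n_records)
    meta = dict(
        kv.split("=", 1) for kv in recording_id.split() if "=" in kv
    )
    codes = [lbl.split()[0] for lbl in labels]
    for c in codes:
        if c not in CANONICAL_ORDER:
            raise FormatError(f"unknown muscle code {c!r} in {path.name}")
    check_pairs_complete(codes)
    rec = EmgRecording(
        samples=np.vstack(channels),
        fs=fs,
        channels=channels_for_codes(codes),
        task=meta.get("task", "T1"),
        label=meta.get("label", "NC"),
        subject_id=meta.get("subject", ""),
        affected_side=meta.get("side", "none"),
    )
    return rec.canonicalized()


# --------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("delimited", "edf"):
            raise FormatError(f"unknown format {format!r}")
        return format
    return "edf" if path.suffix.lower() == ".edf" else "delimited"


def read_recording(path, format: str | None = None) -> EmgRecording:
    """Read a recording from disk, normalizing channels to canonical order.

    ``format`` is inferred from the extension (``.edf`` vs anything else)
    when not given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    return _read_edf(path) if fmt == "edf" else _read_delimited(path)


def write_recording(rec: EmgRecording, path, format: str | None = None) -> Path:
    """Write a recording; returns the path written."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_delimited(rec, path)
    return path
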