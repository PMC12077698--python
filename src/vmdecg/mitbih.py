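"""Optional validation on MIT-BIH style ECG records.

Contains a compact reader (and, for fixture fabrication, writer) for the
WFDB record layout used by the MIT-BIH Arrhythmia Database: a text header
(``.hea``), a binary signal file in format 212 (two 12-bit samples packed
into 3 bytes) or format 16 (little-endian int16), and the MIT annotation
format (``.atr``) carrying beat labels.  Only the subset of the formats
needed to window beats out of such records is supported.

``load_mitbih`` extracts fixed-width windows centered on annotated beats
of the requested classes (default N = normal, V = premature ventricular
contraction, A = premature atrial contraction) from the MLII lead,
resamples them to the target rate and returns a labeled
:class:`~vmdecg.datasets.SignalDataset` with a stratified 80/20 split.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from .datasets import SignalDataset, SyntheticSignal

__all__ = [
    "WFDBRecord",
    "read_record",
    "read_annotations",
    "write_record",
    "write_annotations",
    "load_mitbih",
]

# annotation code <-> beat mnemonic (common subset)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 38: "f",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}


@dataclass
class WFDBRecord:
    name: str
    fs: float
    signals: np.ndarray       # (n_sig, n_samples), physical units
    lead_names: list


def _parse_signal_spec(line: str):
    tok = line.split()
    fname, fmt = tok[0], tok[1]
    gain, baseline = 200.0, 0
    if len(tok) > 2:
        g = tok[2].split("/")[0]
        if "(" in g:
            g, b = g.split("(")
            baseline = int(b.rstrip(")"))
        gain = float(g) if float(g) != 0 else 200.0
    desc = tok[-1] if len(tok) > 4 else ""
    return fname, fmt, gain, baseline, desc


def read_record(header_path) -> WFDBRecord:
    """Read a WFDB record (format 212 or 16) given its ``.hea`` path."""
    header_path = str(header_path)
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    base_dir = os.path.dirname(header_path)
    with open(header_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    specs = [_parse_signal_spec(ln) for ln in lines[1:1 + n_sig]]
    fnames = [s[0] for s in specs]
    if len(set(fnames)) != 1:
        raise NotImplementedError("multi-file records are not supported")
    fmt = specs[0][1]
    raw_path = os.path.join(base_dir, fnames[0])
    with open(raw_path, "rb") as fh:
        buf = fh.read()
    if fmt == "212":
        data = np.frombuffer(buf, dtype=np.uint8)
        n_pairs = len(data) // 3
        d = data[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
        first = ((d[:, 1] & 0x0F) << 8) | d[:, 0]
        second = ((d[:, 1] & 0xF0) << 4) | d[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        flat = np.empty(2 * n_pairs, dtype=np.int32)
        flat[0::2], flat[1::2] = first, second
        total = n_samp * n_sig if n_samp else (len(flat) // n_sig) * n_sig
        adc = flat[:total].reshape(-1, n_sig).T
    elif fmt == "16":
        flat = np.frombuffer(buf, dtype="<i2").astype(np.int32)
        total = n_samp * n_sig if n_samp else (len(flat) // n_sig) * n_sig
        adc = flat[:total].reshape(-1, n_sig).T
    else:
        raise NotImplementedError(f"unsupported WFDB format {fmt!r}")
    phys = np.empty(adc.shape, dtype=float)
    for i, (_, _, gain, baseline, _) in enumerate(specs):
        phys[i] = (adc[i] - baseline) / gain
    return WFDBRecord(name=name, fs=fs, signals=phys, lead_names=[s[4] for s in specs])


def read_annotations(atr_path):
    """Read MIT-format annotations; returns (sample_indices, symbols)."""
    with open(str(atr_path), "rb") as fh:
        buf = fh.read()
    times, symbols = [], []
    t, i = 0, 0
    while i + 1 < len(buf):
        word = buf[i] | (buf[i + 1] << 8)
        i += 2
        code, data = word >> 10, word & 0x3FF
        if code == 0 and data == 0:
            break
        if code == 59:  # SKIP: 4-byte interval follows
            if i + 3 >= len(buf):
                break
            interval = struct.unpack("<i", bytes([buf[i + 2], buf[i + 3], buf[i], buf[i + 1]]))[0]
            t += interval
            i += 4
        elif code == 63:  # AUX: skip padded payload
            i += data + (data & 1)
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        else:
            t += data
            times.append(t)
            symbols.append(_CODE_TO_SYMBOL.get(code, "?"))
    return np.asarray(times, dtype=int), symbols


def write_record(prefix, signals, fs: float, lead_names=None, fmt: str = "16",
                 gain: float = 200.0) -> None:
    """Write ``<prefix>.hea`` + ``<prefix>.dat`` (format 16 only).

    Intended for fabricating small synthetic test records.
    """
    prefix = str(prefix)
    sig = np.atleast_2d(np.asarray(signals, dtype=float))
    n_sig, n_samp = sig.shape
    lead_names = lead_names or [f"lead{i}" for i in range(n_sig)]
    if fmt != "16":
        raise NotImplementedError("the fixture writer supports format 16 only")
    name = os.path.basename(prefix)
    with open(prefix + ".hea", "w") as fh:
        fh.write(f"{name} {n_sig} {fs:g} {n_samp}\n")
        for i in range(n_sig):
            fh.write(f"{name}.dat 16 {gain:g} 12 0 0 0 0 {lead_names[i]}\n")
    adc = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
    adc.T.reshape(-1).tofile(prefix + ".dat")


def write_annotations(atr_path, times, symbols) -> None:
    """Write MIT-format annotations (synthetic fixtures only)."""
    out = bytearray()
    prev = 0
    for t, sym in zip(times, symbols):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"unsupported symbol {sym!r}")
        delta = int(t) - prev
        if delta > 1023:
            b = struct.pack("<i", delta)
            out += struct.pack("<H", 59 << 10)
            out += b[2:4] + b[0:2]  # high word first, as read back
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = int(t)
    out += struct.pack("<H", 0)
    with open(str(atr_path), "wb") as fh:
        fh.write(out)


def load_mitbih(record_prefixes, classes=("N", "V", "A"), window: int = 256,
                fs_out: float = 300.0, test_frac: float = 0.20, seed: int = 0) -> SignalDataset:
    """Window annotated beats of the requested classes out of WFDB records.

    ``record_prefixes``: paths without extension (``<prefix>.hea``,
    ``.dat``, ``.atr`` must exist).  Beats whose window would cross a
    record boundary are skipped and counted in ``meta['skipped']``.
    Requires at least two classes to be present for downstream training.
    """
    classes = tuple(classes)
    rng = np.random.default_rng(seed)
    signals, skipped, unknown = [], 0, 0
    for prefix in record_prefixes:
        prefix = str(prefix)
        rec = read_record(prefix + ".hea")
        lead = 0
        for i, nm in enumerate(rec.lead_names):
            if nm.upper() == "MLII":
                lead = i
                break
        x = rec.signals[lead]
        times, symbols = read_annotations(prefix + ".atr")
        half = window // 2
        for t, sym in zip(times, symbols):
            if sym not in classes:
                unknown += 1
                continue
            if t - half < 0 or t + half > x.size:
                skipped += 1
                continue
            seg = x[t - half:t + half]
            if fs_out != rec.fs:
                up, down = int(round(fs_out)), int(round(rec.fs))
                seg = resample_poly(seg, up, down)
            signals.append(
                SyntheticSignal(samples=seg, fs=fs_out, label=sym, point_id=int(t),
                                noise_sigma=0.0)
            )
    present = {s.label for s in signals}
    if len(present) < 2:
        raise ValueError(
            f"need beats from >= 2 classes for training, found {sorted(present)}"
        )
    labels = np.array([s.label for s in signals])
    split = np.full(labels.shape, "train", dtype=object)
    for lab in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == lab))
        split[idx[: int(round(test_frac * idx.size))]] = "test"
    return SignalDataset(
        signals=signals,
        split=split.astype(str),
        seed=seed,
        meta={"skipped": skipped, "other_symbols": unknown, "classes": list(classes),
              "window": window, "fs_out": fs_out},
    )
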