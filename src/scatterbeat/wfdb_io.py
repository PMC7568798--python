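"""Minimal WFDB record and annotation I/O.

Supports the subset of the WFDB specification needed for MIT-BIH style
records: text headers (``.hea``), signal files in format 212 (packed 12-bit
pairs) and format 16 (little-endian int16), and MIT-format binary beat
annotations (``.atr``) including SKIP long intervals and AUX/NUM/SUB/CHN
modifier words.  A writer for format-16 records and annotations is provided
so synthetic fixtures can exercise the reader offline.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np

# MIT annotation code -> symbol (ecgcodes vocabulary)
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalInfo:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    adc_zero: int
    description: str


@dataclass
class Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalInfo]


def read_header(path: str) -> Header:
    """Parse a ``.hea`` file; ``path`` may omit the extension."""
    if not path.endswith(".hea"):
        path = path + ".hea"
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    name, n_sig = rec[0], int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain = float(gain_part.split("(")[0])
            baseline = int(gain_part.split("(")[1].rstrip(")"))
        else:
            gain = float(gain_part)
            baseline = None
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if gain == 0:
            gain = 200.0
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalInfo(tok[0], fmt,
                                  gain, baseline if baseline is not None else adc_zero,
                                  adc_zero, description))
    return Header(name, n_sig, fs, n_samples, signals)


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format-212 bytes: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2], out[1::2] = s0, s1
    out[out > 2047] -= 4096
    return out[:n_values]


def read_record(path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a WFDB record; returns (physical signals (n, n_sig), fs, names).

    Physical units are ``(adc - baseline) / gain``.  All signals must share
    one signal file (the MIT-BIH layout).
    """
    hdr = read_header(path)
    base = os.path.dirname(os.path.abspath(
        path if not path.endswith(".hea") else path[:-4]))
    dat_path = os.path.join(base, hdr.signals[0].file_name)
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    fmt = hdr.signals[0].fmt
    n_values = hdr.n_samples * hdr.n_sig if hdr.n_samples else None
    if fmt == 212:
        flat = _decode_212(raw, n_values or (len(raw) // 3) * 2)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if n_values:
            flat = flat[:n_values]
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    adc = flat.reshape(-1, hdr.n_sig)
    phys = np.empty(adc.shape, dtype=float)
    for i, s in enumerate(hdr.signals):
        phys[:, i] = (adc[:, i] - s.baseline) / s.gain
    return phys, hdr.fs, [s.description for s in hdr.signals]


def read_annotations(path: str, extension: str = "atr") -> list[tuple[int, str]]:
    """Read MIT-format annotations; returns [(sample_index, symbol), ...]."""
    if not path.endswith("." + extension):
        path = path + "." + extension
    with open(path, "rb") as fh:
        raw = fh.read()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            t += (hi << 16) | lo
        elif code == _AUX:
            i += interval + (interval & 1)
        elif code in (_NUM, _SUB, _CHN):
            pass
        else:
            t += interval
            out.append((t, CODE_TO_SYMBOL.get(code, "?")))
    return out


def write_record(directory: str, name: str, signals: np.ndarray, fs: float,
                 sig_names: list[str], gain: float = 200.0,
                 adc_zero: int = 0) -> str:
    """Write a format-16 WFDB record (``.hea`` + ``.dat``); returns its path."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:  # accept (n_sig, n) layout
        signals = signals.T
    n, n_sig = signals.shape
    adc = np.clip(np.round(signals * gain) + adc_zero, -32768, 32767).astype("<i2")
    dat_name = f"{name}.dat"
    with open(os.path.join(directory, dat_name), "wb") as fh:
        fh.write(adc.reshape(-1).tobytes())
    lines = [f"{name} {n_sig} {fs:g} {n}"]
    for j in range(n_sig):
        lines.append(
            f"{dat_name} 16 {gain:g}({adc_zero})/mV 16 {adc_zero} "
            f"{int(adc[0, j])} 0 0 {sig_names[j]}")
    path = os.path.join(directory, name)
    with open(path + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def write_annotations(path: str, annotations: list[tuple[int, str]],
                      extension: str = "atr") -> None:
    """Write MIT-format annotations given [(sample_index, symbol), ...]."""
    if not path.endswith("." + extension):
        path = path + "." + extension
    prev = 0
    buf = bytearray()
    for sample, symbol in sorted(annotations):
        code = SYMBOL_TO_CODE[symbol]
        delta = sample - prev
        if delta > 1023 or delta < 0:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
    buf += struct.pack("<H", 0)  # EOF
    with open(path, "wb") as fh:
        fh.write(bytes(buf))
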