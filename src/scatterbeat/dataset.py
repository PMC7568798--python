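"""Heartbeat dataset handling: AAMI class mapping, segmentation, balancing.

Beat annotations are mapped onto the ANSI/AAMI EC57:1998 superclasses
(N, S, V, F, Q); class Q (paced / unclassifiable) is discarded.  Beats are
fixed 250-sample windows around the annotated R-peak (99 samples before,
150 after, at 360 Hz).  Class imbalance is addressed by subsampling the
majority class and oversampling minority classes with additive zero-mean
Gaussian noise copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from . import wfdb_io

logger = logging.getLogger("scatterbeat")

BEAT_LENGTH = 250
PRE_SAMPLES = 99   # samples before the R-peak (R sits at index 99)
POST_SAMPLES = 150

#: AAMI class order used everywhere (confusion matrices, reports).
CLASS_ORDER = ("N", "S", "V", "F")

#: MIT-BIH records from pacemaker patients, excluded by default.
DEFAULT_PACED_RECORDS = ("102", "104", "107", "217")


class AamiClass(str, Enum):
    """ANSI/AAMI EC57 beat superclasses."""

    N = "N"   # nonectopic
    S = "S"   # supraventricular ectopic
    V = "V"   # ventricular ectopic
    F = "F"   # fusion of ventricular and normal
    Q = "Q"   # paced / unclassifiable (discarded downstream)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Single-character WFDB beat codes -> AAMI class.  This table is the one
# editable source of truth for the beat-symbol vocabulary.
SYMBOL_MAP: dict[str, AamiClass] = {
    "N": AamiClass.N,   # normal
    "L": AamiClass.N,   # left bundle branch block
    "R": AamiClass.N,   # right bundle branch block
    "e": AamiClass.N,   # atrial escape
    "j": AamiClass.N,   # nodal (junctional) escape
    "A": AamiClass.S,   # atrial premature
    "a": AamiClass.S,   # aberrated atrial premature
    "J": AamiClass.S,   # nodal (junctional) premature
    "S": AamiClass.S,   # supraventricular premature
    "V": AamiClass.V,   # premature ventricular contraction
    "E": AamiClass.V,   # ventricular escape
    "F": AamiClass.F,   # fusion of ventricular and normal
    "/": AamiClass.Q,   # paced
    "f": AamiClass.Q,   # fusion of paced and normal
    "Q": AamiClass.Q,   # unclassifiable
}

# Long beat-type names (case-insensitive; a trailing " beat(s)" is ignored).
NAME_MAP: dict[str, AamiClass] = {
    "normal": AamiClass.N,
    "left bundle branch": AamiClass.N,
    "left bundle branch block": AamiClass.N,
    "right bundle branch": AamiClass.N,
    "right bundle branch block": AamiClass.N,
    "atrial escape": AamiClass.N,
    "nodal (junctional) escape": AamiClass.N,
    "nodal escape": AamiClass.N,
    "junctional escape": AamiClass.N,
    "atrial premature": AamiClass.S,
    "aberrant atrial": AamiClass.S,
    "aberrated atrial premature": AamiClass.S,
    "nodal (junctional) premature": AamiClass.S,
    "nodal premature": AamiClass.S,
    "junctional premature": AamiClass.S,
    "supraventricular premature": AamiClass.S,
    "premature ventricular contraction": AamiClass.V,
    "ventricular escape": AamiClass.V,
    "fusion of ventricular and normal": AamiClass.F,
    "paced": AamiClass.Q,
    "fusion of paced and normal": AamiClass.Q,
    "unclassifiable": AamiClass.Q,
}


@dataclass
class Beat:
    """One segmented heartbeat with provenance."""

    samples: np.ndarray
    label: AamiClass
    record_id: str = ""
    r_index: int = 0
    augmented: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LENGTH,):
            raise ValueError(f"a beat must have exactly {BEAT_LENGTH} samples")


class PacedRecordError(RuntimeError):
    """Raised when a pacemaker record is refused by the exclusion policy."""


def map_annotation_symbol(symbol: str) -> AamiClass:
    """Map a beat annotation (WFDB code or beat-type name) to its AAMI class.

    Raises ``ValueError`` for symbols outside the beat vocabulary.
    """
    if len(symbol) == 1:
        if symbol in SYMBOL_MAP:
            return SYMBOL_MAP[symbol]
    else:
        key = symbol.strip().lower()
        for suffix in (" beats", " beat"):
            if key.endswith(suffix):
                key = key[: -len(suffix)]
        if key in NAME_MAP:
            return NAME_MAP[key]
    raise ValueError(f"unknown beat annotation symbol: {symbol!r}")


def segment_beats(signal: np.ndarray, r_peaks, labels,
                  record_id: str = "") -> list[Beat]:
    """Cut fixed 250-sample beats around annotated R-peaks.

    Beats whose window would cross a record boundary are dropped, as are
    beats labeled Q; the input order is preserved.
    """
    signal = np.asarray(signal, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) != len(labels):
        raise ValueError("r_peaks and labels differ in length")
    if np.any(np.diff(r_peaks) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    beats = []
    for r, lab in zip(r_peaks, labels):
        lab = AamiClass(lab)
        if lab is AamiClass.Q:
            continue
        lo, hi = r - PRE_SAMPLES, r + POST_SAMPLES
        if lo < 0 or hi >= len(signal):
            continue
        beats.append(Beat(signal[lo:hi + 1].copy(), lab, record_id, int(r)))
    return beats


def load_wfdb_record(path: str, lead_name: str = "MLII",
                     exclude_paced: bool = True,
                     paced_records=DEFAULT_PACED_RECORDS
                     ) -> tuple[np.ndarray, np.ndarray, list[AamiClass]]:
    """Load one WFDB record: MLII channel, annotated R-peaks, AAMI labels.

    The reference annotation sample indices serve as R-peak locations (beat
    detection is deliberately not performed).  Records on the paced-record
    exclusion list raise ``PacedRecordError`` when ``exclude_paced`` is on.
    """
    import os
    name = os.path.basename(path)
    if exclude_paced and name in paced_records:
        raise PacedRecordError(f"record {name} is on the paced-record exclusion list")
    signals, fs, sig_names = wfdb_io.read_record(path)
    if lead_name not in sig_names:
        raise ValueError(
            f"record {name} has no {lead_name!r} channel (found {sig_names})")
    channel = signals[:, sig_names.index(lead_name)]
    anns = wfdb_io.read_annotations(path)
    r_peaks, labels = [], []
    for sample, symbol in anns:
        if symbol in SYMBOL_MAP:  # beat annotations only
            r_peaks.append(sample)
            labels.append(SYMBOL_MAP[symbol])
    return channel, np.asarray(r_peaks, dtype=int), labels


def plan_balance(counts: dict, target_per_class: int) -> dict:
    """Balancing-policy arithmetic: per class, how many originals to keep and
    how many noisy copies to add so every class ends at ``target_per_class``.

    Classes at or above the target are subsampled (no noise); classes below
    keep all originals and add noisy copies of resampled originals.
    """
    if target_per_class <= 0:
        raise ValueError("target_per_class must be positive")
    plan = {}
    for cls, n in counts.items():
        if n <= 0:
            raise ValueError(f"class {cls} is empty")
        keep = min(n, target_per_class)
        plan[cls] = {"keep": keep, "augment": target_per_class - keep}
    return plan


def augment_to_balance(beats: list[Beat], target_per_class: int = 90000,
                       noise_variance: float = 0.05, seed: int = 0) -> list[Beat]:
    """Balance classes to ``target_per_class`` beats each.

    Majority classes are randomly subsampled without noise; minority classes
    keep every original and append copies corrupted by i.i.d. zero-mean
    Gaussian noise of the given variance (in squared signal units) until the
    target is reached.  Kept originals retain their input order; augmented
    copies are appended class by class.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[AamiClass, list[int]] = {}
    for i, b in enumerate(beats):
        by_class.setdefault(AamiClass(b.label), []).append(i)
    plan = plan_balance({c: len(ix) for c, ix in by_class.items()}, target_per_class)

    keep_mask = np.zeros(len(beats), dtype=bool)
    for cls in sorted(by_class, key=lambda c: CLASS_ORDER.index(c.value)
                      if c.value in CLASS_ORDER else 99):
        idx = np.asarray(by_class[cls])
        n_keep = plan[cls]["keep"]
        if n_keep < len(idx):
            idx = np.sort(rng.choice(idx, size=n_keep, replace=False))
        keep_mask[idx] = True
    out = [beats[i] for i in range(len(beats)) if keep_mask[i]]

    sigma = float(np.sqrt(noise_variance))
    for cls in sorted(by_class, key=lambda c: CLASS_ORDER.index(c.value)
                      if c.value in CLASS_ORDER else 99):
        n_aug = plan[cls]["augment"]
        if n_aug == 0:
            continue
        sources = rng.integers(0, len(by_class[cls]), size=n_aug)
        for s in sources:
            src = beats[by_class[cls][s]]
            noisy = src.samples + rng.normal(0.0, sigma, size=BEAT_LENGTH)
            out.append(replace(src, samples=noisy, augmented=True))
    logger.info("balanced dataset: %d beats (%d per class)",
                len(out), target_per_class)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def beats_to_csv(beats: list[Beat], path: str) -> None:
    """Persist beats as CSV: metadata columns followed by s000..s249."""
    cols = {f"s{i:03d}": np.asarray([b.samples[i] for b in beats])
            for i in range(BEAT_LENGTH)}
    df = pd.DataFrame({
        "label": [AamiClass(b.label).value for b in beats],
        "record_id": [b.record_id for b in beats],
        "r_index": [b.r_index for b in beats],
        "augmented": [int(b.augmented) for b in beats],
        **cols,
    })
    df.to_csv(path, index=False)


def beats_from_csv(path: str) -> list[Beat]:
    df = pd.read_csv(path, keep_default_na=False)
    sample_cols = [f"s{i:03d}" for i in range(BEAT_LENGTH)]
    samples = df[sample_cols].to_numpy(dtype=float)
    return [Beat(samples[i], AamiClass(df["label"].iloc[i]),
                 str(df["record_id"].iloc[i]), int(df["r_index"].iloc[i]),
                 bool(df["augmented"].iloc[i]))
            for i in range(len(df))]
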