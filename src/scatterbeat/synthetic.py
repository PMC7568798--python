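"""Synthetic labeled heartbeats with class-distinct lead-II-like morphology.

Each beat is a sum of Gaussian bumps standing in for the P, Q, R, S and T
waves, sampled on the standard 250-sample grid (nominal 360 Hz) with the
R-peak at index 99.  The four templates sketch the textbook AAMI classes:
N has a full P-QRS-T sequence; S a reduced P moved close to the R-peak;
V a widened QRS without P and an inverted T; F averages the N and V shapes.
Per-beat jitter on amplitudes, widths and offsets plus baseline noise gives
within-class variability.  These are test fixtures with enough class
separation to exercise the pipeline end to end, not physiological models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import wfdb_io
from .dataset import BEAT_LENGTH, PRE_SAMPLES, AamiClass, Beat

R_INDEX = PRE_SAMPLES  # 99


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: center offset from the R-peak, width, amplitude."""

    offset: float      # samples relative to the R-peak
    width: float       # Gaussian sigma, samples
    amplitude: float   # mV


@dataclass(frozen=True)
class BeatTemplate:
    label: AamiClass
    components: tuple[WaveComponent, ...]
    amp_jitter: float = 0.05      # relative sigma on amplitudes
    width_jitter: float = 0.05    # relative sigma on widths
    offset_jitter: float = 1.0    # absolute sigma on offsets, samples
    noise_variance: float = 4e-4  # baseline noise, mV^2


def _waves(*comps) -> tuple[WaveComponent, ...]:
    return tuple(WaveComponent(*c) for c in comps)


#: Default class templates (offset, width, amplitude) per wave.
DEFAULT_TEMPLATES: dict[AamiClass, BeatTemplate] = {
    AamiClass.N: BeatTemplate(AamiClass.N, _waves(
        (-54, 9, 0.15),    # P
        (-7, 3, -0.12),    # Q
        (0, 4, 1.00),      # R
        (7, 3, -0.20),     # S
        (52, 18, 0.30),    # T
    )),
    AamiClass.S: BeatTemplate(AamiClass.S, _waves(
        (-32, 7, 0.05),    # reduced P, shortened pre-R interval
        (-7, 3, -0.12),
        (0, 4, 1.00),
        (7, 3, -0.20),
        (52, 16, 0.28),
    )),
    AamiClass.V: BeatTemplate(AamiClass.V, _waves(
        (0, 12, 0.90),     # widened QRS, no P
        (24, 6, -0.40),
        (55, 20, -0.35),   # inverted T
    )),
    # F is morphologically between N and V: both sets at half amplitude.
    AamiClass.F: BeatTemplate(AamiClass.F, _waves(
        (-54, 9, 0.075), (-7, 3, -0.06), (0, 4, 0.50), (7, 3, -0.10),
        (52, 18, 0.15),
        (0, 12, 0.45), (24, 6, -0.20), (55, 20, -0.175),
    )),
}


def template_waveform(template: BeatTemplate) -> np.ndarray:
    """Noise- and jitter-free waveform of a template (the class mean shape)."""
    t = np.arange(BEAT_LENGTH, dtype=float)
    x = np.zeros(BEAT_LENGTH)
    for c in template.components:
        x += c.amplitude * np.exp(-((t - (R_INDEX + c.offset)) ** 2)
                                  / (2.0 * c.width**2))
    return x


def generate_beat(template: BeatTemplate, seed=None) -> Beat:
    """Draw one beat: jittered Gaussian components plus baseline noise.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed seed
    reproduces the beat exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = np.arange(BEAT_LENGTH, dtype=float)
    x = rng.normal(0.0, np.sqrt(template.noise_variance), BEAT_LENGTH)
    for c in template.components:
        amp = c.amplitude * (1.0 + template.amp_jitter * rng.normal())
        width = max(c.width * (1.0 + template.width_jitter * rng.normal()), 0.5)
        center = R_INDEX + c.offset + template.offset_jitter * rng.normal()
        x += amp * np.exp(-((t - center) ** 2) / (2.0 * width**2))
    return Beat(x, template.label, record_id="synthetic", r_index=R_INDEX)


def generate_dataset(n_per_class: int, seed: int = 0,
                     templates: dict[AamiClass, BeatTemplate] | None = None
                     ) -> list[Beat]:
    """Balanced 4-class synthetic dataset, shuffled, reproducible by seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    templates = templates or DEFAULT_TEMPLATES
    rng = np.random.default_rng(seed)
    beats = [generate_beat(templates[cls], rng)
             for cls in (AamiClass.N, AamiClass.S, AamiClass.V, AamiClass.F)
             for _ in range(n_per_class)]
    order = rng.permutation(len(beats))
    return [beats[i] for i in order]


def write_wfdb_fixture(directory: str, name: str = "synth100",
                       n_beats: int = 12, seed: int = 0,
                       gap: int = 310) -> str:
    """Write a tiny synthetic two-channel WFDB record with beat annotations.

    Channel 0 is a low-amplitude distractor; channel 1 is labeled MLII and
    carries the beats, so channel selection by name is exercised.  Returns
    the record path (without extension).  Clearly synthetic: for testing
    the WFDB reader offline only.
    """
    rng = np.random.default_rng(seed)
    classes = [AamiClass.N, AamiClass.S, AamiClass.V, AamiClass.F]
    total = n_beats * gap + 200
    mlii = np.zeros(total)
    anns = []
    symbols = {AamiClass.N: "N", AamiClass.S: "A",
               AamiClass.V: "V", AamiClass.F: "F"}
    pos = 150
    for i in range(n_beats):
        cls = classes[i % 4]
        beat = generate_beat(DEFAULT_TEMPLATES[cls], rng)
        r = pos + R_INDEX
        mlii[pos:pos + BEAT_LENGTH] += beat.samples
        anns.append((r, symbols[cls]))
        pos += gap
    distractor = 0.05 * rng.normal(size=total)
    path = wfdb_io.write_record(directory, name,
                                np.column_stack([distractor, mlii]),
                                fs=360.0, sig_names=["V5", "MLII"])
    wfdb_io.write_annotations(path, anns)
    return path
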