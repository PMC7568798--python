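"""Two-order 1-D wavelet scattering transform with Gabor (analytic Morlet) filter banks.

The scattering transform cascades wavelet convolution, complex modulus and
Gaussian low-pass averaging.  Order 0 is the low-passed signal, order 1 the
low-passed wavelet moduli, order 2 the low-passed moduli of moduli, restricted
to frequency-decreasing paths.  The output is locally translation invariant up
to the invariance scale ``T`` and stable to small deformations, which is what
makes it useful as a fixed (non-learned) feature extractor for heartbeats.

All convolutions are computed by FFT on a reflection-padded copy of the input;
the averaged coefficients are critically downsampled at a power-of-two hop
derived from the low-pass bandwidth.  Under the default ECG configuration
(360 Hz, T = 0.5 s, Q = [8, 1], 250-sample beats) the transform produces
75 scattering paths and 8 time windows per beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("scatterbeat")

# ---------------------------------------------------------------------------
# Frozen filter-bank design constants.
#
# XI_MAX          highest wavelet center frequency, cycles/sample
# PHI_SUPPORT     low-pass Gaussian support in standard deviations: the
#                 +-3 sigma extent of phi equals the invariance scale T
# LIN_STEP        linear-regime spacing, in units of the low-pass sigma
# LIN_FLOOR       lowest wavelet center, in units of the low-pass sigma
# FWHM            full width at half maximum of a unit-sigma Gaussian;
#                 used both as the "bandwidth" in the frequency-decreasing
#                 path rule and to set the critical hop
# ---------------------------------------------------------------------------
XI_MAX = 0.35
PHI_SUPPORT = 6.0
LIN_STEP = 1.0
LIN_FLOOR = 1.5
FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ScatteringConfig:
    """Architecture of the scattering network.

    Parameters
    ----------
    sampling_rate : float
        Input sampling rate in Hz.
    invariance_scale : float
        Time support T of the low-pass filter, in seconds.  Features are
        invariant to translations up to roughly this scale.
    q_factors : tuple of int
        Wavelets per octave for each filter-bank layer, one entry per order.
    max_order : int
        Maximal scattering order (2 keeps ~99% of the signal energy).
    signal_length : int
        Expected input length in samples.
    oversampling : int
        log2 oversampling factor; 0 means critical downsampling.
    """

    sampling_rate: float = 360.0
    invariance_scale: float = 0.5
    q_factors: tuple[int, ...] = (8, 1)
    max_order: int = 2
    signal_length: int = 250
    oversampling: int = 0

    def __post_init__(self) -> None:
        if self.invariance_scale * self.sampling_rate > self.signal_length:
            raise ValueError(
                "invariance scale exceeds the signal duration: "
                f"T*fs = {self.invariance_scale * self.sampling_rate:.1f} "
                f"> {self.signal_length} samples"
            )
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if len(self.q_factors) != self.max_order:
            raise ValueError("q_factors must have max_order entries")
        if any(q < 1 for q in self.q_factors):
            raise ValueError("every Q factor must be >= 1")

    @property
    def padded_length(self) -> int:
        """FFT length: next power of two accommodating two-sided reflection."""
        return int(2 ** np.ceil(np.log2(2 * self.signal_length)))


@dataclass
class FilterBank:
    """Frequency-domain Gabor wavelets and Gaussian low-pass for the cascade.

    ``wavelets_layer1``/``wavelets_layer2`` hold the transfer functions on the
    full FFT grid of length ``padded_length``; center frequencies are strictly
    decreasing within each layer.  ``paths`` lists every scattering path as a
    tuple: ``()`` for order 0, ``(i1,)`` for order 1, ``(i1, i2)`` for the
    frequency-decreasing order-2 paths.
    """

    config: ScatteringConfig
    lowpass: np.ndarray
    wavelets_layer1: list[np.ndarray]
    wavelets_layer2: list[np.ndarray]
    center_frequencies: list[np.ndarray]   # Hz, one array per layer
    bandwidths: list[np.ndarray]           # Hz (Gaussian sigma), per layer
    hop: int
    paths: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def n_windows(self) -> int:
        return int(np.ceil(self.config.signal_length / self.hop))

    @property
    def window_times(self) -> np.ndarray:
        """Window positions as sample indices into the original signal."""
        return np.arange(0, self.config.signal_length, self.hop)


def _layer_frequencies(q: int, sigma_phi: float, xi_max: float = XI_MAX
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Center frequencies and Gaussian sigmas (cycles/sample) for one layer.

    Geometric spacing (Q per octave) while the wavelet sigma exceeds the
    low-pass sigma, then linear spacing at constant low-pass bandwidth.  The
    relative sigma is set so adjacent geometric filters cross at half power.
    """
    alpha = (1.0 - 2.0 ** (-1.0 / q)) / (2.0 * np.sqrt(np.log(2.0)))
    xis, sigmas = [], []
    xi = xi_max
    while alpha * xi > sigma_phi:
        xis.append(xi)
        sigmas.append(alpha * xi)
        xi *= 2.0 ** (-1.0 / q)
    while xi >= LIN_FLOOR * sigma_phi:
        xis.append(xi)
        sigmas.append(sigma_phi)
        xi -= LIN_STEP * sigma_phi
    return np.asarray(xis), np.asarray(sigmas)


def _morlet_hat(freqs: np.ndarray, xi: float, sigma: float) -> np.ndarray:
    """Analytic Morlet transfer function with exact zero mean.

    A Gaussian bump at +xi minus a DC-matched correction Gaussian, so that
    psi_hat(0) = 0 identically.
    """
    main = np.exp(-((freqs - xi) ** 2) / (2.0 * sigma**2))
    corr = np.exp(-(xi**2) / (2.0 * sigma**2)) * np.exp(-(freqs**2) / (2.0 * sigma**2))
    return main - corr


def _normalize_layer(wavelets: list[np.ndarray], phi_hat: np.ndarray,
                     freqs: np.ndarray) -> None:
    """Scale a wavelet layer so the Littlewood-Paley sum never exceeds 1.

    The LP function is |phi|^2 + sum_j (|psi_j(w)|^2 + |psi_j(-w)|^2)/2; a
    common scalar on the wavelets makes its supremum exactly 1, which makes
    the wavelet-modulus operator nonexpansive.
    """
    w = np.zeros_like(freqs)
    for psi in wavelets:
        w += 0.5 * (np.abs(psi) ** 2 + np.abs(psi[_neg_index(freqs)]) ** 2)
    mask = w > 1e-12 * w.max()
    scale = np.sqrt(np.min((1.0 - np.abs(phi_hat[mask]) ** 2) / w[mask]))
    for psi in wavelets:
        psi *= scale


def _neg_index(freqs: np.ndarray) -> np.ndarray:
    """Index array mapping each FFT bin to the bin of its negated frequency."""
    n = len(freqs)
    return (-np.arange(n)) % n


def littlewood_paley(bank: FilterBank, layer: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Littlewood-Paley sum |phi|^2 + sum (|psi(w)|^2 + |psi(-w)|^2)/2.

    Returns (frequencies in cycles/sample, LP values) on the FFT grid.
    """
    freqs = np.fft.fftfreq(bank.config.padded_length)
    wavelets = bank.wavelets_layer1 if layer == 1 else bank.wavelets_layer2
    s = np.abs(bank.lowpass) ** 2
    neg = _neg_index(freqs)
    for psi in wavelets:
        s = s + 0.5 * (np.abs(psi) ** 2 + np.abs(psi[neg]) ** 2)
    return freqs, s


def build_filter_banks(config: ScatteringConfig) -> FilterBank:
    """Construct the Gabor wavelet filter banks and low-pass for ``config``.

    Wavelets are returned in the frequency domain on the padded FFT grid,
    strictly decreasing in center frequency within each layer; the low-pass
    is a unit-gain (at DC) Gaussian whose +-3 sigma support equals the
    invariance scale.  The path table covers order 0, all order-1 paths and
    the frequency-decreasing order-2 paths.
    """
    m = config.padded_length
    freqs = np.fft.fftfreq(m)

    # low-pass: time-domain sigma such that 6 sigma = T (in samples)
    sigma_t = config.invariance_scale * config.sampling_rate / PHI_SUPPORT
    sigma_phi = 1.0 / (2.0 * np.pi * sigma_t)  # cycles/sample
    phi_hat = np.exp(-(freqs**2) / (2.0 * sigma_phi**2))

    layers_xi, layers_sigma, layers_psi = [], [], []
    for q in config.q_factors:
        xis, sigmas = _layer_frequencies(q, sigma_phi)
        psis = [_morlet_hat(freqs, xi, sg) for xi, sg in zip(xis, sigmas)]
        _normalize_layer(psis, phi_hat, freqs)
        layers_xi.append(xis)
        layers_sigma.append(sigmas)
        layers_psi.append(psis)

    # critical hop: power of two not exceeding 1/(2*FWHM) of the low-pass
    hop = int(2 ** np.floor(np.log2(1.0 / (2.0 * FWHM * sigma_phi))))
    hop = max(1, hop >> config.oversampling)

    paths: list[tuple[int, ...]] = [()]
    paths += [(i,) for i in range(len(layers_xi[0]))]
    if config.max_order >= 2:
        for i1, (xi1, sg1) in enumerate(zip(layers_xi[0], layers_sigma[0])):
            for i2, xi2 in enumerate(layers_xi[1]):
                if xi2 < FWHM * sg1:  # frequency-decreasing rule
                    paths.append((i1, i2))

    fs = config.sampling_rate
    bank = FilterBank(
        config=config,
        lowpass=phi_hat,
        wavelets_layer1=layers_psi[0],
        wavelets_layer2=layers_psi[1] if config.max_order >= 2 else [],
        center_frequencies=[xi * fs for xi in layers_xi],
        bandwidths=[sg * fs for sg in layers_sigma],
        hop=hop,
        paths=paths,
    )
    logger.debug(
        "filter bank: %d order-1 wavelets, %d order-2 wavelets, %d paths, hop %d",
        len(bank.wavelets_layer1), len(bank.wavelets_layer2), bank.n_paths, bank.hop,
    )
    return bank


@dataclass
class ScatteringTensor:
    """Scattering coefficients of one beat: ``coefficients[path, window]``.

    ``path_table[p]`` gives the wavelet-index tuple of row ``p`` (empty tuple
    for the order-0 row); ``window_times`` the window positions in samples.
    """

    coefficients: np.ndarray
    path_table: list[tuple[int, ...]]
    window_times: np.ndarray

    @property
    def n_paths(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_windows(self) -> int:
        return self.coefficients.shape[1]


def _pad_reflect(x: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    """Reflection-pad rows of ``x`` (n, N) to length m; returns (padded, left)."""
    n = x.shape[-1]
    left = (m - n) // 2
    right = m - n - left
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(left, right)], mode="reflect"), left


def _transform_stack(signals: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Scattering coefficients for a stack of signals, shape (n, paths, windows)."""
    cfg = bank.config
    m = cfg.padded_length
    padded, left = _pad_reflect(signals, m)
    grid = left + bank.window_times

    f_hat = np.fft.fft(padded, axis=-1)
    phi = bank.lowpass

    def lowpass_sample(x_hat: np.ndarray) -> np.ndarray:
        return np.abs(np.fft.ifft(x_hat * phi, axis=-1))[..., grid]

    n = signals.shape[0]
    out = np.empty((n, bank.n_paths, len(grid)))
    out[:, 0, :] = lowpass_sample(f_hat)

    order1_index = {}  # wavelet index -> row
    u1_hats = {}
    row = 1
    for i1, psi1 in enumerate(bank.wavelets_layer1):
        u1 = np.abs(np.fft.ifft(f_hat * psi1, axis=-1))
        u1_hat = np.fft.fft(u1, axis=-1)
        out[:, row, :] = lowpass_sample(u1_hat)
        order1_index[i1] = row
        u1_hats[i1] = u1_hat
        row += 1

    for path in bank.paths:
        if len(path) == 2:
            i1, i2 = path
            u2 = np.abs(np.fft.ifft(u1_hats[i1] * bank.wavelets_layer2[i2], axis=-1))
            out[:, row, :] = lowpass_sample(np.fft.fft(u2, axis=-1))
            row += 1
    return out


def scattering_transform(signal: np.ndarray, bank: FilterBank,
                         config: ScatteringConfig | None = None) -> ScatteringTensor:
    """Compute the scattering coefficients of one signal.

    Raises
    ------
    ValueError
        If the signal length does not match the configuration or the input
        contains NaN.
    """
    config = config or bank.config
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.shape[0] != config.signal_length:
        raise ValueError(
            f"expected a 1-D signal of length {config.signal_length}, "
            f"got shape {signal.shape}"
        )
    if np.isnan(signal).any():
        raise ValueError("input signal contains NaN")
    coeffs = _transform_stack(signal[None, :], bank)[0]
    return ScatteringTensor(coeffs, list(bank.paths), bank.window_times.copy())


def transform_batch(beats, config: ScatteringConfig | None = None,
                    bank: FilterBank | None = None, chunk_size: int = 512,
                    n_jobs: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Transform a batch of beats into a stacked coefficient array.

    Parameters
    ----------
    beats : sequence of Beat, or array (n, signal_length)
        Input heartbeats; Beat objects contribute their samples and label.
    n_jobs : int
        Worker processes for the chunked transform; the output is identical
        for any worker count.

    Returns
    -------
    (coefficients, labels) : (ndarray (n, paths, windows), ndarray of str)
        Per-beat tensors stacked in input order; labels empty strings when
        the input is a bare array.
    """
    if len(beats) == 0:
        raise ValueError("empty batch")
    if hasattr(beats[0], "samples"):
        signals = np.stack([np.asarray(b.samples, dtype=float) for b in beats])
        labels = np.asarray([str(b.label) for b in beats])
    else:
        signals = np.asarray(beats, dtype=float)
        labels = np.asarray([""] * signals.shape[0])
    if config is None and bank is not None:
        config = bank.config
    elif config is None:
        config = ScatteringConfig(signal_length=signals.shape[1])
    if signals.shape[1] != config.signal_length:
        raise ValueError("beat length does not match the configuration")
    if np.isnan(signals).any():
        raise ValueError("input beats contain NaN")
    if bank is None:
        bank = build_filter_banks(config)

    chunks = [signals[i:i + chunk_size] for i in range(0, signals.shape[0], chunk_size)]
    if n_jobs != 1 and len(chunks) > 1:
        from joblib import Parallel, delayed
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_transform_stack)(c, bank) for c in chunks)
    else:
        parts = [_transform_stack(c, bank) for c in chunks]
    return np.concatenate(parts, axis=0), labels
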