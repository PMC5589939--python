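"""Spectral estimation: Welch PSD, (imaginary) coherence, band averaging.

PSD and cross-spectra use Welch's method with a sliding Hanning window
(default 2 s, 25% overlap, 2000 FFT points, i.e. 0.5 Hz resolution at
fs = 1000 Hz) and per-segment mean removal. Magnitude-squared coherence is
|S_xy|^2 / (S_xx * S_yy); the imaginary variant is
|Im(S_xy / sqrt(S_xx * S_yy))| and vanishes for zero-lag-identical signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.fft import rfft, rfftfreq

from .bands import DEFAULT_BANDS, BandScheme

__all__ = [
    "EpochSignals",
    "SpectralConnectome",
    "BandConnectome",
    "welch_psd",
    "coherence_matrix",
    "imaginary_coherence_matrix",
    "band_average",
    "average_epochs",
]


@dataclass(frozen=True)
class EpochSignals:
    """One epoch of ROI time series: samples x n_rois, with sampling rate."""

    data: np.ndarray
    fs: float
    epoch_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("signals must be a 2-D (samples x n_rois) array")
        if not np.isfinite(data).all():
            raise ValueError("signals contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SpectralConnectome:
    """Per-frequency-bin symmetric connectivity matrices (bins x n x n)."""

    freqs: np.ndarray
    matrices: np.ndarray

    def __post_init__(self) -> None:
        if self.matrices.shape[0] != self.freqs.shape[0]:
            raise ValueError("one matrix per frequency bin required")


@dataclass(frozen=True)
class BandConnectome:
    """One symmetric weighted matrix per band of a :class:`BandScheme`."""

    matrices: np.ndarray  # (n_bands, n, n)
    scheme: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        if self.matrices.ndim != 3:
            raise ValueError("matrices must be (n_bands, n, n)")
        if self.matrices.shape[0] != len(self.scheme):
            raise ValueError(
                f"{self.matrices.shape[0]} matrices for {len(self.scheme)} bands"
            )

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    def __getitem__(self, band: str) -> np.ndarray:
        return self.matrices[self.scheme.index(band)]


def _welch_params(x: EpochSignals, window_s: float, overlap_frac: float, nfft: int):
    nperseg = int(round(window_s * x.fs))
    if nperseg < 2:
        raise ValueError("window too short for the sampling rate")
    if x.n_samples < nperseg:
        raise ValueError(
            f"signal has {x.n_samples} samples but one {window_s} s window "
            f"requires at least {nperseg}"
        )
    if nfft < nperseg:
        raise ValueError(f"nfft={nfft} must be >= window length {nperseg}")
    noverlap = int(nperseg * overlap_frac)  # fractional overlap rounded down
    step = nperseg - noverlap
    n_segments = 1 + (x.n_samples - nperseg) // step
    return nperseg, noverlap, step, n_segments


def welch_psd(
    x: EpochSignals,
    window_s: float = 2.0,
    overlap_frac: float = 0.25,
    nfft: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per ROI.

    Returns
    -------
    freqs : (n_bins,) array — bin grid with spacing fs / nfft.
    psd : (n_bins, n_rois) array — nonnegative power spectral density.
    """
    nperseg, noverlap, _, _ = _welch_params(x, window_s, overlap_frac, nfft)
    freqs, psd = _signal.welch(
        x.data,
        fs=x.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
        axis=0,
    )
    return freqs, psd


def _cross_spectra(
    x: EpochSignals, window_s: float, overlap_frac: float, nfft: int
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged Welch cross-spectral matrix S, shape (n_bins, n, n)."""
    if x.n_rois < 2:
        raise ValueError("coherence requires at least 2 ROIs")
    nperseg, _, step, n_segments = _welch_params(x, window_s, overlap_frac, nfft)
    if n_segments < 2:
        raise ValueError(
            f"only {n_segments} Welch segment(s) available; coherence from a "
            "single averaged segment is identically 1 (degenerate) — provide a "
            "longer signal or a shorter window"
        )
    win = _signal.get_window("hann", nperseg)
    starts = np.arange(n_segments) * step
    segs = np.stack([x.data[s : s + nperseg] for s in starts])  # (seg, t, roi)
    segs = segs - segs.mean(axis=1, keepdims=True)
    X = rfft(segs * win[None, :, None], n=nfft, axis=1)  # (seg, bin, roi)
    S = np.einsum("sfi,sfj->fij", X, np.conj(X)) / n_segments
    freqs = rfftfreq(nfft, d=1.0 / x.fs)
    return freqs, S


def _normalize_cross_spectra(S: np.ndarray) -> np.ndarray:
    """S_xy / sqrt(S_xx S_yy) with zero-power bins mapped to 0."""
    auto = np.real(np.einsum("fii->fi", S))
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    return C


def coherence_matrix(
    x: EpochSignals,
    window_s: float = 2.0,
    overlap_frac: float = 0.25,
    nfft: int = 2000,
) -> SpectralConnectome:
    """Magnitude-squared coherence between every pair of ROIs.

    The returned matrices are symmetric with values in [0, 1] and the
    diagonal forced to 0 for network use.
    """
    freqs, S = _cross_spectra(x, window_s, overlap_frac, nfft)
    C = np.abs(_normalize_cross_spectra(S)) ** 2
    C = np.clip((C + C.transpose(0, 2, 1)) / 2.0, 0.0, 1.0)
    idx = np.arange(C.shape[1])
    C[:, idx, idx] = 0.0
    return SpectralConnectome(freqs=freqs, matrices=C)


def imaginary_coherence_matrix(
    x: EpochSignals,
    window_s: float = 2.0,
    overlap_frac: float = 0.25,
    nfft: int = 2000,
) -> SpectralConnectome:
    """|imaginary part of the normalized cross-spectrum|, insensitive to
    zero-phase-lag coupling (identical signals score exactly 0)."""
    freqs, S = _cross_spectra(x, window_s, overlap_frac, nfft)
    C = np.abs(np.imag(_normalize_cross_spectra(S)))
    C = np.clip((C + C.transpose(0, 2, 1)) / 2.0, 0.0, 1.0)
    idx = np.arange(C.shape[1])
    C[:, idx, idx] = 0.0
    return SpectralConnectome(freqs=freqs, matrices=C)


def band_average(sc: SpectralConnectome, bands: BandScheme = DEFAULT_BANDS) -> BandConnectome:
    """Element-wise mean of per-bin matrices over each band's bins.

    Bin inclusion is closed on both endpoints (f_low <= f <= f_high), so
    band edges that sit exactly on the grid are kept.
    """
    out = np.empty((len(bands), sc.matrices.shape[1], sc.matrices.shape[2]))
    tol = 1e-9
    for b, band in enumerate(bands):
        mask = (sc.freqs >= band.f_low - tol) & (sc.freqs <= band.f_high + tol)
        if not mask.any():
            raise ValueError(
                f"band {band.name!r} ({band.f_low}-{band.f_high} Hz) contains no "
                "frequency bins on the given grid"
            )
        out[b] = sc.matrices[mask].mean(axis=0)
    return BandConnectome(matrices=out, scheme=bands)


def average_epochs(epochs: list[BandConnectome]) -> BandConnectome:
    """Element-wise mean of band connectomes across epochs."""
    if not epochs:
        raise ValueError("cannot average an empty list of epochs")
    scheme = epochs[0].scheme
    shape = epochs[0].matrices.shape
    for e in epochs[1:]:
        if e.scheme != scheme or e.matrices.shape != shape:
            raise ValueError("epochs must share band scheme and shape")
    return BandConnectome(
        matrices=np.mean([e.matrices for e in epochs], axis=0), scheme=scheme
    )
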