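"""Multitaper spectral estimation on concatenated same-phase EEG.

One-second epochs are tapered with discrete prolate spheroidal (Slepian)
sequences, Fourier transformed, and averaged over epochs and tapers into
auto- and cross-spectral densities (1 Hz resolution).  Epochs are aligned
to the concatenation joins so no epoch straddles a splice.  Channel spectra
can be pooled (per-channel normalized, epoch-count weighted) into a single
summary spectrum, and the burst/suppression band-power ratio gives the
relative SNR in dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .phases import PhaseSegments

__all__ = [
    "TaperSet",
    "SpectrumSet",
    "CrossSpectralDensity",
    "dpss_tapers",
    "multitaper_csd",
    "pooled_power_spectrum",
    "find_band_peak",
    "relative_snr_db",
    "band_csd",
]

log = logging.getLogger(__name__)

DEFAULT_EPOCH_S = 1.0
DEFAULT_NW = 2.0
DEFAULT_K = 3


@dataclass(frozen=True)
class TaperSet:
    """Orthonormal Slepian tapers for one epoch length."""

    n_samples: int
    time_bandwidth: float
    tapers: np.ndarray  # (K, n_samples), rows orthonormal
    concentrations: np.ndarray  # (K,) eigenvalues, decreasing

    @property
    def n_tapers(self) -> int:
        return self.tapers.shape[0]


@dataclass
class SpectrumSet:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # (n_channels, n_freqs), uV^2/Hz
    n_epochs: int


@dataclass
class CrossSpectralDensity:
    frequencies: np.ndarray  # Hz
    matrix: np.ndarray  # (n_freqs, n_channels, n_channels), complex Hermitian
    n_epochs: int

    def auto_spectra(self) -> SpectrumSet:
        p = np.real(np.einsum("fcc->fc", self.matrix)).T.copy()
        return SpectrumSet(frequencies=self.frequencies, power=p, n_epochs=self.n_epochs)


def dpss_tapers(n: int, time_bandwidth: float = DEFAULT_NW, k: int = DEFAULT_K) -> TaperSet:
    """First ``k`` Slepian sequences of length ``n``, orthonormalized."""
    if n < 8:
        raise ValueError("epoch too short for tapering (need n >= 8)")
    if k > 2 * time_bandwidth - 1:
        raise ValueError(
            f"K={k} tapers exceed the well-concentrated limit 2*NW-1={2 * time_bandwidth - 1:g}")
    tap, conc = windows.dpss(n, time_bandwidth, Kmax=k, return_ratios=True, norm=2)
    tap = tap / np.linalg.norm(tap, axis=1, keepdims=True)
    return TaperSet(n_samples=n, time_bandwidth=float(time_bandwidth),
                    tapers=tap, concentrations=np.asarray(conc))


def _epoch_starts(segments: PhaseSegments, n_epoch: int) -> list[int]:
    """Start offsets of epochs that do not straddle a concatenation join."""
    bounds = list(segments.joins) + [segments.data.shape[1]]
    starts = []
    for s, e in zip(bounds, bounds[1:]):
        starts.extend(range(s, e - n_epoch + 1, n_epoch))
    return starts


def epoch_taper_fft(
    segments: PhaseSegments,
    epoch: float = DEFAULT_EPOCH_S,
    time_bandwidth: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray]:
    """Tapered epoch FFTs: (freqs, X[epoch, taper, channel, freq]).

    Epochs are demeaned per channel; the scaling is such that
    ``mean_k |X|^2 * (2 - delta_{0,Nyq}) / fs`` is a one-sided density.
    """
    fs = segments.fs
    n_epoch = int(round(epoch * fs))
    if segments.data.shape[1] < n_epoch:
        raise ValueError("segment shorter than one spectral epoch")
    tapers = dpss_tapers(n_epoch, time_bandwidth, k).tapers
    starts = _epoch_starts(segments, n_epoch)
    if len(starts) < 2:
        log.warning("multitaper estimate from %d epoch(s): high variance", len(starts))
    ep = np.stack([segments.data[:, s:s + n_epoch] for s in starts])  # (E, C, N)
    ep = ep - ep.mean(axis=2, keepdims=True)
    tapered = ep[:, None, :, :] * tapers[None, :, None, :]  # (E, K, C, N)
    x = np.fft.rfft(tapered, axis=3)
    freqs = np.fft.rfftfreq(n_epoch, d=1.0 / fs)
    return freqs, x


def multitaper_csd(
    segments: PhaseSegments,
    epoch: float = DEFAULT_EPOCH_S,
    time_bandwidth: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> CrossSpectralDensity:
    """One-sided cross-spectral density averaged over epochs and tapers."""
    freqs, x = epoch_taper_fft(segments, epoch, time_bandwidth, k)
    n_ep = x.shape[0]
    fs = segments.fs
    s = np.einsum("ekcf,ekdf->fcd", np.conj(x), x) / (n_ep * x.shape[1])
    scale = np.full(len(freqs), 2.0 / fs)
    scale[0] = 1.0 / fs
    n_epoch = int(round(epoch * fs))
    if n_epoch % 2 == 0:
        scale[-1] = 1.0 / fs
    s *= scale[:, None, None]
    s = 0.5 * (s + np.conj(np.transpose(s, (0, 2, 1))))  # enforce Hermitian symmetry
    return CrossSpectralDensity(frequencies=freqs, matrix=s, n_epochs=n_ep)


def band_csd(csd: CrossSpectralDensity, band: tuple[float, float] = (1.0, 4.0)) -> np.ndarray:
    """Unweighted mean of the CSD over the integer bins of ``band``."""
    sel = (csd.frequencies >= band[0] - 1e-9) & (csd.frequencies <= band[1] + 1e-9)
    if not np.any(sel):
        raise ValueError(f"band {band} outside the spectral support")
    return csd.matrix[sel].mean(axis=0)


def pooled_power_spectrum(spectra: SpectrumSet) -> np.ndarray:
    """Pooled power: mean over channels of total-power-normalized spectra.

    Each channel is first normalized by its own total power so high-gain
    channels do not dominate; with equal epoch counts per channel the
    epoch-count weighting reduces to a plain mean.
    """
    p = np.asarray(spectra.power, dtype=float)
    if p.size == 0 or p.shape[0] < 1:
        raise ValueError("pooled spectrum needs at least one channel")
    tot = p.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return (p / tot).mean(axis=0)


def find_band_peak(
    frequencies: np.ndarray,
    pooled: np.ndarray,
    search_range: tuple[float, float] = (0.5, 30.0),
) -> tuple[float, float]:
    """Half-maximum band around the pooled-spectrum peak, clipped to range."""
    frequencies = np.asarray(frequencies, dtype=float)
    pooled = np.asarray(pooled, dtype=float)
    sel = (frequencies >= search_range[0]) & (frequencies <= search_range[1])
    if not np.any(sel):
        raise ValueError("search range outside the spectral support")
    f = frequencies[sel]
    p = pooled[sel]
    if np.ptp(p) <= 1e-12 * max(np.max(np.abs(p)), 1e-300):
        log.warning("flat pooled spectrum: returning the full search range")
        return search_range
    imax = int(np.argmax(p))
    half = p[imax] / 2.0
    lo = imax
    while lo > 0 and p[lo - 1] >= half:
        lo -= 1
    hi = imax
    while hi < len(p) - 1 and p[hi + 1] >= half:
        hi += 1
    return float(f[lo]), float(f[hi])


def relative_snr_db(
    burst: PhaseSegments,
    suppression: PhaseSegments,
    band: tuple[float, float] = (1.0, 4.0),
    epoch: float = DEFAULT_EPOCH_S,
    time_bandwidth: float = DEFAULT_NW,
    k: int = DEFAULT_K,
) -> float:
    """Burst/suppression band-power ratio in dB (summed over channels)."""
    if burst.fs != suppression.fs or burst.data.shape[0] != suppression.data.shape[0]:
        raise ValueError("burst and suppression segments must share fs and channels")
    out = []
    for seg in (burst, suppression):
        csd = multitaper_csd(seg, epoch, time_bandwidth, k)
        psd = csd.auto_spectra()
        sel = (psd.frequencies >= band[0] - 1e-9) & (psd.frequencies <= band[1] + 1e-9)
        out.append(float(psd.power[:, sel].sum()))
    p_burst, p_supp = out
    if p_supp <= 0:
        raise ZeroDivisionError("zero suppression-phase band power")
    return float(10.0 * np.log10(p_burst / p_supp))
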