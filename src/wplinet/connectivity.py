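"""Weighted phase lag index (WPLI) connectivity.

For two channels x, y with per-segment cross-spectrum S_xy(f), the WPLI at a
frequency bin is

    WPLI(f) = | E[ Im S_xy(f) ] | / E[ | Im S_xy(f) | ]

with expectation over segments; the band value is the unweighted mean over
the bins inside the band. The imaginary cross-spectrum vanishes for zero-lag
(volume-conducted) coupling, and the magnitude weighting discounts segments
with near-zero lag, so WPLI isolates consistent true phase lags. The
estimator is invariant to rescaling either channel and lies in [0, 1]; the
degenerate 0/0 case (e.g., identical signals) is mapped to 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .spectral import BandDefinition


@dataclass
class CrossSpectralSamples:
    """Per-segment spectral coefficients restricted to one band.

    ``coeffs`` has shape (n_segments, n_channels, n_bins): Hann-windowed FFT
    coefficients of every segment at the bins inside [band.lo, band.hi).
    The cross-spectrum of a pair is ``S_xy = coeffs[:, x] * conj(coeffs[:, y])``,
    Hermitian by construction.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    band: BandDefinition
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (segments x channels x bins)")
        if self.n_segments < 2:
            raise ValueError(
                f"{self.n_segments} segment(s): WPLI needs at least 2")

    @property
    def n_segments(self) -> int:
        return self.coeffs.shape[0]

    def cross_spectrum(self, i: int, j: int) -> np.ndarray:
        """Per-segment complex cross-spectrum S_ij, shape (segments, bins)."""
        return self.coeffs[:, i, :] * np.conj(self.coeffs[:, j, :])


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel WPLI weights for one band."""

    W: np.ndarray
    band: BandDefinition
    channel_labels: list[str]
    condition: dict[str, str] = field(default_factory=dict)
    subject: int | None = None
    n_subjects: int = 1
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(W), 0, atol=1e-12):
            raise ValueError("W must have zero diagonal")
        if W.min() < -1e-12 or W.max() > 1 + 1e-12:
            raise ValueError("WPLI values must lie in [0, 1]")
        self.W = W

    def mean_weight(self) -> float:
        """Mean off-diagonal weight (the matrix-level connectivity summary)."""
        n = self.W.shape[0]
        return float(self.W.sum() / (n * (n - 1)))

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = self.W.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "subject": self.subject, "band": self.band.name,
                    **{k: v for k, v in self.condition.items()},
                    "ch_i": self.channel_labels[i],
                    "ch_j": self.channel_labels[j],
                    "wpli": self.W[i, j]})
        return pd.DataFrame(rows)


def cross_spectra(ep, band: BandDefinition, seg_sec: float = 2.0,
                  overlap: float = 0.5,
                  condition: dict[str, str] | None = None,
                  scalp_only: bool = True) -> CrossSpectralSamples:
    """Segment-level spectral coefficients inside a band.

    Segments of ``seg_sec`` with fractional ``overlap`` are cut from every
    retained epoch of the selected condition (segments never straddle
    epochs), Hann-windowed and Fourier-transformed; expectation in the WPLI
    is then taken over this pooled segment collection.
    """
    nperseg = int(round(seg_sec * ep.fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    idx = ep.retained(condition)
    if len(idx) == 0:
        raise ValueError(f"no retained epochs for condition {condition}")
    ch_idx = ep.scalp_indices() if scalp_only else np.arange(ep.epochs.shape[1])
    labels = [ep.channel_labels[i] for i in ch_idx]

    n_samp = ep.epochs.shape[-1]
    if nperseg > n_samp:
        raise ValueError(f"segment ({nperseg} samples) longer than epoch "
                         f"({n_samp} samples)")
    starts = np.arange(0, n_samp - nperseg + 1, step)
    window = get_window("hann", nperseg)
    freqs = np.fft.rfftfreq(nperseg, 1 / ep.fs)
    mask = band.bin_mask(freqs)
    if mask.sum() == 0:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}) contains no FFT bin "
            f"at df={ep.fs / nperseg:.3g} Hz")

    segs = []
    for t in idx:
        x = ep.epochs[t][ch_idx]
        for s in starts:
            seg = x[:, s:s + nperseg]
            seg = seg - seg.mean(axis=1, keepdims=True)
            segs.append(np.fft.rfft(seg * window, axis=1)[:, mask])
    coeffs = np.stack(segs)
    return CrossSpectralSamples(coeffs, freqs[mask], band, labels)


#: A pair/bin whose mean |Im S| falls below this fraction of its mean |S| is
#: treated as zero-lag degenerate (0/0 -> 0 by convention). Guards against
#: floating-point imaginary residue on truly identical or zero-lag signals.
DEGENERATE_RTOL = 1e-9


def wpli_spectrum(samples: CrossSpectralSamples) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin WPLI for every channel pair.

    Returns ``(freqs, per_bin)`` with ``per_bin`` of shape
    (channels, channels, bins): |mean_seg Im S| / mean_seg |Im S| per bin,
    zero where the denominator is (numerically) zero.
    """
    F = samples.coeffs                       # (S, C, B)
    # Im(S_xy) for all pairs at once: S x C x C x B
    cross = F[:, :, None, :] * np.conj(F[:, None, :, :])
    im = np.imag(cross)
    num = np.abs(im.mean(axis=0))            # C x C x B
    den = np.abs(im).mean(axis=0)
    scale = np.abs(cross).mean(axis=0)
    ok = den > DEGENERATE_RTOL * scale
    per_bin = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    return samples.freqs, per_bin


def wpli(samples: CrossSpectralSamples,
         condition: dict[str, str] | None = None,
         subject: int | None = None,
         bin_weighting: str = "uniform") -> ConnectivityMatrix:
    """WPLI matrix from per-segment cross-spectral samples.

    Per pair and bin: |mean_seg Im S| / mean_seg |Im S|, zero when the
    denominator vanishes (logged in ``degenerate_pairs``). The band value
    averages bins uniformly by default; ``bin_weighting="power"`` weights
    bins by mean cross-spectral magnitude.
    """
    F = samples.coeffs
    n_ch = F.shape[1]
    _, per_bin = wpli_spectrum(samples)
    if bin_weighting == "uniform":
        W = per_bin.mean(axis=2)
    elif bin_weighting == "power":
        mag = np.abs(F[:, :, None, :] * np.conj(F[:, None, :, :])).mean(axis=0)
        wsum = mag.sum(axis=2)
        W = np.where(wsum > 0, (per_bin * mag).sum(axis=2)
                     / np.where(wsum > 0, wsum, 1.0), 0.0)
    else:
        raise ValueError(f"unknown bin_weighting {bin_weighting!r}")
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)  # symmetrize against floating-point asymmetry
    degenerate = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)
                  if not per_bin[i, j].any()]
    return ConnectivityMatrix(W, samples.band, list(samples.channel_labels),
                              condition=dict(condition or {}),
                              subject=subject, degenerate_pairs=degenerate)


def band_wpli(ep, band: BandDefinition, seg_sec: float = 2.0,
              overlap: float = 0.5, condition: dict[str, str] | None = None,
              subject: int | None = None) -> ConnectivityMatrix:
    """Convenience: cross-spectra + WPLI in one call."""
    samples = cross_spectra(ep, band, seg_sec=seg_sec, overlap=overlap,
                            condition=condition)
    return wpli(samples, condition=condition, subject=subject)


def group_connectivity(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-subject matrices (montage and band must match)."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.channel_labels != first.channel_labels:
            raise ValueError("montage mismatch between matrices")
        if m.band != first.band:
            raise ValueError("band mismatch between matrices")
    W = np.mean([m.W for m in matrices], axis=0)
    return ConnectivityMatrix(W, first.band, list(first.channel_labels),
                              condition=dict(first.condition), subject=None,
                              n_subjects=len(matrices))
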