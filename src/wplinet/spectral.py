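"""Power spectral density and band-aggregated power.

PSD is estimated with Welch's method (Hann-windowed overlapping segments,
one-sided density normalization) averaged over the retained epochs of a
condition. Band powers integrate the PSD over half-open frequency intervals
[lo, hi) on the FFT grid; relative power normalizes by the sum of the five
analysis bands (i.e., total 1-50 Hz power, matching the analysis band-pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import REGIONS


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency band with half-open edge ownership [lo, hi)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got ({self.lo}, {self.hi})")

    def bin_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs < self.hi)


#: Canonical band table: delta 1-4, theta 4-8, alpha 8-13, beta 13-30,
#: gamma 30-50 Hz.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

#: Alternative edge set sometimes used when reporting band-power results
#: (alpha 8-14, beta 14-31, gamma 31-50); selectable, never silently merged
#: with the canonical table.
RESULTS_SECTION_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 50.0),
)

BAND_TABLES: dict[str, tuple[BandDefinition, ...]] = {
    "canonical": CANONICAL_BANDS,
    "results-section-bands": RESULTS_SECTION_BANDS,
}


def get_band(name: str, table: tuple[BandDefinition, ...] = CANONICAL_BANDS) -> BandDefinition:
    for b in table:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in table]}")


@dataclass
class SpectralSummary:
    """Per-channel PSD with optional band aggregates.

    ``psd`` is in microvolts^2 / Hz on the ``freqs`` grid. After
    :func:`band_aggregate`, ``band_power`` (microvolts^2) and
    ``relative_power`` (unitless, rows summing to 1 over the defined bands)
    are filled in; ``region_means`` maps region name -> per-band mean power
    over that region's electrodes.
    """

    freqs: np.ndarray
    psd: np.ndarray                      # channels x freqs
    channel_labels: list[str]
    bands: tuple[BandDefinition, ...] = ()
    band_power: np.ndarray | None = None         # channels x bands
    relative_power: np.ndarray | None = None
    relative_defined: np.ndarray | None = None   # per-channel flag
    region_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if (self.psd < -1e-12).any():
            raise ValueError("PSD must be non-negative")

    def band_table(self) -> pd.DataFrame:
        """Tidy per-electrode band powers."""
        if self.band_power is None:
            raise ValueError("run band_aggregate first")
        rows = []
        for i, lab in enumerate(self.channel_labels):
            for j, b in enumerate(self.bands):
                rows.append({
                    "electrode": lab, "band": b.name,
                    "power": self.band_power[i, j],
                    "rel_power": (self.relative_power[i, j]
                                  if self.relative_defined[i] else np.nan),
                })
        return pd.DataFrame(rows)


def welch_psd(ep, seg_sec: float = 2.0, overlap: float = 0.5,
              condition: dict[str, str] | None = None) -> SpectralSummary:
    """Welch PSD per channel, averaged over retained epochs.

    Parameters
    ----------
    ep : EpochSet
        Baseline-corrected epochs.
    seg_sec : float
        Hann segment length in seconds (must give >= 64 samples).
    overlap : float
        Fractional segment overlap in [0, 1).
    condition : dict, optional
        Restrict the average to trials matching ``channel_type`` /
        ``music_type``.
    """
    nperseg = int(round(seg_sec * ep.fs))
    if nperseg < 64:
        raise ValueError(f"segment of {seg_sec}s at fs={ep.fs} gives "
                         f"{nperseg} < 64 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    idx = ep.retained(condition)
    if len(idx) == 0:
        raise ValueError(f"no retained epochs for condition {condition}")
    noverlap = int(round(overlap * nperseg))
    freqs, psd = signal.welch(ep.epochs[idx], fs=ep.fs, window="hann",
                              nperseg=min(nperseg, ep.epochs.shape[-1]),
                              noverlap=noverlap, detrend="constant",
                              scaling="density", axis=-1)
    return SpectralSummary(freqs, psd.mean(axis=0),
                           list(ep.channel_labels))


def band_aggregate(summary: SpectralSummary,
                   bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                   regions: dict[str, tuple[str, ...]] | None = None,
                   integration: str = "rect") -> SpectralSummary:
    """Fill in band powers, relative powers, and region means.

    Band power integrates the PSD over the band's bins with half-open
    ownership (a bin exactly at ``hi`` belongs to the next band). The
    default ``integration="rect"`` sums bin-width x PSD, which makes
    contiguous bands tile the frequency axis exactly — the discrete
    Parseval property of the Welch estimate carries over to the band sum.
    ``integration="trapezoid"`` integrates the PSD as a piecewise-linear
    function of frequency within each band instead (slightly down-weights
    the band-edge bins, so band sums no longer tile exactly).

    Relative power divides by the sum over the given bands; channels with
    zero total power are flagged undefined instead of propagating NaN.
    """
    freqs = summary.freqs
    for b in bands:
        mask = b.bin_mask(freqs)
        if mask.sum() < 2:
            raise ValueError(
                f"band {b.name} [{b.lo}, {b.hi}) covers {int(mask.sum())} "
                f"bins of the PSD grid (df={freqs[1] - freqs[0]:.3g} Hz)")
    n_ch = summary.psd.shape[0]
    power = np.zeros((n_ch, len(bands)))
    df = float(np.diff(freqs).mean())
    for j, b in enumerate(bands):
        mask = b.bin_mask(freqs)
        if integration == "rect":
            power[:, j] = summary.psd[:, mask].sum(axis=1) * df
        elif integration == "trapezoid":
            power[:, j] = np.trapezoid(summary.psd[:, mask], freqs[mask], axis=1)
        else:
            raise ValueError(f"unknown integration rule {integration!r}")
    total = power.sum(axis=1)
    defined = total > 0
    rel = np.zeros_like(power)
    rel[defined] = power[defined] / total[defined, None]

    regions = REGIONS if regions is None else regions
    region_means: dict[str, dict[str, float]] = {}
    for rname, members in regions.items():
        rows = [i for i, lab in enumerate(summary.channel_labels)
                if lab in members]
        if rows:
            region_means[rname] = {
                b.name: float(power[rows, j].mean())
                for j, b in enumerate(bands)}
    return SpectralSummary(freqs, summary.psd, summary.channel_labels,
                           bands=tuple(bands), band_power=power,
                           relative_power=rel, relative_defined=defined,
                           region_means=region_means)
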