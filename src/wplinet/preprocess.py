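"""Continuous-recording containers and the EEG cleaning chain.

The chain implemented here takes a raw multichannel recording to clean,
baseline-corrected, amplitude-screened epochs:

    band-pass -> notch -> bad-channel interpolation -> epoching + baseline
    -> ocular ICA -> linked-mastoid re-reference -> +/- amplitude rejection

All filters are zero-phase (forward-backward Butterworth). No operation
mutates its input; every output carries a provenance ``history`` entry so the
applied order is auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import MASTOID_SYNONYMS, channel_positions


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names (extended 10-20 for scalp channels).
    eog_labels : tuple of str
        Subset of ``channel_labels`` flagged as electro-oculogram channels;
        excluded from scalp-level operations (ICA decomposition, rejection).
    reference : str
        One of ``{"average", "linked-mastoid", "other"}``.
    history : list of str
        Provenance log; each operation appends one entry.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    eog_labels: tuple[str, ...] = ()
    reference: str = "average"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        missing = set(self.eog_labels) - set(self.channel_labels)
        if missing:
            raise ValueError(f"EOG labels not in channel list: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def scalp_indices(self) -> np.ndarray:
        """Indices of non-EOG channels."""
        return np.array([i for i, lab in enumerate(self.channel_labels)
                         if lab not in self.eog_labels], dtype=int)

    def index_of(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channel_labels}"
            ) from None

    def copy_with(self, data: np.ndarray, entry: str, **changes) -> "Recording":
        """New Recording with replaced data and a provenance entry appended."""
        return dataclasses.replace(
            self, data=data, history=[*self.history, entry], **changes
        )


@dataclass
class EpochSet:
    """Stimulus-locked, equal-length, baseline-corrected segments.

    ``epochs`` has shape (n_trials, n_channels, n_samples); ``labels`` carries
    one ``(channel_type, music_type)`` pair per trial. Trials flagged in
    ``rejected_mask`` are excluded from every downstream average.
    """

    epochs: np.ndarray
    fs: float
    labels: list[tuple[str, str]]
    channel_labels: list[str]
    eog_labels: tuple[str, ...] = ()
    baseline_window: tuple[float, float] | None = None
    rejected_mask: np.ndarray | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.epochs.shape[0], dtype=bool)
        self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def retained(self, condition: dict[str, str] | None = None) -> np.ndarray:
        """Indices of non-rejected trials, optionally filtered by condition.

        ``condition`` may constrain ``channel_type`` and/or ``music_type``.
        """
        idx = []
        for i, (ch_type, mu_type) in enumerate(self.labels):
            if self.rejected_mask[i]:
                continue
            if condition:
                if condition.get("channel_type", ch_type) != ch_type:
                    continue
                if condition.get("music_type", mu_type) != mu_type:
                    continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.channel_labels)
                         if lab not in self.eog_labels], dtype=int)

    def copy_with(self, entry: str, **changes) -> "EpochSet":
        return dataclasses.replace(self, history=[*self.history, entry], **changes)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _check_band(lo: float, hi: float, fs: float) -> None:
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= fs / 2:
        raise ValueError(f"high edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")


def bandpass(rec: Recording, lo: float = 0.1, hi: float = 50.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass.

    High-pass and low-pass are applied as separate second-order-section
    cascades (numerically stabler than one very wide band-pass when the low
    edge sits near DC). Forward-backward application doubles the effective
    order and cancels phase distortion.
    """
    _check_band(lo, hi, rec.fs)
    sos_hp = signal.butter(order, lo, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(order, hi, btype="lowpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    out = signal.sosfiltfilt(sos_lp, out, axis=1)
    return rec.copy_with(out, f"bandpass({lo}-{hi} Hz, butter{order}, zero-phase)")


def notch(rec: Recording, lo: float = 49.0, hi: float = 51.0,
          order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop (line-noise notch)."""
    _check_band(lo, hi, rec.fs)
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(out, f"notch({lo}-{hi} Hz, butter{order}, zero-phase)")


# ---------------------------------------------------------------------------
# bad-channel interpolation
# ---------------------------------------------------------------------------

def interpolate_bad(rec: Recording, bad: list[str],
                    method: str = "spline") -> Recording:
    """Replace bad channels by estimates from the good scalp channels.

    ``method="spline"`` uses spherical-spline interpolation on the standard
    extended 10-20 electrode positions; ``method="distance"`` uses
    inverse-distance weighting, which also serves as the fallback when a
    channel has no known standard position. Good channels are never touched.
    """
    if not bad:
        return rec.copy_with(rec.data.copy(), "interpolate_bad([])")
    bad = list(bad)
    for lab in bad:
        rec.index_of(lab)  # raises with channel list on typo
    scalp = [rec.channel_labels[i] for i in rec.scalp_indices()]
    good = [lab for lab in scalp if lab not in bad]
    if len(good) < 4:
        raise ValueError("need at least 4 good scalp channels to interpolate")

    pos = channel_positions(tuple(rec.channel_labels))
    bad_idx = np.array([rec.index_of(b) for b in bad])
    good_idx = np.array([rec.index_of(g) for g in good])
    have_pos = not np.isnan(pos[np.concatenate([bad_idx, good_idx])]).any()

    out = rec.data.copy()
    if method == "spline" and have_pos:
        out[bad_idx] = _spline_interpolate(rec, bad, good)
    else:
        # inverse-distance fallback; without positions, plain mean of goods
        for bi in bad_idx:
            if have_pos:
                d = np.linalg.norm(pos[good_idx] - pos[bi], axis=1)
                w = 1.0 / np.maximum(d, 1e-6)
            else:
                w = np.ones(len(good_idx))
            out[bi] = (w[:, None] * rec.data[good_idx]).sum(0) / w.sum()
    return rec.copy_with(out, f"interpolate_bad({bad}, method={method})")


def _spline_interpolate(rec: Recording, bad: list[str],
                        good: list[str]) -> np.ndarray:
    """Spherical-spline estimates for bad channels (via mne's implementation)."""
    import warnings

    import mne

    labels = good + bad
    info = mne.create_info(labels, rec.fs, ch_types="eeg", verbose="error")
    data_v = np.array([rec.data[rec.index_of(lab)] for lab in labels]) * 1e-6
    raw = mne.io.RawArray(data_v, info, verbose="error")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        raw.set_montage("standard_1020", verbose="error")
    raw.info["bads"] = list(bad)
    raw.interpolate_bads(reset_bads=True, verbose="error")
    rebuilt = raw.get_data() * 1e6
    return np.array([rebuilt[labels.index(b)] for b in bad])


# ---------------------------------------------------------------------------
# ocular ICA
# ---------------------------------------------------------------------------

def remove_ocular_ica(rec_or_ep, threshold: float = 0.8, n_components: int | None = None,
                      random_state: int = 0):
    """Remove independent components that track the EOG channels.

    Works on a continuous :class:`Recording` or, matching pipelines that
    decompose after segmentation, on an :class:`EpochSet` (trials are
    concatenated for the decomposition and the cleaned data re-split).

    A FastICA decomposition is run on the scalp channels only; any component
    whose absolute Pearson correlation with any EOG channel reaches
    ``threshold`` is zeroed before back-projection. Returns
    ``(cleaned, report)`` where ``report`` lists removed components and their
    EOG correlations.
    """
    if isinstance(rec_or_ep, EpochSet):
        ep = rec_or_ep
        n_tr, n_ch, n_s = ep.epochs.shape
        flat = ep.epochs.transpose(1, 0, 2).reshape(n_ch, n_tr * n_s)
        rec = Recording(flat, ep.fs, list(ep.channel_labels),
                        eog_labels=ep.eog_labels, history=list(ep.history))
        cleaned, report = remove_ocular_ica(rec, threshold, n_components,
                                            random_state)
        out = cleaned.data.reshape(n_ch, n_tr, n_s).transpose(1, 0, 2)
        return ep.copy_with(
            f"remove_ocular_ica(threshold={threshold}, "
            f"removed={report['removed']})", epochs=out), report

    rec = rec_or_ep
    if not rec.eog_labels:
        raise ValueError(
            "no EOG channel present: skip ocular ICA explicitly or supply a "
            "blink regressor channel"
        )
    if rec.duration < 60:
        raise ValueError("need at least 60 s of data for a stable decomposition")

    from sklearn.decomposition import FastICA

    scalp = rec.scalp_indices()
    eog_idx = [rec.index_of(lab) for lab in rec.eog_labels]
    X = rec.data[scalp].T  # samples x channels
    n_comp = n_components or len(scalp)
    ica = FastICA(n_components=n_comp, whiten="unit-variance",
                  random_state=random_state, max_iter=1000, tol=1e-4)
    sources = ica.fit_transform(X)  # samples x components

    eog = rec.data[eog_idx]
    corr = np.zeros((sources.shape[1], len(eog_idx)))
    for j in range(sources.shape[1]):
        for k in range(len(eog_idx)):
            corr[j, k] = _pearson(sources[:, j], eog[k])
    removed = np.where((np.abs(corr) >= threshold).any(axis=1))[0]

    sources_clean = sources.copy()
    sources_clean[:, removed] = 0.0
    X_clean = ica.inverse_transform(sources_clean)

    out = rec.data.copy()
    out[scalp] = X_clean.T
    report = {
        "removed": removed.tolist(),
        "n_components": int(sources.shape[1]),
        "eog_correlations": {int(j): corr[j].tolist() for j in removed},
        "threshold": threshold,
    }
    entry = f"remove_ocular_ica(threshold={threshold}, removed={removed.tolist()})"
    return rec.copy_with(out, entry), report


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# re-referencing
# ---------------------------------------------------------------------------

def rereference_linked_mastoids(rec_or_ep, mastoid_labels: tuple[str, str] = ("TP9", "TP10")):
    """Re-express every channel relative to the mean of the two mastoids.

    Accepts M1/M2 as synonyms for TP9/TP10. Works on a continuous
    :class:`Recording` or an :class:`EpochSet`.
    """
    labels = (rec_or_ep.channel_labels if isinstance(rec_or_ep, Recording)
              else rec_or_ep.channel_labels)

    resolved = []
    for lab in mastoid_labels:
        if lab in labels:
            resolved.append(lab)
        elif MASTOID_SYNONYMS.get(lab) in labels:
            resolved.append(MASTOID_SYNONYMS[lab])
        else:
            raise ValueError(
                f"mastoid channel {lab!r} not found; channels: {labels}")
    idx = [labels.index(lab) for lab in resolved]
    entry = f"rereference_linked_mastoids({resolved})"

    if isinstance(rec_or_ep, Recording):
        ref = rec_or_ep.data[idx].mean(axis=0, keepdims=True)
        return rec_or_ep.copy_with(rec_or_ep.data - ref, entry,
                                   reference="linked-mastoid")
    ep = rec_or_ep
    ref = ep.epochs[:, idx, :].mean(axis=1, keepdims=True)
    return ep.copy_with(entry, epochs=ep.epochs - ref)


# ---------------------------------------------------------------------------
# epoching, baseline, rejection
# ---------------------------------------------------------------------------

def epoch_and_baseline(rec: Recording, events, t0: float = 0.0,
                       t1: float = 30.0,
                       baseline: tuple[float, float] = (-5.0, 0.0)) -> EpochSet:
    """Cut stimulus-locked epochs and subtract each channel's baseline mean.

    ``events`` is an :class:`~wplinet.simulate.EventList`-like object with
    ``onsets`` (0-based sample indices) and ``labels``. The epoch spans
    ``[onset + t0, onset + t1)``; the baseline window is relative to onset
    (default the 5 s pre-stimulus fixation). Trials whose epoch or baseline
    window falls outside the recording are dropped with a logged warning
    entry rather than failing the whole set.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    n_samp = int(round((t1 - t0) * rec.fs))
    b0, b1 = baseline
    kept_epochs, kept_labels, dropped = [], [], []
    for onset, label in zip(np.asarray(events.onsets, dtype=int), events.labels):
        s0 = onset + int(round(t0 * rec.fs))
        s1 = s0 + n_samp
        p0 = onset + int(round(b0 * rec.fs))
        p1 = onset + int(round(b1 * rec.fs))
        if s0 < 0 or s1 > rec.n_samples or p0 < 0 or p1 > rec.n_samples or p1 <= p0:
            dropped.append(int(onset))
            continue
        seg = rec.data[:, s0:s1]
        base = rec.data[:, p0:p1].mean(axis=1, keepdims=True)
        kept_epochs.append(seg - base)
        kept_labels.append(tuple(label))
    if not kept_epochs:
        raise ValueError("no epoch fits inside the recording")
    entry = (f"epoch_and_baseline(t0={t0}, t1={t1}, baseline={baseline}, "
             f"dropped_onsets={dropped})")
    return EpochSet(np.stack(kept_epochs), rec.fs, kept_labels,
                    list(rec.channel_labels), eog_labels=rec.eog_labels,
                    baseline_window=baseline,
                    history=[*rec.history, entry])


def reject_amplitude(ep: EpochSet, threshold: float = 75.0) -> EpochSet:
    """Flag trials whose scalp amplitude exceeds +/- ``threshold`` microvolts.

    "Exceeding" is strict: a peak exactly at the threshold is kept. EOG
    channels are ignored. Raises if the screen would reject every trial.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    scalp = ep.scalp_indices()
    peaks = np.abs(ep.epochs[:, scalp, :]).max(axis=(1, 2))
    mask = ep.rejected_mask | (peaks > threshold)
    if mask.all():
        raise ValueError(
            f"amplitude screen at +/-{threshold} uV rejected all "
            f"{ep.n_trials} trials")
    return ep.copy_with(
        f"reject_amplitude(threshold={threshold}, rejected={int(mask.sum())})",
        rejected_mask=mask)
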