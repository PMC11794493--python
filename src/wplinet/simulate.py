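"""Synthetic EEG and behavioral-rating generator with planted ground truth.

The generator emulates the study conditions the analysis assumes: a
within-subject 3 (sensory channel: visual, auditory, audiovisual) x
2 (music type: nostalgic, non-nostalgic) passive-stimulation design recorded
on a 64-channel extended 10-20 montage.

Neural side
-----------
Each trial's signal is pink (1/f) background noise plus, per frequency band
with nonzero coupling, a shared narrowband source mixed into a designated
channel subset. Each coupled channel receives the source shifted by a phase
offset drawn once per subject (magnitudes in [pi/4, pi/2], alternating sign
across the subset), so any pair of coupled channels has a fixed nonzero phase
lag of consistent sign — exactly the structure the weighted phase lag index
is designed to detect, with strength controlled by the mixing gain
``g in [0, 1]``. Offsets are per-subject, not per-trial, so condition
contrasts stay within-subject. Artifacts (stereotyped frontal blinks mirrored
on VEOG/HEOG, 50 Hz line noise, rare high-amplitude spikes) are injected on
top so the cleaning chain is exercised with known ground truth.

Behavioral side
---------------
Per-trial 9-point Likert ratings (state nostalgia plus the pleasure, arousal,
dominance affective dimensions) are drawn as cell-mean + Gaussian noise,
truncated and rounded to the 1-9 grid. Default cell means and SDs follow the
descriptive statistics of the study the design emulates.

Everything is deterministic given ``(seed, subject_id)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .montage import CHANNELS_64, EOG_CHANNELS, channel_positions
from .preprocess import Recording
from .spectral import CANONICAL_BANDS, BandDefinition

CHANNEL_TYPES = ("visual", "auditory", "audiovisual")
MUSIC_TYPES = ("nostalgic", "non-nostalgic")
SCALES = ("nostalgia", "pleasure", "arousal", "dominance")

#: Default per-cell behavioral means, keyed (scale, channel_type, music_type),
#: calibrated to the study's descriptive tables (state-nostalgia cells to the
#: simple-effect means; affective scales to the descriptive table).
DEFAULT_BEHAVIOR_MEANS: dict[tuple[str, str, str], float] = {
    ("nostalgia", "visual", "nostalgic"): 7.35,
    ("nostalgia", "auditory", "nostalgic"): 7.65,
    ("nostalgia", "audiovisual", "nostalgic"): 7.79,
    ("nostalgia", "visual", "non-nostalgic"): 3.29,
    ("nostalgia", "auditory", "non-nostalgic"): 3.86,
    ("nostalgia", "audiovisual", "non-nostalgic"): 3.80,
    ("pleasure", "auditory", "nostalgic"): 7.132,
    ("pleasure", "visual", "nostalgic"): 6.991,
    ("pleasure", "audiovisual", "nostalgic"): 7.192,
    ("pleasure", "auditory", "non-nostalgic"): 4.916,
    ("pleasure", "visual", "non-nostalgic"): 4.57,
    ("pleasure", "audiovisual", "non-nostalgic"): 5.209,
    ("arousal", "auditory", "nostalgic"): 7.114,
    ("arousal", "visual", "nostalgic"): 6.877,
    ("arousal", "audiovisual", "nostalgic"): 7.209,
    ("arousal", "auditory", "non-nostalgic"): 4.937,
    ("arousal", "visual", "non-nostalgic"): 4.507,
    ("arousal", "audiovisual", "non-nostalgic"): 4.798,
    ("dominance", "auditory", "nostalgic"): 7.13,
    ("dominance", "visual", "nostalgic"): 6.84,
    ("dominance", "audiovisual", "nostalgic"): 7.344,
    ("dominance", "auditory", "non-nostalgic"): 6.402,
    ("dominance", "visual", "non-nostalgic"): 6.0,
    ("dominance", "audiovisual", "non-nostalgic"): 6.486,
}

DEFAULT_BEHAVIOR_SD: dict[tuple[str, str, str], float] = {
    ("nostalgia", "visual", "nostalgic"): 0.95,
    ("nostalgia", "auditory", "nostalgic"): 0.88,
    ("nostalgia", "audiovisual", "nostalgic"): 0.65,
    ("nostalgia", "visual", "non-nostalgic"): 1.57,
    ("nostalgia", "auditory", "non-nostalgic"): 1.81,
    ("nostalgia", "audiovisual", "non-nostalgic"): 1.80,
    ("pleasure", "auditory", "nostalgic"): 1.002,
    ("pleasure", "visual", "nostalgic"): 0.84,
    ("pleasure", "audiovisual", "nostalgic"): 0.986,
    ("pleasure", "auditory", "non-nostalgic"): 0.86,
    ("pleasure", "visual", "non-nostalgic"): 0.928,
    ("pleasure", "audiovisual", "non-nostalgic"): 0.648,
    ("arousal", "auditory", "nostalgic"): 0.94,
    ("arousal", "visual", "nostalgic"): 1.115,
    ("arousal", "audiovisual", "nostalgic"): 1.063,
    ("arousal", "auditory", "non-nostalgic"): 1.069,
    ("arousal", "visual", "non-nostalgic"): 0.984,
    ("arousal", "audiovisual", "non-nostalgic"): 1.183,
    ("dominance", "auditory", "nostalgic"): 1.308,
    ("dominance", "visual", "nostalgic"): 1.491,
    ("dominance", "audiovisual", "nostalgic"): 1.301,
    ("dominance", "auditory", "non-nostalgic"): 1.515,
    ("dominance", "visual", "non-nostalgic"): 1.809,
    ("dominance", "audiovisual", "non-nostalgic"): 1.616,
}

#: Default per-band coupling gains by music type: the nostalgic condition has
#: elevated alpha- and gamma-band phase coupling; theta and beta are
#: condition-equal (null bands); delta carries no planted source.
DEFAULT_BAND_COUPLING: dict[str, dict[str, float]] = {
    "delta": {"nostalgic": 0.0, "non-nostalgic": 0.0},
    "theta": {"nostalgic": 0.3, "non-nostalgic": 0.3},
    "alpha": {"nostalgic": 0.6, "non-nostalgic": 0.3},
    "beta": {"nostalgic": 0.3, "non-nostalgic": 0.3},
    "gamma": {"nostalgic": 0.6, "non-nostalgic": 0.3},
}


@dataclass
class EventList:
    """Trial onsets (0-based sample indices) with condition labels."""

    onsets: np.ndarray
    labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if len(self.onsets) != len(self.labels):
            raise ValueError("one label per onset required")
        if len(self.onsets) > 1 and not (np.diff(self.onsets) > 0).all():
            raise ValueError("onsets must be strictly increasing")
        for ch, mu in self.labels:
            if ch not in CHANNEL_TYPES or mu not in MUSIC_TYPES:
                raise ValueError(f"unknown condition label ({ch}, {mu})")


@dataclass
class ArtifactSpec:
    """Rates and amplitudes of injected artifacts."""

    blink_rate_per_min: float = 0.0
    line_noise_uv: float = 0.0      # 50 Hz amplitude
    spike_prob_per_epoch: float = 0.0
    blink_amp_uv: float = 200.0
    spike_amp_uv: float = 150.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the emulated study's conditions: 64 channels at
    500 Hz, 30 s trials, 5 trials per cell of the 3 x 2 design, 9-point
    Likert ratings with the published cell means and SDs.
    """

    n_subjects: int = 36
    n_channels: int = 64
    fs: float = 500.0
    trial_sec: float = 30.0
    n_trials_per_cell: int = 5
    band_coupling: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(c) for b, c in DEFAULT_BAND_COUPLING.items()})
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    n_coupled: int = 16
    noise_sd: float = 10.0          # microvolts, pink background
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    behavior_means: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_MEANS))
    behavior_sd: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_SD))
    gap_sec: float = 8.0            # 5 s fixation + 3 s blank between trials
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_cell <= 0:
            raise ValueError("subject and trial counts must be positive")
        if self.trial_sec <= 0:
            raise ValueError("trial duration must be positive")
        band_map = {b.name: b for b in self.bands}
        for name, cond_map in self.band_coupling.items():
            if name not in band_map:
                raise ValueError(f"coupling refers to unknown band {name!r}")
            for cond, g in cond_map.items():
                if cond not in MUSIC_TYPES:
                    raise ValueError(f"unknown music type {cond!r}")
                if not 0 <= g <= 1:
                    raise ValueError(f"coupling g={g} outside [0, 1]")
        top = max(b.hi for b in self.bands)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for band edge {top} Hz")
        for key, m in self.behavior_means.items():
            if not 1 <= m <= 9:
                raise ValueError(f"behavior mean {m} for {key} outside [1, 9]")
        if not 2 <= self.n_coupled <= self.n_channels:
            raise ValueError("n_coupled must be in [2, n_channels]")

    @property
    def channel_labels(self) -> list[str]:
        if self.n_channels == 64:
            return list(CHANNELS_64)
        return [CHANNELS_64[i] for i in range(self.n_channels)]

    @property
    def coupled_indices(self) -> np.ndarray:
        """Evenly spread subset of scalp channels carrying the planted source."""
        return np.linspace(0, self.n_channels - 1, self.n_coupled).round().astype(int)

    def trials_per_subject(self) -> int:
        return self.n_trials_per_cell * len(CHANNEL_TYPES) * len(MUSIC_TYPES)

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                fs: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _narrowband_source(rng: np.random.Generator, n: int, fs: float,
                       band: BandDefinition) -> np.ndarray:
    """Unit-variance band-limited Gaussian source as an analytic signal."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    mask = (freqs >= band.lo) & (freqs < band.hi)
    spec = np.zeros(len(freqs), dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n=n)
    x /= max(x.std(), 1e-12)
    return signal.hilbert(x)


def _blink_template(fs: float, width_sec: float = 0.35) -> np.ndarray:
    """Stereotyped unit-peak blink waveform (squared half-sine bump)."""
    n = int(round(width_sec * fs))
    t = np.linspace(0, np.pi, n)
    return np.sin(t) ** 2


def _blink_topography(labels: list[str]) -> np.ndarray:
    """Per-channel blink gain, decaying with distance from Fp1/Fp2."""
    pos = channel_positions(tuple(labels))
    out = np.zeros(len(labels))
    try:
        fp = np.stack([pos[labels.index("Fp1")], pos[labels.index("Fp2")]])
    except ValueError:
        fp = None
    for i, lab in enumerate(labels):
        if np.isnan(pos[i]).any() or fp is None or np.isnan(fp).any():
            out[i] = 0.0
            continue
        d = np.linalg.norm(fp - pos[i], axis=1).min()
        out[i] = np.exp(-d / 0.04)  # ~4 cm decay scale
    return out


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def _subject_rng(config: SimulationConfig, subject_id: int,
                 stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, subject_id, stream]))


def _subject_phase_offsets(config: SimulationConfig,
                           subject_id: int) -> dict[str, np.ndarray]:
    """Per-band per-coupled-channel phase offsets, fixed for a subject.

    Magnitudes are uniform in [pi/4, pi/2]; the sign alternates across the
    coupled subset so most channel pairs carry a sizable, sign-consistent
    phase lag.
    """
    rng = _subject_rng(config, subject_id, stream=1)
    offsets = {}
    for band in config.bands:
        mag = rng.uniform(np.pi / 4, np.pi / 2, size=config.n_coupled)
        sign = np.where(np.arange(config.n_coupled) % 2 == 0, 1.0, -1.0)
        offsets[band.name] = mag * sign
    return offsets


def make_trial_order(config: SimulationConfig, subject_id: int) -> list[tuple[str, str]]:
    """Block order visual -> auditory -> audiovisual; music types shuffled
    within each block (per-subject randomization, deterministic in seed)."""
    rng = _subject_rng(config, subject_id, stream=2)
    order = []
    for ch_type in CHANNEL_TYPES:
        block = ([(ch_type, "nostalgic")] * config.n_trials_per_cell
                 + [(ch_type, "non-nostalgic")] * config.n_trials_per_cell)
        rng.shuffle(block)
        order.extend([tuple(x) for x in block])
    return order


def make_subject_recording(config: SimulationConfig,
                           subject_id: int) -> tuple[Recording, EventList]:
    """Continuous recording plus event list for one subject.

    The recording covers all trials in block order with ``gap_sec`` of
    noise-only inter-trial interval (fixation + blank) before each trial and
    after the last. Deterministic given ``(config.seed, subject_id)``.
    """
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError(f"subject_id {subject_id} outside [0, {config.n_subjects})")
    fs = config.fs
    n_trial = int(round(config.trial_sec * fs))
    n_gap = int(round(config.gap_sec * fs))
    order = make_trial_order(config, subject_id)
    n_total = n_gap + len(order) * (n_trial + n_gap)

    labels = config.channel_labels + list(EOG_CHANNELS)
    n_scalp = config.n_channels
    rng = _subject_rng(config, subject_id, stream=0)
    offsets = _subject_phase_offsets(config, subject_id)
    coupled = config.coupled_indices

    data = np.empty((len(labels), n_total))
    data[:n_scalp] = config.noise_sd * _pink_noise(rng, (n_scalp, n_total), fs)
    data[n_scalp:] = 5.0 * _pink_noise(rng, (len(EOG_CHANNELS), n_total), fs)

    onsets, event_labels = [], []
    cursor = n_gap
    for ch_type, mu_type in order:
        for band in config.bands:
            g = config.band_coupling.get(band.name, {}).get(mu_type, 0.0)
            if g == 0.0:
                continue
            z = _narrowband_source(rng, n_trial, fs, band)
            contrib = np.real(z[None, :]
                              * np.exp(1j * offsets[band.name])[:, None])
            data[coupled, cursor:cursor + n_trial] += g * config.noise_sd * contrib
        onsets.append(cursor)
        event_labels.append((ch_type, mu_type))
        cursor += n_trial + n_gap

    _inject_artifacts(data, labels, n_scalp, fs, config, rng,
                      onsets, n_trial)

    rec = Recording(data, fs, labels, eog_labels=EOG_CHANNELS,
                    reference="average",
                    history=[f"simulated(subject={subject_id}, seed={config.seed})"])
    return rec, EventList(np.array(onsets), event_labels)


def _inject_artifacts(data, labels, n_scalp, fs, config, rng, onsets, n_trial):
    spec = config.artifact_spec
    n_total = data.shape[1]
    if spec.blink_rate_per_min > 0:
        template = _blink_template(fs)
        topo = _blink_topography(labels[:n_scalp])
        n_blinks = rng.poisson(spec.blink_rate_per_min * n_total / fs / 60.0)
        veog = labels.index("VEOG") if "VEOG" in labels else None
        heog = labels.index("HEOG") if "HEOG" in labels else None
        for _ in range(n_blinks):
            start = rng.integers(0, n_total - len(template))
            seg = slice(start, start + len(template))
            data[:n_scalp, seg] += spec.blink_amp_uv * topo[:, None] * template
            if veog is not None:
                data[veog, seg] += spec.blink_amp_uv * template
            if heog is not None:
                data[heog, seg] += 0.3 * spec.blink_amp_uv * template
    if spec.line_noise_uv > 0:
        t = np.arange(n_total) / fs
        phase = rng.uniform(0, 2 * np.pi)
        data[:n_scalp] += spec.line_noise_uv * np.sin(2 * np.pi * 50.0 * t + phase)
    if spec.spike_prob_per_epoch > 0:
        for onset in onsets:
            if rng.uniform() < spec.spike_prob_per_epoch:
                ch = rng.integers(0, n_scalp)
                pos = onset + rng.integers(0, n_trial)
                data[ch, pos] += spec.spike_amp_uv * rng.choice([-1.0, 1.0])


def blink_ground_truth(config: SimulationConfig, subject_id: int,
                       n_total: int) -> np.ndarray:
    """Re-derive the injected blink time course for a subject's recording.

    Provided for artifact-removal validation: replays the generator's random
    stream to reconstruct the blink component exactly.
    """
    # Replaying requires identical draw order; easiest is to regenerate the
    # recording with and without blinks and difference the VEOG channel.
    with_blinks, _ = make_subject_recording(config, subject_id)
    quiet_cfg = config.with_(artifact_spec=replace(config.artifact_spec,
                                                   blink_rate_per_min=0.0))
    without, _ = make_subject_recording(quiet_cfg, subject_id)
    veog = with_blinks.index_of("VEOG")
    return with_blinks.data[veog] - without.data[veog]


def generate_behavior(config: SimulationConfig) -> pd.DataFrame:
    """Per-trial ratings table for all subjects.

    Columns: subject, trial, channel_type, music_type, nostalgia, pleasure,
    arousal, dominance, rt_ms. Ratings are cell-mean + Gaussian(behavior_sd)
    noise, truncated and rounded to the 1-9 Likert grid; reaction times are
    lognormal filler (recorded in the emulated study but never analyzed).
    Deterministic given ``config.seed``.
    """
    for scale in SCALES:
        for ch in CHANNEL_TYPES:
            for mu in MUSIC_TYPES:
                if (scale, ch, mu) not in config.behavior_means:
                    raise ValueError(f"behavior mean missing for {(scale, ch, mu)}")
    rows = []
    for subject in range(config.n_subjects):
        rng = _subject_rng(config, subject, stream=3)
        order = make_trial_order(config, subject)
        for trial, (ch_type, mu_type) in enumerate(order):
            row = {"subject": subject, "trial": trial,
                   "channel_type": ch_type, "music_type": mu_type}
            for scale in SCALES:
                m = config.behavior_means[(scale, ch_type, mu_type)]
                sd = config.behavior_sd.get((scale, ch_type, mu_type), 0.0)
                v = m + (sd * rng.standard_normal() if sd > 0 else 0.0)
                row[scale] = int(np.clip(np.round(v), 1, 9))
            row["rt_ms"] = float(np.round(rng.lognormal(7.0, 0.3), 1))
            rows.append(row)
    return pd.DataFrame(rows)
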