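"""Reading and writing standard EEG formats and tidy result tables.

Recordings are written as BrainVision triplets (.vhdr/.vmrk/.eeg) in the
IEEE_FLOAT_32 multiplexed dialect (stated in the header) and read back —
from BrainVision or EDF+ — through mne, converting to microvolts and
parsing trial markers into an event list. Marker files use the format's
native 1-based sample convention on disk; in memory everything is 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import Recording
from .simulate import CHANNEL_TYPES, MUSIC_TYPES, EventList

#: Stimulus-code mapping for the 3 x 2 design, S1..S6.
CONDITION_CODES: dict[tuple[str, str], int] = {
    (ch, mu): 1 + i * len(MUSIC_TYPES) + j
    for i, ch in enumerate(CHANNEL_TYPES)
    for j, mu in enumerate(MUSIC_TYPES)
}
CODE_CONDITIONS = {v: k for k, v in CONDITION_CODES.items()}


def write_brainvision(rec: Recording, events: EventList | None,
                      path: str | Path) -> Path:
    """Write a recording (and its markers) as a BrainVision triplet.

    ``path`` is the .vhdr path (or basename); the .vmrk and .eeg siblings
    are placed next to it. Data are stored as IEEE float32, multiplexed,
    in microvolts with unit resolution. Returns the .vhdr path.
    """
    path = Path(path)
    if path.suffix != ".vhdr":
        path = path.with_suffix(".vhdr")
    base = path.stem
    vmrk = path.with_suffix(".vmrk")
    eeg = path.with_suffix(".eeg")

    sampling_interval_us = 1e6 / rec.fs
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "; Written by wplinet",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        f"MarkerFile={base}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, 1):
        lines.append(f"Ch{i}={lab},,1,µV")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={base}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    if events is not None:
        for k, (onset, label) in enumerate(zip(events.onsets, events.labels), 2):
            code = CONDITION_CODES[tuple(label)]
            # BrainVision marker positions are 1-based
            mlines.append(f"Mk{k}=Stimulus,S{code:>3},{int(onset) + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return path


def read_recording(path: str | Path,
                   eog_labels: tuple[str, ...] = ("VEOG", "HEOG")):
    """Read a BrainVision (.vhdr) or EDF+ (.edf) recording.

    Returns ``(Recording, EventList)``; the event list is empty when the
    file carries no recognized stimulus markers. Data are converted to
    microvolts and marker positions to 0-based sample indices.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".vhdr":
        if not path.with_suffix(".eeg").exists():
            raise FileNotFoundError(
                f"missing binary data file {path.with_suffix('.eeg')}")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix!r} "
                         "(expected .vhdr or .edf)")

    data_uv = raw.get_data() * 1e6
    labels = list(raw.ch_names)
    eog = tuple(lab for lab in eog_labels if lab in labels)
    rec = Recording(data_uv, float(raw.info["sfreq"]), labels,
                    eog_labels=eog, reference="average",
                    history=[f"read_recording({path.name})"])

    onsets, cond_labels = [], []
    for ann in raw.annotations:
        desc = ann["description"]
        code = _parse_stimulus_code(desc)
        if code is None or code not in CODE_CONDITIONS:
            continue
        onsets.append(int(round(ann["onset"] * rec.fs)))
        cond_labels.append(CODE_CONDITIONS[code])
    events = EventList(np.array(onsets, dtype=int), cond_labels)
    return rec, events


def _parse_stimulus_code(desc: str) -> int | None:
    desc = desc.strip()
    if "/" in desc:  # mne renders BrainVision markers as "Stimulus/S  3"
        desc = desc.split("/", 1)[1]
    if desc.startswith("S"):
        try:
            return int(desc[1:].strip())
        except ValueError:
            return None
    return None


def write_matrix_csv(matrix, path: str | Path) -> Path:
    """Square CSV with channel-label header row/column."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(matrix.W, index=matrix.channel_labels,
                      columns=matrix.channel_labels)
    df.to_csv(path, float_format="%.10g")
    return path


def read_matrix_csv(path: str | Path):
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), list(df.columns)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify)
                    + "\n", encoding="utf-8")
    return path


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON-serializable: {type(v)}")
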