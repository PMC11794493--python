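"""Extended 10-20 montage conventions used throughout the package.

The 64-channel layout mirrors a standard 64-electrode actiCAP arrangement
(extended international 10-20 system). All labels exist in mne's
``standard_1020`` montage, so 3-D positions are available for spherical-spline
interpolation and for distance-based artifact topographies.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Standard 64-channel extended 10-20 labels (actiCAP-64 ordering).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

#: Simulated electro-oculogram channel labels (appended after scalp channels).
EOG_CHANNELS: tuple[str, ...] = ("VEOG", "HEOG")

#: Accepted synonyms for the linked-mastoid reference electrodes.
MASTOID_SYNONYMS: dict[str, str] = {"M1": "TP9", "M2": "TP10"}

#: Scalp regions used for region-mean summaries. The literature names regions
#: without a universal electrode list; this grouping is editable via config.
REGIONS: dict[str, tuple[str, ...]] = {
    "prefrontal": ("Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8"),
    "frontal": ("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
                "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
                "FT8", "FT10"),
    "central": ("C5", "C3", "C1", "Cz", "C2", "C4", "C6"),
    "temporal": ("T7", "T8", "TP9", "TP7", "TP8", "TP10"),
    "parietal": ("CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
                 "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"),
    "occipital": ("PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
                  "O1", "Oz", "O2"),
}


@lru_cache(maxsize=4)
def channel_positions(labels: tuple[str, ...] = CHANNELS_64) -> np.ndarray:
    """3-D electrode positions (meters) from mne's standard_1020 montage.

    Returns an array of shape ``(len(labels), 3)``. Labels without a known
    position get NaN rows (callers fall back to distance-free conventions).
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos_map = montage.get_positions()["ch_pos"]
    out = np.full((len(labels), 3), np.nan)
    for i, lab in enumerate(labels):
        key = lab if lab in pos_map else MASTOID_SYNONYMS.get(lab, lab)
        if key in pos_map:
            out[i] = pos_map[key]
    return out


def region_of(label: str) -> str | None:
    """Region name for an electrode label, or None for EOG/unknown labels."""
    for name, members in REGIONS.items():
        if label in members:
            return name
    return None
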