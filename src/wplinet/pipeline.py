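"""End-to-end orchestration: simulate (or read) -> preprocess -> spectra /
connectivity -> network metrics -> statistics, with a reproducible config
surface and a run manifest.

The manifest records the effective config, a config hash, per-stage
provenance, warnings, and a checksum for every output file, so a run is
fully reconstructible (identical config + seed => identical checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graphnet, io, preprocess, simulate, spectral, stats
from .connectivity import band_wpli, group_connectivity
from .simulate import MUSIC_TYPES, SCALES, SimulationConfig
from .spectral import BAND_TABLES


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable to YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # preprocessing
    l_freq: float = 0.1
    h_freq: float = 50.0
    notch: tuple[float, float] = (49.0, 51.0)
    bad_channels: list[str] = field(default_factory=list)
    run_ica: bool = True
    ica_threshold: float = 0.8
    ica_on_epochs: bool = True      # decompose after epoching (analysis order)
    rereference: bool = True
    mastoids: tuple[str, str] = ("TP9", "TP10")
    epoch_t0: float = 0.0
    epoch_t1: float | None = None   # default: trial_sec
    baseline: tuple[float, float] = (-5.0, 0.0)
    reject_uv: float = 75.0
    # spectral / connectivity
    band_table: str = "canonical"
    analysis_bands: list[str] = field(
        default_factory=lambda: ["theta", "alpha", "beta", "gamma"])
    seg_sec: float = 2.0
    overlap: float = 0.5
    # graph conventions
    distance_rule: str = "inverse"
    clustering_variant: str = "onnela"
    # statistics
    outlier_sd: float = 3.0
    adjust: str | None = None
    # bookkeeping
    seed: int = 0
    out_dir: str = "wplinet_out"

    def __post_init__(self) -> None:
        if self.band_table not in BAND_TABLES:
            raise ValueError(f"unknown band table {self.band_table!r}; "
                             f"known: {sorted(BAND_TABLES)}")
        known = {b.name for b in BAND_TABLES[self.band_table]}
        unknown = set(self.analysis_bands) - known
        if unknown:
            raise ValueError(f"unknown band name(s) {sorted(unknown)}; "
                             f"known: {sorted(known)}")

    def bands(self):
        table = BAND_TABLES[self.band_table]
        return [b for b in table if b.name in self.analysis_bands]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["behavior_means"] = {
            "|".join(k): v for k, v in d["simulation"]["behavior_means"].items()}
        d["simulation"]["behavior_sd"] = {
            "|".join(k): v for k, v in d["simulation"]["behavior_sd"].items()}
        d["simulation"]["bands"] = [dataclasses.asdict(b)
                                    for b in self.simulation.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "behavior_means" in sim:
            sim["behavior_means"] = {tuple(k.split("|")): v
                                     for k, v in sim["behavior_means"].items()}
        if "behavior_sd" in sim:
            sim["behavior_sd"] = {tuple(k.split("|")): v
                                  for k, v in sim["behavior_sd"].items()}
        if "bands" in sim:
            sim["bands"] = tuple(spectral.BandDefinition(**b)
                                 for b in sim["bands"])
        if "artifact_spec" in sim and isinstance(sim["artifact_spec"], dict):
            sim["artifact_spec"] = simulate.ArtifactSpec(**sim["artifact_spec"])
        for key in ("notch", "mastoids", "baseline"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def demo(cls, seed: int = 1) -> "PipelineConfig":
        """Small end-to-end configuration: 6 subjects, 16 channels, two
        analysis bands, short trials — finishes in well under a minute."""
        sim = SimulationConfig(n_subjects=6, n_channels=16, fs=128.0,
                               trial_sec=10.0, n_trials_per_cell=2,
                               n_coupled=16, gap_sec=3.0)
        return cls(simulation=sim, run_ica=False, rereference=False,
                   analysis_bands=["alpha", "gamma"], baseline=(-2.0, 0.0),
                   seed=seed)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, **params) -> None:
        self.stages.append({"stage": name, **params})

    def add_output(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path.name)] = digest

    def to_json(self, path: str | Path) -> Path:
        return io.write_json(dataclasses.asdict(self), path)


def screen_outlier_subjects(cell: pd.DataFrame, k: float = 3.0,
                            dv: str = "value"):
    """Outlier screen on subject-level cell means.

    Within each design cell, values beyond +/- k SD of the cell's mean are
    flagged (single pass); flagged subjects are dropped listwise so the
    within-subject ANOVA keeps complete cases. Returns
    ``(filtered_table, dropped_subject_ids)``.
    """
    dropped: set = set()
    for _, grp in cell.groupby(["channel_type", "music_type"]):
        if len(grp) < 3:
            continue
        _, log = stats.exclude_outliers(grp[dv].to_numpy(), k=k)
        dropped.update(grp["subject"].to_numpy()[log["removed_indices"]])
    return cell[~cell["subject"].isin(dropped)], sorted(dropped)


def preprocess_subject(rec, events, cfg: PipelineConfig):
    """Apply the cleaning chain to one subject's continuous recording.

    Order: band-pass -> notch -> interpolate -> epoch + baseline ->
    (ICA on epochs) -> linked-mastoid re-reference -> amplitude rejection.
    With ``ica_on_epochs=False`` the decomposition runs on the continuous
    data before epoching instead.
    """
    rec = preprocess.bandpass(rec, cfg.l_freq, cfg.h_freq)
    rec = preprocess.notch(rec, *cfg.notch)
    rec = preprocess.interpolate_bad(rec, cfg.bad_channels)
    report = None
    if cfg.run_ica and not cfg.ica_on_epochs:
        rec, report = preprocess.remove_ocular_ica(rec, cfg.ica_threshold)
    t1 = cfg.epoch_t1 if cfg.epoch_t1 is not None else cfg.simulation.trial_sec
    ep = preprocess.epoch_and_baseline(rec, events, cfg.epoch_t0, t1,
                                       cfg.baseline)
    if cfg.run_ica and cfg.ica_on_epochs:
        ep, report = preprocess.remove_ocular_ica(ep, cfg.ica_threshold)
    if cfg.rereference:
        ep = preprocess.rereference_linked_mastoids(ep, cfg.mastoids)
    ep = preprocess.reject_amplitude(ep, cfg.reject_uv)
    return ep, report


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full simulated study and write all result tables.

    Per subject: simulate -> preprocess -> per band x music type WPLI
    matrix -> network metrics; plus per-condition band-power spectra.
    Group level: mean WPLI matrices, band-wise metric t-tests, behavioral
    RM-ANOVAs and simple effects. Writes tidy CSVs, JSON summaries, the
    effective config and a manifest with per-file checksums.
    """
    from . import __version__

    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation.with_(seed=cfg.seed)
    manifest = RunManifest(cfg.config_hash(), __version__)
    bands = cfg.bands()

    metric_rows, spectra_rows = [], []
    per_band_cond: dict[tuple[str, str], list] = {
        (b.name, mu): [] for b in bands for mu in MUSIC_TYPES}

    for subject in range(sim.n_subjects):
        rec, events = simulate.make_subject_recording(sim, subject)
        ep, ica_report = preprocess_subject(rec, events, cfg)
        n_rej = int(ep.rejected_mask.sum())
        if n_rej:
            manifest.warnings.append(
                f"subject {subject}: {n_rej} epoch(s) rejected at "
                f"+/-{cfg.reject_uv} uV")
        manifest.add_stage("preprocess", subject=subject,
                           history=ep.history[-6:],
                           ica_removed=(ica_report or {}).get("removed"))
        for band in bands:
            for mu in MUSIC_TYPES:
                cond = {"music_type": mu}
                try:
                    M = band_wpli(ep, band, cfg.seg_sec, cfg.overlap,
                                  condition=cond, subject=subject)
                except ValueError as err:
                    manifest.warnings.append(
                        f"subject {subject} band {band.name} {mu}: {err}")
                    continue
                per_band_cond[(band.name, mu)].append(M)
                nm = graphnet.network_summary(
                    M, distance=cfg.distance_rule,
                    clustering_variant=cfg.clustering_variant)
                metric_rows.append({
                    "subject": subject, "band": band.name, "music_type": mu,
                    "mean_wpli": M.mean_weight(), **nm.as_dict()})
        for ch_type in simulate.CHANNEL_TYPES:
            cond = {"channel_type": ch_type, "music_type": "nostalgic"}
            summary = spectral.band_aggregate(
                spectral.welch_psd(ep, cfg.seg_sec, cfg.overlap, cond),
                tuple(BAND_TABLES[cfg.band_table]))
            tab = summary.band_table()
            tab.insert(0, "subject", subject)
            tab.insert(1, "channel_type", ch_type)
            tab.insert(2, "music_type", "nostalgic")
            spectra_rows.append(tab)

    metrics = pd.DataFrame(metric_rows)
    metrics_path = out / "network_metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    manifest.add_output(metrics_path)

    spectra = pd.concat(spectra_rows, ignore_index=True)
    spectra_path = out / "band_power.csv"
    spectra.to_csv(spectra_path, index=False)
    manifest.add_output(spectra_path)

    for (band_name, mu), mats in per_band_cond.items():
        if not mats:
            continue
        gm = group_connectivity(mats)
        p = io.write_matrix_csv(gm, out / f"wpli_{band_name}_{mu}.csv")
        manifest.add_output(p)
        manifest.add_stage("group_connectivity", band=band_name,
                           music_type=mu, n=gm.n_subjects,
                           mean_wpli=gm.mean_weight())

    tt = stats.band_metric_ttests(
        metrics, ["mean_wpli", "strength", "global_efficiency",
                  "local_efficiency", "char_path_length"],
        adjust=cfg.adjust)
    tt_path = out / "network_ttests.csv"
    tt.to_csv(tt_path, index=False)
    manifest.add_output(tt_path)
    if cfg.adjust is None:
        manifest.warnings.append(
            f"network_ttests: {int(tt['n_tests_family'].iloc[0])} "
            "uncorrected band x metric tests (set adjust='fdr' to correct)")

    behavior = simulate.generate_behavior(sim)
    beh_path = out / "behavior.csv"
    behavior.to_csv(beh_path, index=False)
    manifest.add_output(beh_path)

    anova_rows, simple_rows = [], []
    for scale in SCALES:
        cell = behavior.groupby(["subject", "channel_type", "music_type"],
                                as_index=False)[scale].mean()
        cell = cell.rename(columns={scale: "value"})
        cell, dropped = screen_outlier_subjects(cell, k=cfg.outlier_sd)
        if dropped:
            manifest.warnings.append(
                f"{scale}: subjects {dropped} excluded by the "
                f"+/-{cfg.outlier_sd} SD screen")
        res = stats.rm_anova_3x2(cell)
        t = res.table()
        t.insert(0, "scale", scale)
        anova_rows.append(t)
        for mu in MUSIC_TYPES:
            for r in stats.simple_effects(cell, within="channel_type",
                                          at_factor="music_type", at_level=mu,
                                          adjust=cfg.adjust):
                simple_rows.append({"scale": scale, **r.as_row()})
    anova_path = out / "behavior_anova.csv"
    pd.concat(anova_rows, ignore_index=True).to_csv(anova_path, index=False)
    manifest.add_output(anova_path)
    simple_path = out / "behavior_simple_effects.csv"
    pd.DataFrame(simple_rows).to_csv(simple_path, index=False)
    manifest.add_output(simple_path)

    cfg_path = cfg.to_yaml(out / "config.yaml")
    manifest.add_output(cfg_path)
    manifest.to_json(out / "manifest.json")
    return manifest
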