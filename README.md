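# wplinet

Functional brain networks from multichannel EEG, built on the **weighted
phase lag index (WPLI)**: a full, reproducible pipeline from continuous
64-channel recordings (real or simulated) to per-band connectivity matrices,
weighted graph metrics, band-power spectra, and within-subject statistics.

The package targets studies of emotion induction with a within-subject
3 (sensory channel: visual, auditory, audiovisual) × 2 (music type:
nostalgic, non-nostalgic) design — passive stimulation trials with per-trial
9-point Likert ratings (state nostalgia plus the pleasure / arousal /
dominance affective dimensions) recorded alongside EEG. It is equally usable
as a library of well-tested building blocks for any WPLI-network analysis.

## The method

For channels *x*, *y*, with per-segment cross-spectra *S_xy(f)* from
Hann-windowed overlapping segments, the WPLI at a frequency bin is

```
WPLI(f) = | E[ Im S_xy(f) ] |  /  E[ | Im S_xy(f) | ]
```

The imaginary cross-spectrum is blind to zero-lag (volume-conducted)
coupling, and the magnitude weighting emphasizes segments with a consistent
phase lag, so WPLI ∈ [0, 1] isolates genuine lagged interactions. Band
values average the per-bin WPLI over the bins in each of the five canonical
bands (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz).

Each per-subject, per-condition WPLI matrix is treated as a weighted
complete graph (nodes = electrodes, edge length = 1/weight) on which the
pipeline computes node **strength** Σⱼwᵢⱼ, Onnela weighted **clustering**,
**characteristic path length** L (mean Dijkstra distance over reachable
pairs), **global efficiency** E = mean of 1/dᵢⱼ, and **local efficiency**
(mean neighborhood-subgraph efficiency). Condition contrasts use paired
t-tests per band and metric; behavioral ratings get a two-way
repeated-measures ANOVA with Greenhouse–Geisser correction, partial
eta-squared effect sizes, and paired-t simple effects.

Because raw data for such studies are rarely deposited, the package ships a
first-class **synthetic-data generator**: band-limited common sources with
per-subject phase offsets are mixed into the channels at a per-band,
per-condition gain g ∈ [0, 1] over pink background noise, with optional
blink / line-noise / spike artifacts and Likert ratings drawn at published
cell means. Every downstream stage is validated against this planted ground
truth.

## Worked example

Simulate a small study (6 subjects, 16 channels, alpha and gamma coupling
elevated from g = 0.3 to g = 0.6 under the nostalgic condition) and run the
whole pipeline:

```python
from wplinet import PipelineConfig, SimulationConfig, run_pipeline

sim = SimulationConfig(n_subjects=6, n_channels=16, fs=128.0, trial_sec=10.0,
                       n_trials_per_cell=2, n_coupled=16, gap_sec=3.0)
cfg = PipelineConfig(simulation=sim, run_ica=False, rereference=False,
                     analysis_bands=["alpha", "gamma"],
                     baseline=(-2.0, 0.0), seed=1)
manifest = run_pipeline(cfg, "demo_out")
```

`demo_out/network_ttests.csv` then contains (seed 1):

```
 band            metric        t            p  mean_nostalgic  mean_non-nostalgic
alpha         mean_wpli  31.5520  6.0049e-07          0.7709              0.5822
alpha          strength  31.5520  6.0049e-07         11.5628              8.7324
alpha global_efficiency  25.5892  1.7019e-06          0.8086              0.6402
alpha  local_efficiency  25.5589  1.7120e-06          0.8085              0.6399
alpha  char_path_length -19.0094  7.4598e-06          1.3284              1.6983
gamma         mean_wpli  39.9732  1.8355e-07          0.7916              0.5932
...
```

Reading: under the nostalgic condition the planted coupling raises the mean
WPLI (0.77 vs 0.58 in alpha), hence node strength and both efficiencies
rise while the characteristic path length falls — the positive t's on
strength/efficiency and the negative t on path length, all far below
p = 0.05, recover the planted effect. `behavior_anova.csv` holds the
rating ANOVAs and `wpli_<band>_<condition>.csv` the group-mean matrices;
`manifest.json` records config hash, stage provenance and per-file
checksums (identical config + seed ⇒ identical checksums).

The same kind of run is available from the shell (`--demo` uses a built-in
6-subject configuration; `--config` takes any persisted `config.yaml`):

```bash
wplinet run-all --demo --seed 1 --out-dir demo_out
wplinet simulate --subjects 2 --out-dir sim_out     # BrainVision triplets
wplinet stats sim_out/behavior.csv --scale pleasure
```

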