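# Methods

This note documents the models, estimators, conventions and design choices
behind `wplinet`, and what the simulation-based validation does and does not
show about real EEG.

## 1. The synthetic study

The generator emulates a within-subject 3 (sensory channel: visual,
auditory, audiovisual) × 2 (music type: nostalgic, non-nostalgic) passive
stimulation experiment: blocks in the fixed order visual → auditory →
audiovisual, each block holding `n_trials_per_cell` nostalgic and as many
non-nostalgic trials in per-subject random order, each trial preceded by a
fixation gap that also serves as the baseline window.

### Neural model

Per trial, each scalp channel carries unit-variance pink (1/f-amplitude)
noise scaled to `noise_sd` (default 10 µV — a realistic background scale
that also exercises relative-power code nontrivially, unlike white noise).
For each frequency band *b* with coupling gain g(b, condition) > 0, a
band-limited Gaussian common source (brickwall-filtered to the band,
represented as an analytic signal) is added to a designated channel subset
at amplitude g·`noise_sd`, with each channel receiving the source shifted by
a per-subject, per-band phase offset. Offset magnitudes are uniform in
[π/4, π/2] with alternating sign across the subset, so almost every coupled
pair carries a sizable, sign-consistent phase lag — precisely the structure
WPLI detects — while zero-lag common components cancel out of the
estimator. Offsets are fixed per subject (not per trial) so condition
contrasts remain purely within-subject.

This is deliberately *not* a biophysical model: there is no head geometry,
no volume conduction beyond the additive common-source construction, and no
nonstationarity within a trial. Consequently, passing the recovery tests
shows the *pipeline* is correct and well-calibrated, not that real nostalgia
EEG behaves this way.

Default gains: alpha and gamma at 0.6 (nostalgic) vs 0.3 (non-nostalgic),
theta and beta condition-equal at 0.3, delta 0. One caveat worth knowing:
the band sources have sharp spectral edges, but Hann-windowed segment
spectra leak a little energy into the one or two bins adjacent to a band
edge, so a strong condition effect in alpha/gamma induces a faint echo in
the neighboring beta bins. The null-band *calibration* is unaffected
(gains there are condition-equal by construction), but a "null" band
adjacent to a strongly modulated one in the same simulation is only
approximately null.

### Artifacts

* **Blinks**: a stereotyped 0.35 s squared-half-sine bump at a Poisson rate
  per minute, amplitude 200 µV on VEOG (30% on HEOG), projected onto scalp
  channels with an exponential spatial decay (~4 cm scale) from Fp1/Fp2
  using standard 10-20 positions — giving ICA a genuinely rank-one frontal
  component to find.
* **Line noise**: a 50 Hz sinusoid of configurable amplitude, common phase
  across scalp channels.
* **Spikes**: with a per-epoch probability, one single-sample deflection of
  ±150 µV (default) in a random channel — ground truth for the ±75 µV
  rejection screen.

### Behavioral model

Per-trial ratings are cell-mean + Gaussian(cell SD) noise, truncated and
rounded to the 1–9 Likert grid. Cell means and SDs default to published
descriptive statistics for this design (state-nostalgia cells ≈ 7.3–7.8
nostalgic vs 3.3–3.9 non-nostalgic; pleasure/arousal ≈ 6.9–7.2 vs 4.5–5.2;
dominance ≈ 6.8–7.3 vs 6.0–6.5). Two modeling notes: the published SDs are
treated as per-trial SDs and there is no separate subject random intercept,
so subject-level means are less variable than in real data by roughly
√(trials per cell); simulated test statistics are therefore larger than
published ones, and the validation is directional (sign + significance
power), never a numeric match to published t or F values. Truncation at 9
slightly compresses the upper cells.

## 2. Preprocessing chain

Order (recorded in each output's provenance history): band-pass 0.1–50 Hz →
notch 49–51 Hz → bad-channel interpolation → epoching + baseline
subtraction → ocular ICA → linked-mastoid re-reference → ±75 µV rejection.

* **Filters**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), high-pass and low-pass as separate cascades for numerical
  stability near DC. Zero-phase is verified by cross-correlation lag tests.
* **Interpolation**: spherical splines on standard 10-20 positions (via
  mne's implementation behind the package's own surface), inverse-distance
  fallback when positions are unknown. No automatic bad-channel detection —
  labels come from config.
* **ICA**: FastICA on scalp channels only (EOG excluded from the
  decomposition); any component whose |Pearson r| with an EOG channel
  reaches the threshold (default 0.8) is zeroed before back-projection. The
  contract is the removal criterion, not the decomposition algorithm. The
  decomposition can run on epochs (default, matching analysis chains that
  decompose after segmentation) or on continuous data (`ica_on_epochs=False`,
  the more common practice); both entry points are supported.
* **Baseline**: default window is the 5 s pre-onset fixation; epochs default
  to [0, 30] s (the stimulus duration; the generator's `trial_sec` is
  configurable because stated stimulus and epoch durations differ in this
  literature).
* **Rejection**: "exceeding ±75 µV" is read strictly (a peak exactly at
  75 µV survives), evaluated per epoch on scalp channels after baseline
  correction. Rejected epochs are excluded from every downstream mean; a
  screen that would reject everything raises instead of propagating NaNs.
* **Re-reference**: each channel minus the mean of TP9/TP10 (M1/M2 accepted
  as synonyms). Reduced simulated montages (< 64 channels) may not include
  the mastoids; such configs set `rereference=False` rather than silently
  skipping.

## 3. Spectral estimation

Welch PSD: 2 s Hann segments, 50% overlap, constant detrend, one-sided
density normalization, averaged over the retained epochs of the selected
condition. Band power uses **half-open** edge ownership [lo, hi) — a bin at
13 Hz belongs to beta, never alpha — and by default the Riemann sum
(bin width × PSD). This choice makes contiguous bands tile the 1–50 Hz axis
exactly, so the discrete Parseval identity carries to the band sum (validated
to 2% against the variance of ideally band-limited signals); trapezoidal
integration is available (`integration="trapezoid"`) but slightly
down-weights band-edge bins and does not tile. Relative power divides by
the sum of the five analysis bands (the 1–50 Hz analysis range), not total
Nyquist power; channels with zero total power are flagged undefined rather
than emitting NaN.

Two band tables ship: the canonical one (α 8–13, β 13–30, γ 30–50) as
default and a "results-section-bands" variant (α 8–14, β 14–31, γ 31–50)
selectable by config — both appear in this literature and they are never
merged silently.

## 4. WPLI connectivity

Per pair and bin, WPLI = |mean over segments of Im S| / mean of |Im S|,
with expectation pooled over all Hann segments of all retained epochs of a
condition (segment-level pooling maximizes the sample count; segments never
straddle epoch boundaries). The band value is the unweighted mean over the
band's bins (a power-weighted mean is exposed as an option). Conventions:

* plain WPLI, not the debiased-squared variant (values live on [0, 1] and
  match how group means are usually reported);
* 0/0 → 0 for degenerate (zero-lag) pairs, detected with a relative
  tolerance of 1e-9 against the mean cross-spectral magnitude so that
  floating-point imaginary residue on identical signals cannot masquerade
  as coupling; degenerate pairs are logged per matrix;
* segmentation shares the Welch parameters so PSD and connectivity use one
  spectral estimate.

The estimator is exactly invariant to positive rescaling of any channel,
bounded in [0, 1], suppresses zero-lag common sources (validated by
simulation), and its null bias decreases with the number of segments
(≈ 1.13/√n per bin under independence — with 15 pooled segments per
condition the null band mean sits near 0.23, which is why even "null"
matrices in small simulations have visibly nonzero weights).

## 5. Network metrics

The full weighted complete graph is analyzed — no thresholding or
binarization. Metadata in every output records the conventions:

* distance rule `1/w` (default; reproduces E_glob ≈ mean WPLI whenever
  direct edges are shortest paths) or `-log(w)`;
* Dijkstra all-pairs distances; unreachable pairs are excluded from the
  characteristic path length (their count is reported) and contribute 0 to
  efficiencies;
* clustering per Onnela (triangle weights normalized by the network-wide
  maximum; Barrat variant by config); nodes with < 2 neighbors get C = 0.
  Clustering is computed and reported but is not part of the headline
  band × metric comparison set (strength, global/local efficiency, path
  length).

All metrics are verified to 1e-9 against exhaustive simple-path enumeration
on random graphs (n ≤ 6) and against closed forms on uniform complete
graphs (E_glob = w, L = 1/w, C = 1, E·L = 1), plus a networkx cross-check.

## 6. Statistics

* **Outlier screen**: single pass, ±3 SD, with mean/SD from the full
  sample (never re-iterated). It operates on subject-level condition means
  per indicator — all reported tests are subject-level — and a flagged
  subject is dropped listwise for that indicator so the within-subject
  ANOVA keeps complete cases.
* **Paired t**: t = mean(d)/(sd(d)/√n), df = n−1, two-sided, Cohen's d_z;
  zero-variance nonzero differences yield an explicit infinite-t flag.
* **RM-ANOVA**: subject-wise sums-of-squares partition; each
  within-subject effect is tested against its own subject × effect error
  term; η²p = SS_effect/(SS_effect + SS_error). Effect SS below 1e-12 of
  the total variation are treated as exactly zero so pure subject effects
  give F = 0 rather than a ratio of rounding residue.
* **Greenhouse–Geisser**: ε from the eigenvalues of the orthonormal-contrast
  covariance, per effect (trivially 1 for single-df effects); corrected p
  uses ε-scaled numerator and denominator df. Note the correction is only
  guaranteed conservative for clearly significant effects; for F < 1 the
  corrected p can drop below the uncorrected one (this matches pingouin and
  SPSS behavior and is asserted in the tests).
* **Simple effects**: pairwise paired t-tests of one factor at a fixed
  level of the other, uncorrected by default (matching common practice in
  this literature) with optional Holm/FDR adjustment; the band × metric
  neural family likewise defaults to uncorrected p-values but carries an
  explicit multiplicity warning and an FDR switch.
* The matrix-level group contrast can be computed subject-level (default,
  the only defensible sampling unit) — entry-level matrix comparisons, as
  sometimes reported in this literature, conflate within-matrix dependence
  and are intentionally not the default.

## 7. Validation design and problem sizes

Simulation-heavy checks run at reduced size, chosen once as a Monte-Carlo
design: recovery of the planted alpha/gamma condition effect uses 36
subjects × 16 channels at 128 Hz with 10 s trials and all channels coupled
(the planted effect is whole-brain, mirroring the headline contrast);
null-band calibration uses 200 replicates of 12 subjects × 8 channels with
condition-equal theta/beta coupling. At these sizes the paired t-test's
empirical false-positive rate is 0.048 (theta) and 0.061 (beta) over 1000
replicates — within the 0.05 ± 0.02 acceptance band; the residual beta
inflation reflects the mild non-normality of band-mean WPLI differences at
15 segments per condition and shrinks with longer recordings. The 200-rep
estimates carry a Monte-Carlo SE of ≈ 0.015.

Behavioral power: at the default (published) cell means and SDs with 38
subjects, the nostalgic > non-nostalgic main effects on pleasure, arousal
and dominance reach p < 0.001, and the audiovisual > visual simple effect
under nostalgia reaches p < 0.05, in effectively 100% of seeds — the
published effects are large relative to the generator's noise model (see
the per-trial-SD caveat in §1).

## 8. I/O and reproducibility

Recordings are written as BrainVision triplets (.vhdr/.vmrk/.eeg,
IEEE_FLOAT_32 multiplexed, µV, the dialect stated in the header) and read
back through mne; EDF+ reading is supported, EDF+ writing is not (no
suitable writer dependency). Marker files use BrainVision's native 1-based
sample positions on disk; everything in memory is 0-based. All tabular
outputs are tidy long-format CSV. A run's manifest records the config hash,
package version, per-stage provenance, warnings (rejected-epoch counts,
multiplicity notes, outlier exclusions) and a SHA-256 checksum per output
file; identical config + seed reproduce identical checksums, which is
asserted in the test suite.

## 9. Known limitations

* No biophysical head model; volume conduction is only emulated as additive
  zero-lag mixing.
* No time–frequency analysis, no source-space connectivity, no PLI /
  coherence / Granger alternatives, no small-world / modularity / MST graph
  analyses, no network-based statistic thresholding.
* The ICA contract is EOG-correlation removal; muscle/cardiac artifact
  classification is out of scope.
* Reaction times are generated as filler and never analyzed.
* The behavioral noise model omits subject random effects (see §1), so
  between-subject heterogeneity in real data is understated.
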