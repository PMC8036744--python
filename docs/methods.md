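# Methods

This note documents the models, defaults and design choices behind
`stratims`, in the spirit of a methods appendix: what is simulated, what is
computed, which knobs matter, and what the synthetic results do and do not
demonstrate.

## The synthetic cohort generator

Real HGSOC MALDI-IMS cohorts are not publicly distributable, so the package
ships a generator (`stratims.synthetic_data`) whose output has the
statistical structure the analysis assumes. Per pixel, the spectrum is

    I(m) = t · [ b(m) + Σ_k h_k · g(m; c_k + δ_k, w) ] + ε(m)

- **Channels.** `n_channels` (default 540) Gaussian peak channels
  (`g`, FWHM `w` = 0.5 Da) on a jittered grid over `mz_range` (default
  800–3200 Da) with a guaranteed ≥ 1.2 Da gap so 0.25 Da single-linkage
  clustering is well posed. Published literature on the emulated cohort
  reports peaks from m/z 600 despite an 800 Da acquisition window; the
  range is configurable (600–3200 accepted) rather than resolving that
  discrepancy.
- **Panel vs run.** Channel centers, base heights `h_k` (log-normal around
  20, clipped to [5, 200]) and marker assignment derive from `panel_seed`,
  separate from the run `seed`. Two cohorts generated with the same
  `panel_seed` share their molecular structure — as two cohorts of the same
  tissue type measured on the same platform do — which is what makes
  cross-dataset model application (the stroma filter) possible at all.
  Noise, labels, compartment geometry and mass calibration come from `seed`.
- **Labels.** Each patient draws one subtype from `subtype_proportions`
  (default 0.376/0.276/0.158/0.190, the prevalences of the emulated
  279-patient cohort); all pixels of a patient's cores share it, matching
  per-core ground-truth labeling. `n_subtype_markers` channels (default 24,
  six per class) are scaled by `effect_size` (default 2.0) **in malignant
  pixels of the associated subtype only** — stroma carries no subtype
  signal, which is precisely why stroma exclusion helps.
- **Compartments.** Each core's stroma is a contiguous blob: the lowest
  `stroma_fraction` (default 0.3) quantile of a Gaussian-smoothed random
  field, mimicking annotated compartment geometry rather than
  salt-and-pepper noise. Compartment markers (default 12) alternate between
  stroma-elevated (× 3.0, e.g. the COL1A1-like anchor at 836.359 Da) and
  malignant-exclusive (× 0.02 residual in stroma, e.g. the histone-H1.2-like
  anchor at 1106.719 Da). A C1-associated subtype anchor emulates ACTA2 at
  976.490 Da.
- **Noise.** Multiplicative log-normal noise on peak heights (`noise_cv`,
  default 0.2), a smooth additive baseline `b` (level 2.0) drifting upward
  toward low mass, a small additive detector floor (`ε`, SD 0.05), a
  per-spectrum log-normal TIC factor `t` (`tic_variation_cv`, default 0.25),
  and per-channel-per-pixel m/z jitter `δ` (SD 0.03 Da). The
  compartment-labeled cohort additionally draws one global calibration
  offset (SD 0.04 Da) to exercise feature parity. No peak-shape model, FFPE
  chemistry, digestion pattern or isotope envelope is simulated.
- **Scales.** The subtype cohort defaults to 60 patients × 1 core × 10×10
  pixels; `stroma_reference_config()` emulates the compartment-annotated
  cohort scale of 19 patients / 35 cores.

What passing tests on this generator show: the pipeline recovers planted
structure (channels, markers, compartments, labels) under realistic noise,
and its metrics agree with independent oracles. What they do not show:
robustness to FFPE chemistry, batch effects beyond a global calibration
offset, overlapping isotope envelopes, or histology that violates the
"stroma carries no subtype signal" idealization.

## Preprocessing and peak picking

Baseline removal is a moving-average lower envelope: iterate
`env ← min(env, moving_average(env, width))` four times, smooth once more,
subtract, clamp at 0 (default `width` 20 points). It is exact on flat
baselines and preserves apexes of peaks narrower than ~width/4. On curved
baselines it leaves low-amplitude ripple; consequently the picked axis
contains the true channels plus low-occurrence ripple clusters (~200 at the
default scale). This is deliberate realism — commercial peak pickers behave
the same way — and downstream Gini selection ignores them.

TIC normalization rescales each spectrum to unit total intensity; all-zero
spectra are dropped with a logged warning rather than failing a batch. Peak
picking thresholds local maxima at `snr_threshold` (default 6) times the
per-spectrum MAD noise (× 1.4826), centroids each maximum by a 3-point
intensity-weighted mean, single-linkage clusters pooled candidates at a
0.25 Da gap, and keeps clusters occurring in ≥ 1 % of spectra. Feature
extraction takes the maximum within ± tolerance (monotone in peak height;
simpler than integration). Whether the emulated study's own picker was
interval- or centroid-based is unknowable; both the SNR threshold and the
gap are parameters.

## Dataset preparation

"Approximately equal numbers of spectra" is operationalized as: stop
sampling a class at the first whole core that reaches the rarest-class
count, bounding overshoot by one core (cores are atomic). The 70/30 split
defaults to core level so that no core contributes pixels to both sides;
a spectrum-level mode exists because the emulated design is ambiguous on
this point, and neither mode is claimed as its intent. Scaling is
per-feature standardization (zero-spread features map to 0), always with
train-only statistics. The 25 % signature cut-off uses `floor`; ties at the
cut break by ascending m/z for determinism.

## Models and metrics

Forests are scikit-learn `RandomForestClassifier`s. Tuning grid-searches two
dimensions at resolution 4 — features-per-split fraction, log-spaced over
[0.05, 0.8], and minimum node size {1, 5, 10, 20} — with stratified 3-fold
CV, objective mean balanced accuracy (robust to residual imbalance), ties
preferring smaller values of both dimensions; tree count is fixed
(`HyperParams.trees`, default 500). One tuned parameter set is applied to
all three replicate learners, each fit on its own training rows restricted
to its own signature; test rows never touch scaling, selection or tuning.

One-vs-one AUC is the Hand-and-Till M measure implemented from rank sums
(ties get half credit); for two classes it reduces exactly to binary AUC,
which the tests verify against `scipy.stats.mannwhitneyu`. Multiclass FDR is
macro-averaged 1 − precision over predicted classes (never-predicted classes
are excluded with a warning); balanced accuracy excludes empty true classes
with a warning. All tie-breaks use the class order C1 < C2 < C4 < C5.

The stroma ensemble uses binary stratification of the compartment-labeled
matrix after parity alignment; each member selects its own signature (a
shared-signature mode exists). Exclusion requires unanimity at the members'
default 0.5 probability cut — the conservative intersection rule; there is
no tuned threshold and no soft down-weighting.

## Pipeline and provenance

`run_pipeline` executes: generate/load → preprocess → reference axis →
parity (greedy nearest-pair matching in ascending |Δ|, injective both ways,
pairs ≥ 0.25 Da rejected) → complete-variant subsets/tuning/training →
stroma ensemble → consensus exclusion → excluded-variant
subsets/training → evaluation → peptide annotation. Both variants share all
upstream artifacts. Every stage seed derives deterministically from the one
config seed; reports are byte-identical across reruns of the same config
and carry its hash. The CLI exposes `simulate`, `run` and `annotate`;
intermediate stages exchange in-memory objects, so the library functions are
the interface for stage-level work.

## Study sizes and runtime choices

The benchmark studies (`stratims.benchmarks`, used by the acceptance script)
run at the default generator scale — 60 cores × 100 spectra × 540 channels,
compartment cohort 19 patients / 35 cores — with forest sizes chosen once
for single-CPU throughput: 150 trees for selection forests, 50 trees for
tuning fits on at most 1200 stratified rows, 200/150 trees for final/stroma
members. Importance rankings and forest accuracy are stable well below the
500-tree defaults at this data scale; the library defaults remain 500.

## Peptide annotation and NanoString labeling

Feature-to-peptide matching takes the reference entry of minimal |Δmass|
below 1.0 Da; several features may share one peptide (many-to-one is
expected), exact ties go to the lower mass and are flagged ambiguous —
a 1.0 Da window is wide, and silent ties would hide real ambiguity.

The count-panel chain runs threshold → positive controls → housekeeping →
log2. Normalization factors are (grand arithmetic mean of per-sample
geometric means) / (sample geometric mean), the standard convention for this
assay family. Sub-background counts are raised to the threshold, not zeroed,
and housekeeping probes are thresholded along with endogenous ones (a flag
disables that). Subtype labels come from a pluggable nearest-centroid rule
(highest Pearson correlation over a signature gene set); the proprietary
39-gene classifier of the emulated study is **not** reconstructed — synthetic
centroids stand in, and label assignment on real panels requires
user-supplied centroids.

## Known limitations

- The generator's additive-noise floor and log-normal peak noise are
  convenient, not measured, models; real FFPE spectra have structured
  chemical noise the baseline ripple only hints at.
- Stroma exclusion's near-perfect synthetic recall/precision reflects the
  planted compartment effects; on tissue, compartment boundaries are mixed
  at 50 µm raster width and performance is necessarily lower.
- Survival analysis, external cohort comparison and IHC validation are out
  of scope; so is any claim that the synthetic benchmark numbers transfer
  to patient data.
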