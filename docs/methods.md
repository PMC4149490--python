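# Methods

## The measurement model

A well holds one antibody and a suspension of cells drawn from a mixture
of populations (e.g. epithelial / immune / fibroblast). The simulator
generates each event's channels in linear fluorescence units:

- **Scatter.** FSC-A, FSC-H, FSC-W and SSC-A are log-normal
  (log10 means 5.0 / 4.9 / 1.85 / 4.5, sds 0.06 / 0.06 / 0.02 / 0.12,
  arbitrary units in an LSR-II-like range). Doublets (default 3% of
  events) multiply FSC-A and FSC-W by 2 with FSC-H unchanged — the
  standard pulse-geometry approximation in which two cells in one laser
  transit double the integrated area and transit width but not the peak
  height.
- **Fluorescence.** Every fluorescence channel carries a population's
  autofluorescence, log-normal with log10 mean 2.0 and sd 0.25. An event
  that is positive for the well's antigen (probability = the
  population's per-antigen positive fraction) adds a stained component,
  log-normal with log10 mean 3.5 and sd 0.30 by default (~30× over
  background, a typical bright conjugate). Sums of log-normals keep all
  values positive and produce the bimodal negative/positive structure
  that FMO gating presumes.
- **Viability.** Dead cells (default 5%) take up the viability dye: the
  DAPI channel adds a log-normal component with log10 mean 3.6 —
  more than 10× the live-mode median, so the two modes are separable.
- **Spillover.** Observed fluorescence rows are true rows times a
  spillover matrix S (unit diagonal; entry (i, j) is the fraction of
  channel i's signal read in channel j). The default 3-colour matrix has
  4–6% PE↔FITC and ≤1% APC cross-talk. Compensation multiplies by S⁻¹.
- **Run-to-run jitter.** Each well draws one N(0, 0.05²) shift of the
  stained component's log10 mean, emulating day-to-day staining/laser
  drift. 0.05 log10 units (~12% intensity) was chosen as a plausible
  drift for a tuned instrument; it leaves replicate profile ranks nearly
  intact, consistent with the high replicate correlations the platform
  is known for. It is a config parameter, not a claim about any
  particular instrument.

Control (FMO) wells are simulated fully unstained — no antibody and no
viability dye — so a single control well provides the reference
distribution for every fluorescence channel, including the viability
channel. Per-well seeds are `SeedSequence(master, crc32(plate),
crc32(well))`, making plate generation reproducible and parallelizable.

**What the generator does not model:** acquisition-time drift within a
plate, well-to-well carryover, cell-size/fluorescence correlation,
non-linear detector response, autofluorescence differences across
channels (uniform by default, per-channel overrides exist), and
antigen–antigen correlation within a population (positivity is drawn
independently per antigen). Passing recovery tests therefore show the
analysis is correct under these idealised conditions, not that it is
robust to every instrument artifact.

## Gating

Gates are deterministic, automatic stand-ins for manual gating:

- Thresholds are empirical percentiles (default 99.9) of the FMO
  control, using the linear-interpolation quantile definition: with
  sorted values x₍₁₎…x₍ₙ₎, the q-quantile interpolates linearly between
  the order statistics bracketing position 1 + q(n−1). This is
  `numpy.quantile(..., method="linear")` and is pinned by a full-sort
  oracle test, so any backend must match the definition, not a library
  default.
- Order is fixed: viability → singlets → positivity; the
  percent-positive denominator is viable singlets. Positivity is
  strictly greater than the threshold; with continuous simulated data
  ties have measure zero (for integerised data the convention matters
  and is stated here).
- The singlet gate keeps events with FSC-W ≤ 1.5 × median FSC-W. With
  the default width sd (0.02 log10) the singlet mode spans ±15% around
  its median while doublets sit at 2×, so the cut separates them
  cleanly at any doublet fraction below ~35%.
- By construction the FMO contract holds: an unstained well read
  against a 99.9th-percentile threshold shows ≈0.1% positives, the
  gate's designed false-positive rate.
- A well passes QC when at least `min_events` (default 10,000) events
  were *collected*; failing wells are reported as missing values, never
  as zeros, so they flow into imputation rather than biasing profiles.

Because FMO thresholds are per-channel percentiles of a control that
experienced the same spillover mixing as the stained wells, gating is
valid on uncompensated data; compensation is provided for analyses that
need unmixed intensities.

## Screening statistics

- Fold change is bidirectional (max/min), so losses and gains are
  symmetric, with both values clamped below at the 1% detection limit
  before the ratio — values below the nominal limit of detection are
  noise and must not inflate ratios. Consequently fold ≥ 1 and is
  always finite.
- The category partition: `undetected` (both conditions < 1%), then
  `both` / `abs_only` / `fold_only` / `unaffected` on the two criteria
  (Δ ≥ 5 points, fold ≥ 2). The influenced fraction is
  (abs_only + fold_only + both) / detected.
- A validation-stage screen (re-testing influenced antigens against
  individual enzymes) is the same classifier run on a restricted antigen
  set; it needs no separate code path.
- Replicate reproducibility is Spearman's ρ over shared non-missing
  antigens with average ranks for ties; the p-value is an exact
  enumeration over all rank permutations for n ≤ 8 and the large-sample
  approximation otherwise, with the method reported. ρ (not ρ²) is
  reported.
- Candidate-marker thresholds (reference mean ≥ 50%, target mean
  ≤ 20%) are configurable defaults; ties in the ranking score break
  alphabetically.

## Profile analytics

- k-NN imputation: distance between rows is Euclidean over mutually
  observed columns scaled by the proportion observed (the nan-Euclidean
  convention); the k nearest rows *with the target column observed*
  donate their mean. k truncates to the donors available. Imputed
  values are means of observed values, hence always inside the observed
  column range. A fully missing column is an error naming the antigen.
- Clustering uses d = 1 − Pearson r between raw percent-positive rows;
  mean centering is applied only on the PCA path. Correlation distance
  lies in [0, 2] but violates the triangle inequality, which
  agglomerative complete linkage does not require. Complete linkage
  (inter-cluster distance = maximum member pairwise distance) yields
  non-decreasing merge heights; merges are verified against a naive
  O(n³) agglomeration oracle. Tree cuts relabel clusters by first leaf
  appearance for determinism.
- PCA is the SVD of the column-centered matrix; the sign of each
  component is fixed by making its largest-magnitude loading positive.
  Requesting more components than the rank truncates with a warning.
- Dendrograms serialise to Newick with ultrametric branch lengths: an
  internal node sits at half its merge height, so a two-leaf tree is
  `(A:h/2,B:h/2);`.

## Pipeline determinism and problem sizes

Every tabular output is stamped with the configuration hash and master
seed; identical config + seed reproduce outputs byte for byte. The demo
screen uses the packaged 24-antibody panel with 4 control wells at
10,000 events per well; recovery tests run 20 seeds for the lability
classifier and 10 seeds for the three-group clustering property — sizes
at which every binomial tolerance (3 standard errors at n = 10,000) is
a fraction of the effects planted, while the whole suite runs in well
under a minute on one core.

## Known limitations

- FCS support is the 3.0 float list-mode dialect this package writes;
  integer data types, multiple data sets per file, and the 2.0/3.1
  dialects are out of scope (the gzip-CSV tabular format is the
  plain-text interchange path).
- The lability classifier uses the screen's fixed thresholds by design;
  it is a detection rule, not an inferential test, and no
  multiple-testing machinery is attached.
- The simulator's positive fractions are planted per population
  independently per antigen; co-expression structure (e.g. CD31/CD34
  co-occurrence beyond population identity) is represented only through
  population membership.
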