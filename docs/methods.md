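# Methods

`breathshift` reimplements, as a tested library, the analysis chain of a
two-cohort real-time breath-metabolomics study of an acute cold-pressor
intervention: each participant provides four guided exhalation measurements
(two before the stimulus at nominally −15 and −5 min, two after at 0 and
+25 min), and the question at every stage is whether — and how consistently
across two independent sites — the exhaled metabolic profile shifts after
the stimulus. This note documents the models, conventions and numerical
choices behind each stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Synthetic study generator

The generator is the package's source of test data with known ground truth;
its defaults are the study conditions.

Log10 intensity of sample *s* (subject × timepoint) and feature *f* is

    x_sf = b_f + λ · z_{s,block(f)} + σ · ε_sf + β_f · log10(2) · post(s)

- `b_f ~ N(4, 0.5)` — feature baselines on the log10 scale, giving the
  ~2.5-decade dynamic range typical of breath feature tables.  The true
  intensity distribution of the instrument is not published; log-normal is
  a modeling convenience, not a claim about the hardware.
- `σ = noise_sd_log10` (default 0.15) — within-subject measurement noise.
- Features are partitioned into `n_blocks` blocks; all samples share one
  latent factor per block, scaled by `λ = σ·sqrt(ρ/(1−ρ))` so the
  within-block Pearson correlation of log intensities equals `block_rho`
  (default 0.6).  Because λ is tied to σ, a zero-noise configuration
  degenerates to exact, noise-free tables — which is what makes the
  exact-recovery invariants testable.
- A fraction `frac_affected` (default 0.1) of features receives a true
  Log2 fold change β_f with |β_f| drawn uniformly from
  `effect_log2fc_range` (default 1.5–2.5, matching the significance
  threshold upward); `frac_down` controls the share of down-regulated
  effects (default 0, reflecting the strongly asymmetric response the
  design targets).
- Left-censoring: intensities below the dataset's `censor_quantile`
  quantile (default 0.05) are set to zero.  Censoring is thresholded, not
  random dropout, because regression-on-order-statistics imputation assumes
  left-censoring.  The default is deliberately mild so that default-config
  pipelines retain most features; heavier censoring (up to the validity
  bound of 0.5) is exercised explicitly in tests.
- Cohort sizes default to (19, 21) with timepoints (−15, −5, 0, +25) min.

Both cohorts share feature ids, affected set and true effects (the
conserved-response scenario); subject draws are independent per cohort.
Optionally, a fraction of feature m/z values is drawn (with ≤0.2 ppm
jitter) from the adduct masses of a compound library so that annotation has
matchable features.

What the generator does **not** emulate: instrument drift, lock-mass error,
Orbitrap peak shapes, polarity-specific chemistry, heteroscedastic noise,
and subject-level covariates (age/sex are packaged as a fixture, not
simulated).  Passing tests therefore demonstrate correctness of the
*analysis machinery* under a plausible data model, not performance on real
spectra.

Raw-recording simulation produces a square-wave capnogram (plateaus at the
requested CO₂ percentage, ~0.5 % baseline) and centroid frames every 0.5 s;
frames inside exhalation plateaus carry the requested peaks with ≤0.5 ppm
m/z jitter and ±10 % intensity noise.

The toy compound library anchors four real metabolites (arginine
C6H14N4O2, creatine C4H9N3O2, threonine C4H9NO3, asparagine C4H8N2O3) at
their correct monoisotopic masses and fills the rest with random CHNOS
formulas constrained to pass the heuristic formula filter; it stands in for
a reference metabolite database in annotation and enrichment tests.

## Spectral preprocessing

- **Exhalation windows** are maximal half-open intervals `[start, end)`
  with CO₂ strictly above 3 % (the end-tidal criterion); `end` is the time
  of the first sample back at/below threshold.
- **Window averaging** matches centroids across frames at ±1 ppm; a peak
  absent from a frame contributes zero to the mean.
- **ppm binning** is greedy single-linkage on sorted m/z: a new bin opens
  when the gap to the previous peak exceeds the tolerance (±1 ppm) of the
  running intensity-weighted consensus.  The boundary is inclusive, with a
  1e-8 relative epsilon so floating-point representation cannot flip an
  exact-tolerance gap.  This is a deliberate, deterministic replacement for
  kernel-density mode splitting; the two agree whenever peaks are separated
  by much more than the tolerance.
- **Sparsity filter**: features with ≥50 % zeros across all samples are
  removed (boundary inclusive: exactly half zeros is removed).
- **ROS imputation**: per feature, all n values are ranked with censored
  zeros lowest; Hazen plotting positions (k−0.5)/n map to standard-normal
  quantiles; ordinary least squares of log(detected) on the detected ranks'
  quantiles is back-transformed at the censored ranks.  Imputed values are
  clamped to the feature's minimum detected value (a censored value cannot
  exceed the detection limit) and are strictly positive.  Features with
  fewer than two detected values fall back to half the table's minimum
  positive intensity, with a warning.  The fit uses natural logs; the
  back-transform makes the base immaterial.
- **AUC aggregation**: the pre value is the trapezoidal area under
  timepoints 1–2 divided by their time interval — identically the mean of
  the two intensities — and likewise for timepoints 3–4.  Time
  normalization keeps the 10-minute pre span and the 25-minute post span
  comparable.  Imputation precedes aggregation: zeros would otherwise
  produce non-positive AUCs and undefined fold changes, so the order is
  forced even though it is not otherwise documented.
- **Instrument QC**: all eight standard Nelson control-chart rules are
  evaluated on the standardized daily gas-standard response against
  historical mean/SD; the verdict is in-control iff no rule fires.

Positive- and negative-polarity features are processed separately and
concatenated; the synthetic tables default to a single polarity.

## Paired differential statistics

Per feature, a two-sided paired t-test of log10 post- vs pre-AUC across
subjects (the log base does not affect t or p); `mean_log2fc` is the
subject-mean of log2(post/pre).  Zero-variance difference vectors are
degenerate: the direction is certain but t is undefined, so p is set to 0
and flagged.  Multiplicity is controlled by Benjamini–Hochberg across all
features of a cohort (the procedure behind the reported FDR is not named;
BH is the field default).  Volcano classes use inclusive thresholds:
up iff Log2FC ≥ 1.5 and FDR ≤ 0.01; down symmetric; otherwise ns.

Cross-cohort overlap of significant sets is tested with the exact
upper-tail hypergeometric probability P(X ≥ k) for k shared features given
the set sizes and the common universe.

PLS-DA uses NIPALS (scikit-learn's `PLSRegression`) on autoscaled log10
intensities with {0,1} class coding, 10-fold stratified cross-validation
(a subject-grouped option exists because fold stratification is otherwise
unstated), pooled out-of-fold accuracy at a 0.5 response cut, and
discriminant Q² = 1 − PRESS/TSS over out-of-fold predictions.

Demographics follow the conventions that reproduce the study's printed
population statistics exactly: mean/SD on full-precision ages; median/IQR
on ages truncated to whole years with linear-interpolation quartiles; the
Mann-Whitney U reported as min(U₁, U₂) from the truncated ages with
midrank ties and the continuity-corrected normal approximation; the sex
2×2 χ² with Yates continuity correction (the uncorrected statistic does
not match the published value; the corrected one does).

## Correlation-network concordance

Pearson correlations of log10 intensities across all samples of a cohort
(subject × timepoint; the value space is otherwise unstated) define a
weighted graph with an edge iff ρ strictly exceeds the cutoff.  Constant
features keep their node but get no edges.

Cross-site metrics per cutoff ∈ {0.1,…,0.9}: Jaccard index of unweighted
edge sets; Pearson correlation of the two ρ vectors over the union of
edges (an edge absent from one site contributes that site's sub-threshold
ρ); mean |ρ_A − ρ_B| over the union.  Cutoff-independent: correlation of
correlations over the full upper triangle (an edges-only variant is
exposed); the trace similarity tr(R_Aᵀ R_B)/(‖R_A‖_F‖R_B‖_F); and the
Pearson correlation of descending eigenvalue spectra.  The trace statistic
is reported in similarity orientation (1 = proportional matrices) with
1 − similarity exposed as a distance, matching how the quantity is
interpreted when larger values are read as more similar.

Permutation p-values permute the subject rows of cohort B independently
per feature column — destroying B's correlation structure while preserving
marginals — recompute R_B and the metric, and report
(1 + #{null ≥ observed})/(1 + n_perm).  The published analysis does not
state its permutation scheme; this one is the natural exchangeability null
for "is the shared structure more than marginals".

Topology per cutoff: connected components; mean local clustering; average
shortest-path length and diameter on the largest component (ties between
equal-sized components broken by node labels for determinism; NaN when the
component has <2 nodes); mean unnormalized node betweenness (the magnitude
of published betweenness values implies unnormalized).  Degree–fold-change
association uses Spearman rank correlation with midrank ties; an all-equal
degree or fold-change vector is reported as (0, NaN, undefined-flag)
rather than an exception.

## Annotation, pathway degree, enrichment

Features are matched to compounds through four ion types — [M+H]⁺, [M−H]⁻
and their single-¹³C isotopologues (offsets +1.00727646677 and
+1.0033548378 Da) — at ±1 ppm.  Formulas are screened by the formula-only
subset of the "seven golden rules": element-count ranges, ring-and-double-
bond plausibility, H/C ∈ [0.2, 3.1], N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3,
S/C ≤ 0.8, and joint multi-heteroatom checks.  Isotope-pattern rules are
excluded: a binned centroid feature carries no isotope envelope.

Pathway-degree analysis keeps pathways with ≥5 annotated features and
reports, per pathway and cohort, the median Log2FC and median node degree
(degree from the ρ = 0.7 network by default), plus the cross-cohort Pearson
correlation of the per-feature Log2FC vectors and of the degree vectors.
Pathways are clustered by average linkage on the Euclidean distance of the
two correlation values (linkage/distance are not documented; these are the
common defaults), and the dendrogram leaf order is returned.

Enrichment is a reduced mummichog-style procedure: per pathway, a one-sided
Fisher exact test of significant vs reference annotated features, with
features annotated to more than one compound contributing weight 0.001
instead of 1 (the ambiguity down-weighting; weight 1 recovers plain
counting).  The null is built from random draws of |significant| features
out of the reference; a gamma distribution fitted to the pooled null
−log p by the method of moments yields p_gamma as its upper tail at the
observed −log p.  The full activity-network scoring of the original
algorithm is intentionally not reproduced; the package treats enrichment
as a black-box scorer with the one documented customization.

## Participant-grouped classifier

Labels: timepoints 1–2 → pre (0), 3–4 → post (1).  Per repeat, subjects
are split 90/5/5 by largest-remainder rounding (all four samples of a
subject travel together; partitions are asserted disjoint every repeat);
standardization and PCA are fit on the training partition only and test
samples are projected into that space; a two-hidden-layer rectified-linear
MLP is trained by adaptive-moment updates with early stopping monitored on
the held-out validation partition (patience 10 epochs, max 500 epochs,
learning rate 1e-3) — monitored externally because a library-internal
validation split would break the grouped protocol.  The grid spans PCA
components {48, 64, 96, 128, 144} × hidden sizes {[32,32], [48,48],
[64,64], [96,96]}.

Reported: pooled ROC AUC over all test predictions of all repeats and the
mean of per-repeat AUCs (both pooling rules are defensible; both are
reported), accuracy at the 0.5 boundary (pooled per-prediction), accuracy
per measurement 1–4, and a subjects × 4 matrix of mean post probabilities
for the repeats in which a subject was tested (missing if never tested,
with a warning).  Probability profiles are clustered by Ward linkage on
Euclidean distances of the 4-dimensional profiles, cut into k = 3 clusters
by default; missing cells are row-mean imputed with a warning.

The classifier accepts any feature table; intensities are log10-transformed
after replacing zeros with half the minimum positive intensity, so imputed
and unimputed tables are both valid inputs.  Interpolated profile-mode
spectra (the original classifier's input) are out of scope with no raw
profile data; the feature-table route is the supported one.

## Pipeline orchestration

`run_pipeline` executes simulate → preprocess → differential → network →
pathways → classify from one YAML-backed config with a single global seed;
unknown keys are rejected by name.  The network stage defaults to the
significant-feature subset (the displayed-network convention; full-shared-
set topology scales quadratically in features and is available via
`subset: "shared"`).  Every artifact is a TSV/JSON/GraphML file; the run
report records per-stage parameters, sha256 digests and headline counts
under a versioned schema, and reruns with the same config and seed are
byte-identical.

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at deliberately moderate sizes chosen to keep
the statistical targets well-powered: ground-truth recovery and type-I
calibration use 20 subjects × 1000 features over 10 seeds; permutation
nulls use 20 seeds × 79 permutations; the classifier grid uses 40 subjects
× 200 features with 4 repeats per cell (test pools of ≥32 predictions per
cell); null classifier calibration uses 25 repeats per seed so the pooled
chance-level AUC has a standard error well inside the ±0.15 acceptance
band.  These sizes are the package's documented defaults for its own
verification, not statements about the original instrumentation.

## Known limitations

- The generator's Gaussian log-intensity model cannot produce the heavy
  tails, drift or batch structure of real SESI-HRMS data.
- ROS imputation fits each feature marginally over all samples; when a
  strong post-intervention effect coexists with heavy censoring of
  pre-intervention values, imputed pre values borrow from the pooled
  distribution and slightly attenuate extreme fold changes.
- The enrichment p_gamma calibration uses a pooled (across pathways) null;
  pathway-size-specific nulls would be tighter for very unequal pathway
  sizes.
- The mzML reader supports the standard encodings (base64, optional zlib,
  32/64-bit floats) but not vendor extensions or indexed random access.
- Published cohort-level values that depend on the deposited raw spectra
  (feature counts, the specific similarity values, classifier AUC) define
  output schemas here, not targets: they cannot be recomputed without the
  original recordings.
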