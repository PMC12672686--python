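# Methods

## The analysis problem

A non-enrichment, slide-based liquid biopsy plates every nucleated cell of
a peripheral-blood draw and images it in four immunofluorescence channels:
DAPI (nuclear DNA), CD138 (syndecan-1, a plasma-cell surface marker), BCMA
(B-cell maturation antigen, with either membrane or perinuclear
localization) and CD45 (pan-leukocyte). Circulating plasma cells occur at
roughly 1–10 per mL of blood against ~5 × 10⁶ nucleated cells per mL, so
the pipeline is a rare-event funnel: unsupervised outlier detection →
machine-learning artifact curation → marker phenotyping → enumeration →
cohort statistics → patient-level prediction.

## Synthetic data model

`synthgen` is the package's study-condition generator, not a test fixture.
One generative model feeds two routes: rendered frames (for segmentation)
and directly sampled event tables (for detection/statistics at scale).

**Geometry and volumes.** Defaults mirror the assay: 8 mL draws, two
slides of 3 × 10⁶ cells analyzed, a CBC of 6 × 10⁶ nucleated cells/mL —
hence an effective analyzed volume of 1 mL, so a class with incidence
λ cells/mL plants Poisson(λ) events per sample. Desk-scale background
population sizes (default 5,000 events per sample in tables, hundreds per
frame) stand in for the assay's millions; feature distributions, not
volume, are what downstream stages consume.

**Intensity model.** Per-event channel medians are Gaussian around
class-specific means (background level 100, positive marker 800, DAPI
1000, BCMA+ whole-cell median 500 with an 800-level band score on the
localized compartment and 200 off-band bleed; 12% relative s.d., clipped
at 0; arbitrary fluorescence units). Artifacts are anuclear (DAPI ≈ 40),
saturated (≈1800) debris with small, irregular, low-solidity shapes.
Leukocytes share the `D | 45` marker profile; plasma-cell classes have a
larger nucleus (radius 10.5 px vs 8.5 px) and a wide cytoplasmic rim
(cell/nucleus radius ratio 2.0 vs 1.35), which keeps the rendered
membrane band geometrically clear of the perinuclear annulus.

**Frame rendering.** Nuclei are filled ellipses in DAPI; CD138/CD45 fill
the cell mask; membrane BCMA paints a 3-px band straddling the cell
boundary, perinuclear BCMA an annulus 1–4 px outside the nucleus; frames
are 1024 × 1024 by default with Gaussian background noise (s.d. 8) and
optional Poisson shot noise. Cells are placed without overlap by rejection
sampling; exceeding capacity raises an error naming the placed count. The
published 100×/2304-frame scanner geometry is emulated structurally, not
replicated.

**Incidence presets.** Per-state cells/mL for the 12 classes anchor to the
published group means where printed (e.g. `D | 138 | BCMA-Memb` rising
1.0026 → 2.7346 → 3.4532 → 3.6084 across MGUS/SMM/NDMM/RRMM) and keep the
published direction of every significant comparison (NDMM above RRMM for
perinuclear classes, CD45 shifts); unprinted entries are calibration
choices at the same order of magnitude. The cohort defaults to the
11/21/19/17 layout; the alternative 11/20/19/18 tabulation is exposed.

**Clinical covariates.** Age (state-specific medians, s.d. 8, clipped to
38–88), an M-spike-like continuous marker whose Gaussian-copula coupling
to the planted `D | 138 | BCMA-Memb` burden is set by
`covariate_correlation` (default 0.5), and Bernoulli(0.3) cytogenetic
flags. These support correlation-recovery experiments, not clinical
realism.

**What the generator does not emulate:** optical PSFs and focus drift,
staining chemistry and batch effects, cell-cell adhesion and doublets,
graded marker expression within a class (levels are two-point plus noise),
and inter-patient heterogeneity beyond Poisson counting. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under these idealized conditions, not their field performance on real
slides.

## Segmentation and features (`imaging`)

Nuclei: Otsu threshold on DAPI → hole filling → watershed on the distance
transform (markers from `peak_local_max`, min separation 5 px) → area
filter [30, 5000] px². Cells: nucleus-seeded watershed over the summed
CD138+BCMA+CD45 signal, restricted to above-Otsu pixels within
`max_expansion` (25 px) of a nucleus, with a minimum 2-px rim fallback;
bright anuclear components are kept as candidate artifacts. Features use
0-based pixel coordinates (x = column), second-central-moment
eccentricity, raw-intensity medians and MADs over the cell mask, and BCMA
band scores: membrane = median over the outermost 3 px of the cell mask,
perinuclear = median over a 3-px band just outside the nucleus (both
configurable; they match the renderer's geometry by construction, and
real-data users should retune them).

## Rare-event detection (`raredetect`)

Features are robust-standardized (median, 1.4826 × MAD; s.d. fallback when
the MAD collapses; constant features dropped), projected by PCA keeping
the smallest k with cumulative explained variance ≥ 0.95, and each event's
Euclidean distance to the coordinate-wise median cell in PC space is
computed. With T the `distance_quantile` (99.5) percentile of those
distances:

* candidates (distance ≥ T) are clustered hierarchically; the default
  complete linkage cut at height T yields exactly the documented rule
  "clusters whose internal maximum distance ≤ T" (ward/average/single
  remain selectable);
* a cluster is flagged rare when it has between `min_cluster_support` (3)
  and `max_rare_cluster_size` (max(10, 0.1%)) members and its centroid
  lies beyond `cluster_margin × T` (margin 1.5);
* any single event beyond `cluster_margin × T` is flagged outright (when
  T degenerates to 0 the `singleton_quantile` percentile substitutes).

The margin exists because a bare percentile rule flags a fixed fraction of
the background's own distance tail; the factor 1.5 sits above the expected
maximum of ~50,000 chi-distributed background distances while staying far
below the ≥6 robust-s.d. displacement that defines a planted rare event.
Ties at every threshold resolve inclusively (≥), favoring sensitivity.
Setting `max_rare_cluster_size = 1` disables clustering and reduces the
screen to a pure distance-threshold rule, which is the brute-force audit
mode used in tests. At desk-scale cohorts the rare fraction is far larger
than on real slides, so the pipeline configuration lowers
`distance_quantile` to 90 and allows clusters up to 20% of events; these
are deliberate scaled-down analysis settings, echoed with
`provenance: repo-default` in run reports.

## Artifact curation (`artifactfilter`)

A histogram gradient-boosting classifier is grid-searched over
hyperparameters and morphometric feature subsets with stratified 5-fold
CV (the fold count is a package default; the model-search budget — grid ×
subsets × folds — is what "iterations" counts). The best mean-accuracy
configuration is refit on all data; events are kept when
P(cell) ≥ 0.90. Class imbalance is handled by stratification only.
Training sets default to 2,000 labeled events (a scaled stand-in for a
manually curated archive of tens of thousands). Serialized models embed a
schema hash checked on load.

## Phenotyping (`phenotype`)

Positivity is median intensity ≥ cutoff, inclusive. Default cutoffs are
estimated per sample from the background-dominated population:
median + 5 × 1.4826 × MAD for CD138 and BCMA; half the background median
for DAPI (every cell is nucleated) and CD45 (the background itself is
CD45-bright, so a high-quantile rule would be circular — the cutoff
separates bright leukocytes from dim plasma cells). BCMA is one
three-state axis: positive events are membrane-localized when the
membrane-band score is ≥ 1.2 × the perinuclear score, perinuclear for the
reverse, otherwise the larger score wins with exact ties going to
membrane. Only this 2 × 3 × 2 factorization yields exactly 12 classes.
DAPI-negative events are non-cells and are excluded (the pipeline keeps
the rows with an empty class so stage counts stay comparable). "Total
Cells" includes all 12 classes, DAPI-only included; a stricter definition
is a one-line filter on the class column. The three-peak structure of
total BCMA intensity is treated as an observation, not a calling rule.

## Enumeration and statistics (`enumstats`)

cells/mL = count × (CBC nucleated / analyzed cells) / blood volume,
evaluated in exact rational arithmetic (`fractions.Fraction`) before a
single float conversion. The Wilcoxon rank-sum engine reports the rank
sum, a tie-corrected standardized z, and a two-sided p defined as
P(|W − E| ≥ |w − E|): exact by an integer dynamic program over rank-sum
counts when the combined n ≤ 50 without ties, exact by full enumeration
over midrank assignments when ties are present and n ≤ 16, and a normal
approximation with tie correction and 0.5 continuity correction otherwise
(degenerate all-equal inputs give p = 1). Disease-state pairs are compared
per class/aggregate with group means on the cells/mL scale and no
multiplicity correction — each comparison stands alone, as in the
reference procedure — with a Benjamini–Hochberg column emitted only as a
convenience. Clinical associations use Spearman (average-rank ties) for
continuous/ordinal variables and the Wilcoxon z for binary ones, the sign
positive when burden is higher in the variable's ==1 category;
constant or all-missing variables are skipped with a log entry. UMAP
embeddings (2-D, seeded, exact single-threaded mode) and Gaussian-KDE
density summaries cover the seven morphometric parameters.

## Prediction (`predict`)

Binary tasks over disease states (precursor {MGUS, SMM} vs overt
{NDMM, RRMM}; precursor vs NDMM; MGUS vs SMM) with the 12 classes + 5
aggregates as features. Univariate: per training fold, the threshold
maximizing training accuracy (accuracy ties broken toward the pooled
median) scored on the held-out fold. Multivariate: decision tree or
random forest (500 trees by default; repeated-cohort experiments use 100
for speed), stratified 5-fold CV repeated 20 times, impurity importances
averaged over folds. Accuracy is plain fraction-correct and always
held-out — the reference study does not state whether its accuracies were
cross-validated; this package always cross-validates, so its numbers are
conservative relative to resubstitution. An optional `groups` argument
switches to stratified group CV to keep replicate samples in one fold.
Constant features fall back to majority-rate prediction with a warning;
single-class labels raise.

## Reproducibility and problem sizes

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; fixed seeds give bit-identical
frames, tables, models and pipeline artifacts (verified by SHA-256
checksums over two independent runs). The repeated-cohort experiments in
the test suite and acceptance script use 15 samples per state with 600
background events per sample, 3 replicates of the 50,000-event recovery
problem, and 40–100 cohort seeds — sizes chosen so the full battery runs
in minutes on a single CPU while keeping every statistical check
well-powered.

## Known limitations

* The detection feature space is the generator's ~16 morphometric/
  intensity features, a stand-in for the much larger proprietary feature
  sets of production rare-cell pipelines.
* Incidence presets are calibrated to printed group means and directions;
  the published per-state distributions beyond means are unknown, so
  cohort-level magnitudes (p-values, accuracies) are properties of this
  simulation, not reproductions of the study's cohort.
* The curation and channel-classification models of the real assay were
  trained on manually curated slides; the package's models are trained on
  synthetic labels and make no claim about real-slide sensitivity or
  specificity.
* Survival analysis, additional flow-cytometry markers and ingestion of
  the deposited imaging archive are out of scope.
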