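# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what its synthetic-data tests do and do not establish
about real data.

## Data model and units

A sample is a 10-cell pool of laser-captured cells of one type (or one
cecal specimen). Measurements are qPCR cycle thresholds (Ct, PCR cycles);
one cycle is a two-fold change in template, so Ct is inherently log2-scale
and all downstream arithmetic stays on that scale. Non-detects are missing
values, never zeros and never imputed: a failed reaction carries no
quantitative information, and substituting a ceiling Ct (a common practice)
would bias −ΔΔCt toward the ceiling. All downstream statistics use
pairwise-complete observations.

The design is hierarchical: treatments (Placebo, Morphine, Naltrexone,
Withdrawal) contain animals (4 per treatment), animals contain replicate
pools per cell type. The animal is the biological replicate.

## Quality control

* **Batch-failure rule.** An assay whose per-batch non-detect fraction
  reaches `failure_rule` (default 1.0, i.e. complete failure) in *any one*
  batch is excluded from the entire dataset — an assay that was
  contaminated or mis-loaded on one array cannot be trusted to be
  comparable on the others. The rule is deliberately all-or-nothing across
  batches and idempotent.
* **Sample QC.** Samples are dropped when their missing fraction exceeds
  `max_missing_frac` (default 0.3) or any housekeeping Ct leaves
  `hk_ct_range` (default 5–35 cycles, guarding against too little or too
  much input). These thresholds are explicit configuration: published
  descriptions of "strict quality control" rarely quantify them, so the
  package never hides them.
* **Detected-but-implausible Ct** (outside 0–40 by default) warns rather
  than drops; whether such values are artifacts is a judgment call the
  package leaves to the analyst.
* **Marker validation** checks that each cell type's own marker (NeuN for
  neurons, Maf for microglia, Gfap for astrocytes) has the strictly
  greatest median among the marker assays within that cell type's samples.
  It must run on globally centered (or −ΔCt) values: per-cell-type
  centering zeroes every gene's within-type median by construction and
  destroys the contrast.

## Reference-gene stability and normalization

Candidate housekeeping assays are scored by (a) raw Ct variance and (b) the
geNorm M value — for candidates j, k the pairwise variation
V_jk = SD over samples of (Ct_j − Ct_k), and M_j is the mean of V_jk over
partners. Because Ct is already log-scale, V_jk is exactly the SD of the
log expression ratio of the original geNorm formulation. Iterative
exclusion repeatedly removes the highest-M candidate (ties: higher
variance, then name), recording the order. Selection combines the variance
rank and M rank as an unweighted mean (no weighting is published for the
two criteria); ties go to the lower-variance assay. A designated
independent control (Gapdh by default) is normalized like any other gene
but is never selectable as a reference.

The reference mean inside each sample is the arithmetic mean of the
reference Ct values — the log of the geometric mean of the linear
quantities. Averaging on the linear scale is the classic mistake this
module documents against. Samples missing any reference assay cannot be
normalized and are dropped with a log entry.

Median centering (step two) defaults to the per-cell-type scope in the
orchestrated brain pipeline, because the three cell-type panels are
effectively separate datasets; global scope is the default for standalone
use and for the cecal panel. Either way the per-gene median over the scope
is exactly 0 afterward, and sample-wise Ct shifts (input-amount artifacts)
cancel exactly in −ΔCt — both identities are tested to 1e-12.

## Differential statistics

The nested ANOVA tests treatments against the animal stratum. The default
`animal_means` method collapses pools to animal means and runs a one-way
ANOVA across treatments on those means; it handles unbalanced pools
(unweighted collapse — the animal, not the pool count, is the unit). The
`balanced_ems` method computes the classical expected-mean-square ratio
F = MS_treatment / MS_animal(treatment) with df (T−1, A−T); on balanced
data the two are identical (tested to 1e-10). The package also ships the
deliberately wrong `pooled_anova` for demonstration: with animal-level
random effects (SD 0.5 vs residual 0.5), pooling inflates the 5% test to
~65% false positives while the nested test stays calibrated — the reason
the nested design exists.

Degenerate inputs: all-identical values return F = 0, p = 1; a zero
denominator mean square returns p = NaN with a warning, and NaN p-values
are excluded from BH adjustment with a logged count.

Microbial differential abundance fits a two-way treatment × taxon
fixed-effects model (statsmodels OLS, type-II SS) over the whole panel —
the published factor structure is not stated, so a per-taxon one-way
switch is provided — plus the two per-taxon Welch contrasts the figures
annotate (Withdrawal vs Morphine, Withdrawal vs Placebo). Significance
tiers for induced/suppressed taxa follow the figure conventions
(0.1 / 0.05 / 0.008 / 0.0009).

Multiple testing uses Benjamini–Hochberg throughout ("q" values); the
procedure is the standard step-up with monotonicity enforcement.

## Dimension reduction

PCA runs on gene-standardized −ΔΔCt (configurable to covariance PCA). The
per-gene composite weight is √(loading_PC2² + loading_PC3²): in these data
the dominant PC captures treatment-independent sample-state variation, and
PC2/PC3 form the treatment-separating plane; the root-sum-square is
invariant to PC sign flips. The PC pair is a parameter (`pcs`), since which
components carry treatment structure is an empirical fact about a dataset,
not a law.

LDA conventions matter because centroid distances depend on them, so they
are fixed and documented: S_W is the pooled within-class covariance
(divisor n − C), S_B the class-size-weighted between-class scatter
(divisor C − 1), discriminants are eigenvectors of S_W⁻¹S_B scaled to
unit pooled within-class variance (wᵀS_W w = 1), ordered by eigenvalue,
with the largest-magnitude gene loading forced positive. A ridge of
1e-6 × trace(S_W)/p stabilizes near-singular scatter. Centroid distances
are Euclidean in the full (C − 1)-dimensional discriminant space (for 3
classes this equals the 2-D plotted space). Distances under this
convention are invariant to invertible linear transforms of the gene space
(tested); an implementation with a different scaling convention will
differ by a global factor, leaving distance *ratios* intact.

With only 4 animals per treatment, even null centroid distances are well
above zero on the whitened scale (class-mean noise is O(σ_animal/√4) per
gene across ~46 genes), so separation claims should be read as ratios
against the Placebo–Morphine baseline, not absolute distances.

## Correlation networks

Within one condition (treatment × cell type), every gene pair gets a
Pearson r over pairwise-complete samples (floor `min_pairs` = 5, pairs
below it untested and logged), a two-sided p from the t transform with
df = n − 2, and a BH q over all tested pairs *within that condition* —
per-condition adjustment matches the one-network-per-panel presentation.
Edges require q < 0.001 and carry r, |r| (weight), and sign; nodes carry
the condition median −ΔΔCt. Zero-variance genes are excluded from testing
but kept as isolated nodes so condition summaries share a gene universe.
Degree summaries and condition deltas (e.g. Withdrawal − Morphine) follow
the handshake lemma by construction and are tested for it.

## Bimodal subphenotypes

No published test accompanies the density-plot observation that some genes
split a condition's samples into high/low groups, so the package uses a
transparent default: fit 1- and 2-component Gaussian mixtures
(deterministic k-means++ initialization from the given seed, ≤500 EM
iterations, tolerance 1e-8, 3 restarts) and call bimodality when
BIC(1) − BIC(2) exceeds `criterion_threshold` (default 6, a conventional
strong-evidence margin) AND both components hold at least
`min_group`/n weight AND both split-side subgroups have ≥ `min_group`
(default 3) samples. The split point is the equal-posterior boundary
between the component means (Brent root-finding; midpoint fallback when
heavy overlap leaves no crossing). An explicit user-supplied cut can
override the model split. Too-small or constant inputs return a
non-bimodal call with a status string, not an exception.

Calibration facts worth knowing: at n = 60 the BIC-6 margin detects a
component-mean separation of 4 units at σ = 0.5 essentially always, but a
separation of only 4·σ (2 units) is near the information limit — expected
2ΔLL ≈ n·ln5 − 2n·ln2 ≈ 13.4 against a penalty of 3·ln60 ≈ 12.3 — and is
found only ~80% of the time. False-positive calls on unimodal nulls stay
≤5%. Clustered noise (animal effects) can occasionally mimic bimodality in
ordinary genes; calls on real data warrant inspection of the density plot.

## Microbiome ratio

Phylum medians F and B are taken from the dedicated phylum-level assays
(not aggregated over member taxa, matching how such tables report single
medians). The normalization factor NF = 1 − F is recomputed per treatment —
it is an anchor that fixes the Firmicutes side of the displayed ratio to
exactly 1, not a constant; the identity F + NF = 1 and the invariance of
the right-hand side under joint F/B shifts (only when NF is recomputed)
are both tested. The published table's NF row is consistent with NF = 1 − F
in all four columns, but the construction is reverse-engineered from the
arithmetic, not stated in prose; an explicit NF override is accepted. A
non-positive B + NF makes the ratio undefined and is flagged, never
clipped. Display rounding is half-even at 2 decimals; the Naltrexone
column is sensitive to the rounding convention (computed 0.425, printed
0.42 — consistent with half-even, not half-up).

## Synthetic data generator

The generator emulates the study conditions: 3 treatments × 4 animals ×
8 pools per animal per cell type for the brain panels (the brain cohort
has no Naltrexone-alone arm; the cecal panel has all 4 treatments with one
sample per animal), 46 measured genes plus 5 housekeeping candidates with
graded noise (Ldha/Actb planted most stable at SD 0.10; Gapdh the
never-selectable control), treatment effects planted in −ΔΔCt units and
mapped to Ct by sign inversion, animal random effects (SD 0.3), residual
Ct noise (SD 0.5), a per-sample latent state factor with heterogeneous
positive gene loadings (SD 0.6, loadings U(0.3, 1)) that reference
normalization cannot remove and that forms the dominant treatment-free
principal component, a shared activation factor across the inflammatory
genes in withdrawal astrocytes (SD 1.0) driving their dense correlation
network, a planted Mapk1 bimodal split (gap 3.0, equal weights) in
withdrawal neurons, cell-type markers at +3 units, and logistic non-detect
dropout in realized Ct (midpoint 37 cycles, scale 1). Effect sizes follow
the qualitative published pattern (withdrawal shifts the inflammatory
program; morphine ≈ placebo; astrocyte effects scaled 1.3×); they are
illustrative defaults, not inferential claims.

The Table-1 calibration deserves a note: global median centering subtracts
each gene's overall median, so planting *group-constant* shifts can never
reproduce prescribed post-centering group medians exactly. The noise-free
construction instead plants per-sample values whose group medians equal
the targets *and* whose overall median is zero; it requires the targets to
split half negative / half positive over equal-sized groups (true for both
phylum rows of the published table) and raises otherwise.

What passing synthetic tests do **not** show: the generator draws Gaussian
noise with planted factor structure — real single-cell qPCR has
heavier-tailed noise, amplification-efficiency differences between assays,
batch-by-gene interactions, and non-random dropout beyond a smooth
logistic in Ct. Recovery of planted truth validates the estimators'
logic and calibration, not their behavior under every real-data pathology.

## Problem sizes in tests

The test suite runs the published calibration checks at the stated sizes
(nested-ANOVA null: 1000 replicates; network FDR: 500 replicates of
20 × 40; bimodality and reference-pair recovery: 200 and 60 replicates)
and scales exploratory checks down (e.g. 30 replicates for shift
recovery); each test states its size. The full suite completes in about a
minute on one CPU.
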