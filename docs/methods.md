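# Methods

## Co-expression module model

Modules are defined operationally, not generatively: given a gene panel and a
cell population, the pipeline computes the pairwise Spearman correlation
matrix (midrank ties) across cells, treats each gene's row of coefficients as
its *correlation profile*, computes Euclidean distances between profiles,
clusters them with average-linkage agglomeration, and cuts the dendrogram at
a fixed cophenetic distance (default 1.65 for chemokine panels in cancer
cells, 1.5 for receptor panels in leukocytes). A flat cluster qualifies as a
module when it has at least two genes and its mean within-cluster pairwise
Spearman *r* exceeds 0.15; everything else is reported as unassigned.
Profile-space clustering (rather than clustering on 1 − r directly) groups
genes by the *pattern* of their correlations with the whole panel, which is
robust to uniformly weak but consistently structured correlations.

Implementation notes: zero-variance genes in the selected population get
*r* = 0 against all partners, are flagged, and are excluded from clustering
(a constant gene carries no rank information; giving it distance-0 profiles
would glue it to arbitrary genes). Singleton flat clusters are never modules
(mean pairwise *r* is undefined on one gene). Module numbering follows the
panel order of each cluster's first gene, so output is deterministic and
invariant to input gene order up to relabeling.

Robustness is quantified by leave-one-patient-out analysis: the full
correlation-and-clustering procedure is repeated with each patient's cells
removed, and each gene pair is scored by the fraction of iterations in which
both genes land in the same module. Genes unassigned in an iteration count
as not co-clustered; iterations with fewer than three cells are skipped and
the denominator adjusted.

## Receptor–ligand permutation test

For chemokine module C and receptor module R, the observed statistic is the
number of curated ligand→receptor pairs with ligand ∈ C and receptor ∈ R.
The null preserves the module size structure: each iteration independently
permutes the gene→module assignment among the genes currently assigned to
any chemokine module, and likewise among receptor-module genes (unassigned
genes are outside the shuffle universe — keeping the marginal module
structure fixed is the standard exchangeability argument). All module pairs
are recounted from the same shuffle, giving a joint null; *p* is the plain
proportion of 10,000 iterations (default) with a count ≥ observed. A
`pseudo` option switches to the (k+1)/(n+1) estimator, which cannot return
exactly 0. An exhaustive enumerator over all distinguishable assignments
(multiset permutations, refused above 10⁶ combinations) provides exact tail
probabilities and serves as the oracle in the test suite; the Monte-Carlo
*p* agrees with it to within 3 binomial standard errors at 10⁵ iterations,
and under a random-pairing null the *p* distribution is approximately
uniform (fraction of *p* ≤ 0.05 measured at ≈ 0.02–0.03 over 500 simulated
datasets).

The shipped pairing table is a curated set of canonical human chemokine →
receptor couplings with a mandatory provenance column; it is fully
user-replaceable, and any count-valued conclusion is conditional on the map
used.

## Module scores, "expressed" flags, and infiltration

The score of module M in patient P is the mean expression of M's genes over
P's population cells (missing when the patient has no such cells). The
binary "module expressed in patient" call has no canonical threshold; the
default builds a per-module null by re-drawing same-sized random gene sets
from the panel and flags scores above the null's 75th percentile. This is
scale-free across modules and is exposed as configuration (`n_null`, or an
explicit threshold). Module–infiltration association uses Spearman *r* per
(module, leukocyte type) with pairwise deletion of incomplete patients,
two-sided *p* from the exact permutation distribution for n ≤ 8 and the
t-approximation above that; constant columns are reported missing, not zero.

## Preprocessing rules

Gene filtering retains genes detected (nonzero) in ≥ 10 cells (default).
Highly variable genes are ranked by dispersion (variance/mean) z-scored
within 20 equal-frequency mean-expression bins; bin edges are values
(quantiles of the mean), so genes with identical means always share a bin,
and a bin whose dispersions are all equal falls back to raw dispersion with
a logged warning. Ties break lexicographically on gene id. The bin count
targets genome-scale matrices; for small panels it should be reduced
(the tests use 3 bins on a 70-gene panel). PCA runs on per-gene centered
(not variance-scaled) values; the number of PCs is the smallest count
explaining ≥ 25% of total variance, floored at 50 and capped at 100, with a
final cap at the matrix rank. Clustering is Leiden modularity on a
Jaccard-weighted kNN graph (Euclidean in PC space), deterministic given a
seed; the community detector is pluggable — what the module guarantees is
the *stability criterion*: the selected k is the smallest whose partition
has pairwise Rand index > 0.8 against the next larger k values.

A caveat documented deliberately: modularity optimization subdivides large
homogeneous point clouds (it strictly prefers splitting a blob of ~100
points at k = 15, and even near-complete graphs admit positive-modularity
splits). Exact cluster-count recovery therefore holds only when blob size is
small relative to k (≲ 1.7k in our fixtures), with the single-cluster case
reached only in the complete-graph limit k = n − 1. Downstream conclusions
should rest on the stability criterion, not on raw community counts.

## Linear-quadratic survival and RBE

Surviving fractions come from colony counts via plating efficiency
(SF(D) = (colonies_D/seeded_D)/PE with PE from the dose-0 record, replicates
kept separate). The LQ model ln SF = −αD − βD² is fit by least squares in
log-survival space with α ≥ 0 [1/Gy], β ≥ 0 [1/Gy²] enforced through
non-negative least squares (an exact constrained solution, no iteration
tolerances); replicates are pooled rather than averaged first, preserving
the error structure, and an active constraint is flagged. Weighting is equal
by default with an optional per-point weight vector. The iso-survival dose
uses the cancellation-free root D_s = 2t/(α + √(α² + 4βt)), t = −ln s, which
stays accurate as β → 0 (the naive quadratic formula loses several digits
there). RBE_s = D_s(reference)/D_s(test); s = 0.10 by default.

Simulated recovery under multiplicative lognormal noise (σ = 0.1, doses
0–8 Gy, 3 replicates) gives a median relative error on α of ≈ 3–5% over
20 curves, and nominal 95% t-intervals from the fit covariance cover the
true α in 88–99% of simulated experiments.

## SASP score and migration index

The SASP factor score is the mean fold change (treated/control) over the ten
established SASP factors CCL2, CCL4, CCL5, CXCL1, CXCL8, CXCL10, ICAM1,
IL1a, IL6, TNFa, computed per replicate and summarized as mean ± SD across
replicates; unlisted analytes are ignored and missing factors logged. The
migration index first normalizes migrated-cell counts to acquired bead
counts (count × ref_beads/sample_beads, with the maximum bead count as the
fixed reference — any fixed reference cancels in the ratio) and then divides
the normalized test count by the normalized control count per immune subset;
subsets with a zero control count are reported missing.

## SA-β-Gal image quantification

DAPI processing: rolling-ball background subtraction (grayscale opening by a
ball structuring element, output clipped at 0), Gaussian blur at the chosen
radius, maxima detection with *topographic* prominence semantics — a
maximum counts only when it stands at least `prominence` above the saddle
connecting it to a higher peak (h-maxima transform; dialects of
"prominence" differ, so this is pinned down deliberately) — thresholded at
`min_threshold`, and one region per accepted maximum by watershed flooding
restricted to above-threshold pixels. Exactly equal twin peaks are a
degenerate tie under this definition and may count separately; real images
never produce exact ties.

Stain processing: the bright-field RGB image is mapped to a blue-dominance
score B − (R+G)/2 (SA-β-Gal product is blue; the transform is pluggable,
e.g. HSV-based alternatives), background-subtracted and blurred the same
way, and stain maxima/regions extracted with stain-specific threshold and
prominence. Nucleus labels are expanded by `enlarge_px` without overlap
(each cell keeps its own territory); a nucleus is positive when its enlarged
territory contains at least `min_positive_area` px² of a stain region
validated by an accepted maximum. Percent senescent = 100 × positive/total,
missing when no cells are found; batch mode pools conditions as
Σ positives / Σ totals. Coordinates are 0-based row/col, areas in px², no
physical calibration. With `quantile_thresholds=True` the thresholds are
quantiles and the prominences fractions of the processed intensity range,
making counts invariant to uniform intensity rescaling. Defaults
(blur 2 px, threshold 800, prominence 500 on 16-bit DAPI; stain threshold
25, prominence 15 on 8-bit dominance; min area 100 px²; enlarge 10 px;
rolling ball 25 px) suit the synthetic fixtures; on real batches they are
meant to be tuned per acquisition, as interactive use of such quantifiers
normally does.

## Synthetic-data generators

*Expression.* A latent-factor Gaussian model on the log-normalized scale:
cells of module M share a per-cell factor f ~ N(0, 1), and each module gene
is λf + √(1−λ²)·ε with loading λ (default 0.8) and noise ε ~ N(0, noise_sd),
then shifted by +3 marginal SD and clipped at 0 to mimic non-negative
log-normalized expression (a documented distributional approximation — the
clip touches ~0.1% of values). Background genes are pure noise. With
noise_sd = 1 the within-module Pearson correlation of the underlying
Gaussian is exactly λ², and the expected Spearman correlation follows the
Gaussian rank relation (6/π)·arcsin(λ²/2) ≈ 0.62 at λ = 0.8 — this is the
analytic check the tests use. Patient labels are round-robin (each of
n_patients gets exactly n_cells_per_patient cells). An optional
`module_activity` map restricts a module's factor to chosen patients;
active patients additionally receive a factor mean of `activity_mean`
(default +1 SD), because "module expressed in a patient" requires elevated,
not merely correlated, expression. A count-level negative-binomial model
was deliberately not used: all downstream statistics operate on rank
correlations of log-normalized values, and the Gaussian factor model is
analytically checkable. The generator does not simulate UMI counts, ambient
RNA, doublets, batch effects, or realistic per-patient cell-count
distributions (cell count per patient is a parameter), so passing tests
demonstrate correctness of the *statistics*, not robustness to those
artifacts.

*Survival.* SF = exp(−αD − βD²)·exp(ε), ε ~ N(0, σ²) multiplicative
lognormal replicate noise; σ = 0 is bit-reproducible and matches the closed
form to 1e−12.

*Images.* Nucleus centers are rejection-sampled at a minimum separation of
2.5 × nucleus radius (bounded retries; failure raises). DAPI is 16-bit:
Gaussian-profile nuclei (amplitude 4000, σ = radius/2) on a noisy dark
background. Bright-field is 8-bit RGB: uniform light background with a
perinuclear blue-dominant disc of radius 1.8 × nucleus radius rendered
around each designated positive cell — tight enough that a stain disc never
engulfs a neighboring nucleus at the minimum separation, which keeps
proximity-based positivity well defined. Truth (total, positive, centers,
mask) is returned exactly as rendered.

*Cytokines.* Lognormal replicate noise around specified fold changes, with
analyte names from the SASP factor list.

All generators take a single integer seed; no global random state is used
anywhere in the package.

## Problem sizes used in tests and the acceptance script

Module recovery: 10 seeds × (5 modules × 6 genes + 40 background, 2,000
cells over 20 patients). Permutation exactness: a 3,360-assignment
configuration enumerated exhaustively vs 10⁵ Monte-Carlo iterations.
Calibration: 500 random-map datasets at 1,000 iterations each. LQ recovery:
20 curves (doses 0–8 Gy, 3 replicates, σ = 0.1). Imaging: 20 fixtures of
50–150 cells at positive fractions 0–0.5 on 384² frames. Leave-one-out:
8 patients × 100 cells, 3 modules × 5 genes. These sizes were chosen so the
statistical targets are well resolved while the whole suite completes in
about a minute of CPU.

## Known limitations

- Module "expression" flags depend on a declared default (75th percentile of
  a gene-label-shuffled null), not on a published rule.
- Receptor–ligand counts are conditional on the pairing table; the shipped
  map is curated and replaceable, not authoritative.
- The blue-dominance stain transform is a stated substitute for an
  unpublished RGB criterion and is validated against synthetic truth only.
- Community counts from modularity-based clustering are not trustworthy per
  se (see the preprocessing caveat); use the Rand-stability criterion.
- The LQ fit assumes log-additive noise; count-based (Poisson) weighting is
  available only through the optional weight vector.
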