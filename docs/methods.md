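# Methods

`cordatlas` re-implements, as a tested library, the computational pipeline of a
developmental single-cell transcriptomics analysis of the mouse spinal cord:
cell identities are read off a binary marker "knowledge matrix", spatial gene
expression patterns are found by exhaustive combinatorial model selection with
negative-binomial likelihood-ratio tests, neuronal subtypes emerge from
iteratively filtered co-expression gene modules, and a neurogenesis pseudotime
is the first principal component of a curated gene space. Every stage is
exercised end-to-end on synthetic data with planted ground truth; nothing is
downloaded.

## Count model and quality control

Counts are UMIs: non-negative integers in a sparse cells × genes matrix
(an `AnnData`). Sequencing depth is equalized across samples by per-cell
hypergeometric thinning of UMI totals until every sample matches the
lowest-depth sample's mean counts per cell. This operates on the UMI matrix
and is an approximation of read-level subsampling, which happens upstream of
the matrices we ever see. Cells are then discarded when more than 6% of their
UMIs come from mitochondrial genes (flagged by the configurable name prefix
`mt-`) or when they detect fewer than 500 genes ("detected" = count > 0).
Both boundaries are inclusive for retention: a cell at exactly 6% mito or
exactly 500 genes stays. The pipeline default is equalize-then-filter.

## Identity assignment

The knowledge matrix is a binary identities × markers table at three levels:
coarse tissue, 13 progenitor domains (floor plate, p3, pMN, p2, p1, p0,
dp6–dp1, roof plate) and 12 neuronal classes (V3, MN, V2a, V2b, V1, V0,
dI6–dI1). Marker profiles are binarized at two UMI counts (a count of exactly
2 is "on") and each cell takes the identity of the row at minimal Euclidean
distance, tissue first, then domain/class within progenitors and neurons. An
identity may own several alternative rows — e.g. early neurons that still
carry the pan-progenitor marker, or motor neurons identified through either
Isl1 or the cholinergic transporter Slc18a3 — and the cell-to-identity
distance is the minimum over rows. Ties are flagged ambiguous and resolved
deterministically to the first row in table order. A cell whose best row is
no closer than the all-zero profile is labelled `unclassified` instead of
being force-assigned; this is the default maximum-distance rule.

The shipped fixture matrix is synthetic: marker names follow the standard
dorsoventral patterning vocabulary (Olig2 for pMN, Dbx1 for p0, Vsx2 for V2a,
…), but the rows were constructed for the simulator and are not transcribed
from any curated supplementary table. Analyses of real data should supply
their own TSV knowledge matrix.

Doublet load is estimated as the fraction of cells positive for two disjoint
lineage signatures (neural and mesodermal by default), where "positive" means
at least half of the signature's markers are on after binarization.

## Combinatorial pattern discovery

For N domains, all 2^N − 2 ordered bipartitions into a "positive" combination
and its complement are scored per gene (8190 partitions from 13 progenitor
domains; the model universe including the trivial empty and full combinations
is 2^13 = 8192, and 2^12 = 4096 for the 12 neuronal classes). Each test is an
approximate χ² likelihood ratio with one degree of freedom: the null fits one
negative-binomial mean to all cells, the alternative one mean per side, both
sharing a fixed per-gene dispersion α (variance = μ + αμ²) estimated once by
the method of moments across all cells, falling back to Poisson when the
moment estimate is non-positive. With fixed dispersion the group MLE mean is
the sample mean, so each partition's log-likelihood assembles from per-domain
sufficient statistics (count sums, cell counts, Σ lgamma(x + 1/α)) and the
whole scan is a (2^N − 2) × N matrix product per gene rather than 8190
separate fits — roughly three orders of magnitude cheaper, with identical
results (verified against a brute-force likelihood grid search).

The gene is associated with the partition of maximal alternative likelihood.
Every unordered bipartition ties exactly with its reversed orientation (the
implementation guarantees bit-identical tie values), and ties resolve to the
smaller positive side, then lexicographically — parsimony plus determinism.
Results are trimmed by four filters: P < 10⁻⁹ and log2 fold-change > 2
(strict), and on the positive sample a mean of ≥ 0.2 UMI and an
expressed-cell ratio ≥ 10% in progenitors / 8% in neurons (inclusive;
"expressed" = count > 0). The fold-change uses a pseudo-mean of 1/(cells in
group) per side to stay finite on empty means. The raw-P cutoff is used as
published, with no FDR correction; it is exposed in `FilterConfig`.

## Gene modules

From the expressed genes, those with positive Spearman correlation ≥ cutoff
to at least 3 other genes are pre-selected, lowering the cutoff along a
schedule (0.50 down to 0.05 in steps of 0.05) until ~2000 genes (configurable)
are retained. The loop then iterates:

1. genes are clustered on the Spearman dissimilarity (1 − ρ) with Ward's
   criterion and the tree is cut into `n_modules` groups (200 for a
   ~2000-gene selection; after filtering the count scales down with the
   surviving gene fraction, minimum 2);
2. per-cell module scores (mean of z-scored log(count+1) over module genes)
   are binarized with a parameter-free adaptive threshold — the split of the
   sorted values minimizing total within-group sum of squares, the 1-D
   two-class (Otsu-type) criterion; modules expressed in fewer than 5 cells
   are excluded;
3. gene-level z-scored log levels are binarized the same way (recomputed each
   iteration), and modules in which fewer than 40% of the gene-level calls
   are true among module-expressing cells are excluded.

Genes of excluded modules are dropped and the survivors re-clustered until no
module is excluded. The gene count strictly decreases otherwise, so the loop
terminates; the module contains no randomness and reruns are bit-identical.
Constant genes (undefined ρ) are treated as uncorrelated and flagged;
zero-variance genes get z = 0; a constant score vector binarizes to all-false.

## Subtypes

Cells of one neuronal class are clustered with Ward linkage on Euclidean
distances between z-scored log levels of curated-module genes; the clade
count k is explicit user input, as in the original curation step, with no
automatic model selection. Mean embryonic stage per clade is the mean of the
numeric part of the stage label. Clades can be flagged against expected-sign
marker rules (e.g. progenitor markers high inside a neuronal class); the
violation threshold is ±0.5 on the clade-mean z score.

## Pseudotime

A dataset balanced over (stage, dorsoventral position) strata — strata under
25 cells are taken whole, the rest subsampled without replacement to the
smallest eligible stratum — defines the PC plane. The gene space is the union
of the modules containing the four anchors (pan-progenitor Sox2, pan-neuronal
Tubb3, early-progenitor Lin28a, late-progenitor Fabp7), purged of genes
differentially expressed against dorsoventral position (omnibus NB LRT,
χ² with N_positions − 1 df, P < 5·10⁻¹⁵). Position pairs each progenitor
domain with its daughter class (p3/V3 … dp1/dI1, floor/roof plate excluded as
progenitor-only); testing against raw identity labels instead would confound
maturity with position and reject every differentiation gene.

Counts are median-ratio normalized — reference = per-gene geometric mean over
the fit cells, computed on genes detected in every fit cell, with a
total-count fallback below 10 such genes — and size factors always come from
the full transcriptome, never from the curated subset, so that subsetting
cannot normalize a gene against itself. After log(1 + normalized count), PCA
is fitted on the balanced matrix and the whole dataset is projected with the
fitted eigenvectors. PC1, oriented so the pan-neuronal anchor increases along
it, is the pseudotime.

Per (domain, gene), expression along pseudotime is smoothed by least squares
on a natural cubic spline with 3 degrees of freedom (intercept plus three
basis columns; knots at the 0, ⅓, ⅔, 1 quantiles of the domain's pseudotime).
Profiles with fewer than 20 expressing cells, or domains too small to
constrain the fit, are set identically to zero and flagged. Each profile is
evaluated on its own domain's pseudotime range; beyond it the natural spline
is unsupported linear extrapolation and is not reported.

## Synthetic data: what it emulates and what it does not

The generator plants known structure under negative-binomial noise with a
fixed per-dataset dispersion (default α = 0.3, baseline mean 0.3 UMI —
typical droplet sparsity): domain identities drawn from stage-resolved
proportions (progenitor share of the neural compartment falling ~72% → ~16%
across e9.5–e13.5, motor neurons early, dI4/dI5 late); marker genes at mean
10 UMI in their identity and 0.05 elsewhere, so binarization at 2 UMI is
informative but noisy; pattern genes with baseline × 2^effect means in their
positive domains; module genes at mean 5 in a planted cell subset; per-cell
latent time t ∈ [0, 1] (progenitors 0–0.55, neurons 0.45–1) with log-linear
ramp genes, Gaussian transient pulses, and optional DV-biased trajectory
genes; doublets as element-wise sums of two cross-lineage parents at a
configured rate; mitochondrial fractions from Beta(2.5, 97.5) (mean 2.5%, a
small tail beyond the 6% cutoff).

It does **not** model ambient RNA, batch or replicate effects, gene–gene
correlation beyond the planted structure, gradual spatial boundaries, or
read-level artifacts. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical assumptions, not robustness to every
failure mode of real droplet data.

Benchmark presets fix the study conditions used by the tests and the
acceptance script:

* **pattern recovery** — 2000 progenitor cells uniform over 13 domains, 50
  pattern genes (each its own positive set of 1–6 domains, log2 effect 3)
  plus 500 null genes; precision/recall are measured over those 550 genes,
  with knowledge-matrix markers excluded from the scan since they are
  genuinely domain-restricted by construction;
* **identity benchmark** — 5 stages × 2000 cells with an 8% mesodermal
  contaminant and 1% planted doublets;
* **module benchmark** — 800 cells, five 40-gene modules each active in 20%
  of cells, 300 sparse noise genes; the clustering granularity is set to 6
  modules — the published 200 is a heuristic for ~2000 genes of real data,
  and for a ~200-gene selection the proportional choice of a handful of
  modules is the analysis decision a practitioner would make;
* **trajectory benchmark** — 5 stages × 800 neural cells (~150 per progenitor
  domain: enough data at the sparse late end of each domain's time window to
  constrain the spline boundary), 4 anchor modules of 25 genes, two planted
  DV-biased genes, three transient pulses centred at t = 0.35 with width
  0.15 — inside the progenitor window and broad enough to be above the
  resolution of a 3-df spline.

## Numerical choices and limitations

* Likelihood ties in the partition scan are exact by construction; all other
  floating-point comparisons use explicit tolerances in the tests.
* Dispersion is per-gene and shared across groups; genes with var < mean are
  fitted as Poisson. The χ² reference for the LRT is asymptotic and
  anti-conservative at very low counts; the published 10⁻⁹ cutoff plus the
  mean/ratio filters control the best-of-8190 selection effect empirically
  (a global-null test asserts a pass fraction < 10⁻³).
* The adaptive threshold places the split between distinct sorted values only
  and takes the lowest-threshold optimum on ties.
* Ward clustering follows the SciPy convention (Lance–Williams update on the
  condensed dissimilarities, the variant consistent with classical Ward under
  Euclidean input); the Spearman dissimilarity is not Euclidean, so heights
  are heuristic, as in the original R workflow.
* `equalize_depth` requires an identical gene universe across samples and
  rounds per-cell targets, so sample means match the minimum to well under
  1%, not exactly.
* The doublet estimator counts dual-signature cells; it misses within-lineage
  doublets by design, mirroring the dual-tissue signature definition.
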