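# Methods

## Morphometry

Each segmented cell is summarized by two dimensionless shape
descriptors. Elongation *E* is the ratio of the major to the minor
axis of the ellipse whose normalized second central moments match the
cell mask's; it is ≥ 1 by construction and grows with spindle shape.
The cell shape index CSI = 4π·area/perimeter² equals 1 for a disc and
falls toward 0 as a shape elongates or roughens.

Axis lengths are computed from the mask's central moments with a
within-pixel variance correction: pixels tile the plane as unit
squares, so each contributes 1/12 to the variance along each axis on
top of its center coordinate. Point-mass moments (the regionprops
default) systematically underestimate the minor axis of thin objects —
for a Gauss-digitized ellipse with semi-axes (25, 5) the point-mass
estimate of *E* is ~5.29 instead of 5, while the corrected estimate is
within 5%. Perimeter uses the Crofton (line-intercept) estimator,
which is far less biased on digitized boundaries than edge counting;
because discrete estimators can still undershoot slightly on small
discs, CSI is clamped to ≤ 1 so the documented range (0, 1] is a hard
contract.

Classification uses the published bounds with strict inequalities:
contractile iff *E* > 3 and CSI < 0.4; synthetic iff 1 < *E* < 3 and
CSI > 0.6; undecided iff 0.4 < CSI < 0.6. Shape combinations the three
classes do not cover (e.g. *E* > 3 with CSI > 0.6), boundary values,
and degenerate objects (collinear pixels, zero perimeter) are labeled
`unclassified` and excluded from the con/syn ratio rather than forced
into a class the thresholds contradict. Degenerate objects are flagged
and kept, never silently dropped.

## Segmentation

Nuclei (channel 0) are smoothed (σ = 1 px), thresholded (Otsu by
default) and connected-component labeled to give one seed per cell;
cell bodies (channel 1) provide the foreground for a seeded watershed
on inverted intensity, which splits touching cells at their intensity
ridge. A threshold is accepted only if the foreground/background mean
separation exceeds 4 background standard deviations and the foreground
covers < 50% of the field; otherwise the well is treated as blank
(empty mask with a warning), which keeps noise-only images from
shattering into spurious objects.

Two refinements matter for unbiased shape measurement. First, when
per-cell refinement is enabled the watershed mask is grown down to the
background noise floor (median + 4·MAD) instead of the global
threshold. Second, each cell is then re-thresholded at 50% of its own
peak intensity inside its watershed territory: for a blurred step edge
the half-maximum contour sits on the true boundary, which removes the
systematic dilation of bright cells and erosion of dim cells that any
single global threshold causes — a bias that propagates directly into
*E* for thin cells, since (a+w)/(b+w) shrinks quickly in the boundary
shift w when b is small. Border-touching objects are removed, as are
objects outside [40, 20000] px².

## Screen statistics

The well-level readout is ratio = (n_contractile + ½)/(n_synthetic + ½).
The half-count pseudocount keeps wells without synthetic (or without
contractile) cells finite and defined; a well with neither class gives
ratio 1 and is flagged low-information. Fold changes normalize each
treated well to the mean control ratio of its own replicate plate,
absorbing plate-to-plate effects. Hit categories layer a directional
consistency requirement over the mean-FC thresholds: a strong
contractile hit needs mean FC > 1.5 *and* FC > 1 in every replicate; a
weak hit needs mean FC > 1.2; a strong synthetic hit mirrors the weak
threshold on the down side (every FC < 1 and mean FC < 1/1.2), since
no explicit numeric down-threshold accompanies the "decreased in all
replicates" rule. Categories are mutually exclusive and exhaustive
over finite FC vectors; NaN fold changes are dropped with a warning
and at least two replicates are required.

## Differential expression

Counts are transformed to logCPM with the half-count/library+1 offset.
Note the offset breaks exact scale invariance: doubling all counts and
library sizes shifts an entry by ≈ 0.36·(1/count) in log2 units, which
is negligible for abundant miRNAs but visible at low counts.

Each miRNA is tested with a two-group moderated t. Residual variances
s²_g (d_g = n₁+n₂−2 df) are assumed to follow a scaled F distribution
around a prior (d0, s0²), estimated by moment matching on the
log-variance scale: e_g = log s²_g − ψ(d_g/2) + log(d_g/2), with d0
solving ψ′(d0/2) = var(e) − ψ′(d_g/2) via Newton inversion of the
trigamma function and s0² from the mean of e. If the observed spread
of log-variances does not exceed pure sampling noise the prior
estimate is degenerate and d0 → ∞ (full shrinkage to s0², normal
reference distribution) with a warning. Posterior variances
s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g) give
t = log₂FC/(s̃_g√(1/n₁+1/n₂)) on d0 + d_g df. This is the standard
empirical-Bayes construction and the test suite verifies exact
agreement (≈ 1e-14) with Bioconductor limma's `lmFit`/`eBayes` on the
same matrix, plus reduction to the ordinary pooled t when d0 = 0.
Mean–variance precision weights (the voom weighting layer) are
deliberately omitted: the calls operate on log₂FC and p, and the
calibration and power contracts are met without them.

p-values are BH-adjusted across all miRNAs. Volcano calls use
|log₂FC| > 0.6 with p < 0.05; the companion threshold "FC > 1.5"
printed alongside corresponds to log₂FC ≈ 0.585, an inconsistency
resolved in favor of 0.6 on the log scale. Both raw-p and FDR
significance modes are exposed (`use_fdr`), since screening practice
uses either depending on context.

## Network integration

miRNA names are normalized by stripping species prefixes and
lower-casing while preserving arm suffixes (-3p/-5p). If the same base
miRNA appears with an arm in one list and without in the other, the
intersection raises instead of silently part-matching — arm identity
changes the molecule.

Shared targets group genes by the exact number k of distinct miRNAs
predicting them. Hub scoring uses Maximal Clique Centrality: maximal
cliques are enumerated by Bron–Kerbosch with pivoting and
MCC(v) = Σ (|C|−1)! over maximal cliques of size ≥ 2 containing v;
isolated nodes (including targets absent from the interaction graph)
score 0. Scoring runs within the subgraph induced by each miRNA's own
targets — mirroring a per-miRNA interaction lookup — with a
whole-graph mode available by passing the full graph. Ties break by
MCC, then degree, then gene name, and the per-miRNA top-3 lists are
deduplicated into the hub set, so one gene can be a hub for several
miRNAs and six miRNAs can yield fewer than 18 hubs. Clique enumeration
aborts beyond a configurable budget (default 10⁶ cliques) with advice
to extract a subgraph.

The merged network takes the k ≥ 4 shared-target stratum plus the hub
set, annotates each node with role (shared/hub/both), k, best MCC and
targeting miRNAs, induces the interaction edges, and exports GraphML.
Drug mapping inner-joins network genes with a drug–gene table and
expands to (miRNA, gene, drug) triples; coverage is the fraction of
hub genes with at least one drug.

## Synthetic data

The generators emulate the study conditions at every level.

**Images.** Cells are ellipses with uniformly random orientation,
placed by rejection sampling (capped at 10,000 attempts per cell) with
a 3 px clearance enforced through exact polygon intersection tests, so
ground-truth objects never overlap. Channel 0 holds nuclei (inner
ellipses at 0.45 of the cell axes, emulating a DNA stain), channel 1
the cell bodies (emulating a lipophilic membrane stain) at intensities
uniform in 120–220 AU on a zero background. Gaussian blur σ = 1 px and
additive Gaussian read noise (σ = 4 AU) model optics and camera;
Poisson shot noise is omitted as unnecessary for exercising
segmentation. Semi-minor axes are uniform in 8–12 px: at this scale
the discretization error of moment-based axis estimates stays well
inside the 5% morphometry contract, whereas below ~6 px pixelization
alone exceeds it.

**Phenotype geometry.** Synthetic cells sample aspect ratios from
Uniform(1, 2) (true CSI 0.84–1.0). Contractile cells sample from
Uniform(6.5, 10). The lower bound matters: a smooth ellipse's CSI is a
fixed function of its aspect ratio q — CSI(3.5) ≈ 0.59, CSI(5) ≈ 0.45,
CSI(6) ≈ 0.38, CSI(6.5) ≈ 0.36 — so ellipses with q between 3 and ~6.3
land in or above the undecided CSI band and cannot be labeled
contractile by the published bounds at all. Real contractile VSMCs are
long spindles whose tapered ends push CSI lower than an ellipse of
equal aspect ratio; with plain ellipses the equivalent morphology
requires q > 6.5, which puts true CSI in 0.24–0.36 and true *E* in
6.5–10 — both with margin beyond the decision boundaries, so planted
labels are unambiguous and ≥ 95% label recovery through the full
imaging stack is a meaningful contract.

**Counts.** miRNA counts are negative binomial with constant
dispersion 0.1, gene-wise mean CPM log-uniform over log₂ CPM ∈ (1, 10),
library sizes log-uniform in 0.5–2 million, four replicates per serum
condition. A planted fraction of miRNAs has its low-serum mean
multiplied by 2^±1.5 with random sign; the truth table records every
planted log₂FC.

**Fixtures.** Target tables realize planted k-way sharing exactly
(each planted gene assigned to a uniform random k-subset of miRNAs)
plus filler genes unique to one miRNA; the interaction graph contains
the planted cliques complete plus Erdős–Rényi background edges at
p = 0.005 among non-clique genes — sparse enough that background
structure cannot out-score a planted 4-clique (MCC 6 per member) in
hub ranking, which is what makes exact planted-hub recovery a fair
contract. A gene may belong to two miRNAs' cliques (modeling a hub
shared between miRNAs) but never to both a clique and the exact-k
shared set.

**What the generators do not emulate**, and hence what passing tests
do not show about real data: cell crowding and physical contact
(cells are placed disjointly; the watershed split is exercised only on
constructed touching pairs), intensity texture (stress fibers,
chromatin), uneven illumination and vignetting, segmentation artifacts
from debris, the heavy-tailed and trended mean–dispersion relationship
of real RNA-seq, correlated miRNA families, and the name/annotation
noise of real target databases.

## Problem sizes and numerical conventions

Default verification scales: 200 rendered cells for morphometry, 50
repetitions of a 3-replicate 400-cell/well screen for hit-calling
statistics, 2000 miRNAs (4 vs 4) for null calibration and power, 200
random ≤ 10-node graphs against the brute-force clique oracle. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning; rerunning any generator or the
CLI with the same seed is byte-identical. Ratios use a 0.5
pseudocount; CSI is clamped at 1; boundary threshold values classify
as `unclassified`; hub ties break deterministically (MCC, degree,
name); BH adjustment is order-invariant.

## Known limitations

The moderated model omits voom precision weights, so very low-count
miRNAs are slightly mis-weighted relative to a weighted fit. MCC on
isolated nodes is defined as 0, which can differ from tools that fall
back to degree for clique-free nodes. The screen model has no spatial
plate effects (and no Z-factor style QC), matching the per-replicate
normalization design. Segmentation assumes one nucleus per cell and
roughly convex cells; heavily overlapping cultures would need a
different instance-segmentation approach.
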