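# Methods

senkit re-implements, as a tested pipeline over synthetic data with known
ground truth, the bespoke computations of a single-cell study of replicative
senescence: distribution-shape model selection across timepoints,
PPI-constrained co-expression networks with dense-module detection, droplet
QC rules, imaging-marker statistics, marker-gene ranking, cell-cycle scoring
and a cluster-level lineage with pseudotime.

## Count-distribution shape selection (`senkit.shapes`)

**Model.** Per gene and per timepoint, UMI counts are modelled by one of
four families: Poisson (P), zero-inflated Poisson (ZIP), negative binomial
(NB) and zero-inflated negative binomial (ZINB). All models use a log link
on the mean with biological replicate as a categorical covariate, so the
mean varies freely by replicate while the NB size θ (variance = μ + μ²/θ)
and the zero-inflation π (a point mass at zero on top of the count
component) are shared across replicates.

**Fitting.** With a saturated replicate factor the per-replicate mean MLE
has a closed form — the replicate sample mean, or for the inflated families
the sample mean weighted by the EM responsibilities of the zero atom. The
fitters exploit this: P is fully closed form; NB profiles θ by Brent search
on the log scale (bounds e⁻⁷…e¹⁶, xatol 1e-5); ZIP runs EM with closed-form
M-steps; ZINB nests the θ profile inside an EM whose (π, μ) updates are
per-replicate scalar recursions. All likelihoods are evaluated on the
per-replicate value histogram (counts are small integers), which is what
makes the parametric bootstrap affordable. Convergence: |ΔlnL| < 1e-6, at
most 200 EM iterations.

Degenerate cases: an all-zero count vector is flagged non-converged for
every family — the rate or the inflation sits on the parameter-space
boundary. Collapse guards: π̂ < 1e-4 refits the non-inflated family (the
reported fit keeps the inflated family label and parameter count, with
π = 0); θ̂ > 1e4 sets a Poisson-limit flag but keeps the family as fitted.

**Goodness of fit.** The KS statistic is D = sup|F̂ₙ − F| over the count
support, where F is the fitted replicate-mixture CDF (replicates weighted by
their cell counts). Because parameters are estimated, the p-value is a
parametric bootstrap: counts are re-simulated under the fitted parameters
with the observed replicate design, refit under the same family, and
p = (1 + #{D_b ≥ D_obs}) / (n_boot + 1). Default n_boot = 100; values below
19 are rejected (p resolution coarser than 0.05). A non-converged bootstrap
refit counts against the null (conservative). No multiplicity correction is
applied to the per-(gene, timepoint, family) screen; α (default 0.05) is
configurable.

**Selection.** Among converged fits passing the KS screen at α, the
minimum-BIC fit wins (BIC = k·ln n − 2·lnL; k = #replicates, +1 for θ or π,
+2 for ZINB). Ties break toward fewer parameters, then the fixed order P,
ZIP, NB, ZINB. The screen is evaluated lazily in ascending BIC order — once
a family passes, worse-BIC families are dominated and are not bootstrapped;
the selected family is provably identical to screening all four. If no
family survives, the gene is unassigned at that timepoint.

**Switching.** A gene's family triple across (T0, T1, T2) is classified:
stable, single transition (exactly one consecutive change), reverting
(A→B→A) or distinct triple; any unassigned timepoint makes the gene
unassigned. "Differentially distributed" genes are reverting ∪ distinct
triple — the patterns that change at both consecutive transitions. Genes
changing at a single transition are reported separately, not in that total.
Census percentages support both a per-timepoint denominator and a fixed
external one (e.g. the number of KS-passing genes).

## QC (`senkit.qc`)

Cell calling: order barcodes by library size, take the upper quantile
(default 0.99, type-7 linear interpolation) of the top `expected_cells`
barcodes, and call every barcode whose total strictly exceeds 10% of that
quantile. If `expected_cells` exceeds the number of barcodes the quantile is
taken over all of them. Gene filtering removes genes detected in fewer than
10% of cells (strict "less than": a gene at exactly the threshold is kept);
undetected genes are always removed. The filter is idempotent and reports
before/after dimensions.

## Networks and modules (`senkit.netmod`)

Edges are Spearman correlations (average ranks for ties) between expression
profiles of gene pairs present in a reference PPI edge list; pairs with
|ρ| > 0.5 (configurable) are kept with their sign. Constant genes have
undefined ρ and their pairs are skipped with a warning. ρ p-values are not
computed — the threshold is on magnitude only.

MCODE is re-implemented from its published definition: vertex weight =
k × density of the highest k-core of the closed neighbourhood; seeded
greedy expansion from the highest-weight unvisited vertex including
neighbours with weight ≥ (1 − vwp) × seed weight (defaults vwp = 0.2,
haircut on, fluff off, 2-core filter — the app's documented defaults).
The haircut is the 2-core of the module (iterated removal of members with
within-module degree < 2), which makes post-processing idempotent and
guarantees the stated module invariants; if a haircut disconnects a module,
each connected component retaining a 2-core stands as its own module.
Signs are ignored for module detection (modules live on the thresholded
topology); signed edge counts are censused separately. Module score is the
density of the induced subgraph.

The degree power law follows the network-tool convention: least squares on
log₁₀(frequency) vs log₁₀(degree) over nonzero bins, reporting γ (negated
slope) and R², not a maximum-likelihood tail fit. At least 3 distinct
positive degrees are required.

## Imaging markers (`senkit.markers_img`)

Pipeline order is fixed and enforced by the drivers: per-marker,
per-timepoint 1.5×IQR outlier removal (type-7 quartiles; grouping within
timepoints avoids deleting genuine senescence shifts as outliers), then
max-scaling of each marker by its global across-timepoint maximum
(post-removal, so a surviving extreme value cannot compress the scale), then
tests. Shift tests are two-sided Wilcoxon rank-sum (exact null for untied
samples up to n = 50, tie-corrected normal approximation otherwise);
timepoints are independent cell populations, hence rank-sum rather than
signed-rank. Positivity fractions use a user-supplied threshold, defaulting
to the 99th percentile of T0 — the analysis reports the fraction above
threshold, not a calibrated assay cutoff. Marker correlations are Spearman;
constant markers are reported missing.

## Cell-level analyses (`senkit.cells`)

Normalization is ln(1 + count·10⁴/depth) — a deliberate, simple stand-in
for variance-stabilising normalization; it preserves zeros and is
depth-relative. Marker ranking is one-vs-rest Wilcoxon per gene with
logFC = ln((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)) and Bonferroni
correction over all genes tested; records are kept at |logFC| > 0.25 and
adjusted p < 0.001 (both configurable). The one-vs-rest background is all
other cells by default. Cell-cycle scoring follows the expression-matched
control scheme: genes are binned by average expression (24 quantile bins),
each phase gene draws 100 control genes from its bin excluding the phase
sets themselves, and score = mean(phase genes) − mean(controls); phase is
G1 when both S and G2M scores are ≤ 0 (within 1e-12 to absorb float noise
on degenerate flat input), otherwise the larger score wins. Gene sets are
user-supplied; nothing is hard-coded.

PCA is centred with deterministic component signs (largest-magnitude
loading positive). Lineage inference is deliberately only the first stage
of tree-based trajectory methods: a Euclidean MST over cluster centroids in
PC space with lineages as root-to-leaf paths. Per-cell pseudotime is the
tree arc length from the root centroid to the cell's clamped orthogonal
projection onto an incident tree segment of its own cluster; when a cluster
has several incident edges the segment with the nearest projection is used.
No principal-curve smoothing is applied, so conclusions are topology-level:
branch order and cluster ordering, not within-cluster dynamics.

## Synthetic data (`senkit.syndata`)

The generators emulate the study design: 3 timepoints × 3 replicates,
per-gene counts from the four families with replicate effects multiplying
the mean (a log-link covariate), droplet profiles as Poisson totals around
a real depth (default 1000) and an ambient depth (default 10) with ~25%
log-normal depth jitter, planted co-expression modules as shared latent
factors inside a preferential-attachment PPI (all within-module pairs are
PPI edges), log-normal marker intensities (log-scale σ = 0.2, about a 20%
CV typical of per-nucleus imaging intensities; at this σ the 1.5×IQR fence
flags < 2% of clean points) with outliers injected above 10× the 99th
percentile, and lineage counts as Poisson samples of exponentiated
Gaussian-perturbed centroids so that log-normalization approximately
recovers the latent geometry.

The bifurcation benchmark uses orthonormal (QR) branch directions spread
over 30 genes at a baseline of 2.5 log-counts. Both choices are structural:
random directions can make the planted Y fail to be the MST of the latent
centroids, and depth normalization shifts each cluster by −ln(total
expression) along the all-ones direction, so near-equal cluster totals are
needed for the latent geometry to survive the count map.

Every generator is a pure function of (parameters, seed); RNG streams are
namespaced per gene/entity so adding entities never perturbs earlier draws.
Not emulated: transcriptome-wide gene–gene covariance, ambient
contamination chemistry, doublets, batch effects beyond the replicate mean
shift, and variance-stabilised residual structure. Passing tests therefore
demonstrate correctness of the computations under the stated generative
models, not robustness to every artefact of real droplet data.

## Problem sizes

The benchmark suite uses 100 genes per family at n = 2000 cells for shape
identification (n = 5000 for ZINB parameter recovery), 100 real + 1000
ambient barcodes for cell calling, an 80-gene/500-cell expression matrix
with one planted 10-gene module for network recovery, 100 seeded runs of
the 4-cluster bifurcation (50 cells per cluster), 100 no-signal runs of
500 genes × 400 cells for the marker-filter type-I check, and 1500 imaged
cells across three timepoints for the marker statistics.

## Known limitations

* The ZIP/NB BIC tie-break is an arbitrary fixed order; exact ties are
  measure-zero on real data.
* The KS screen is per fit without multiplicity correction; with many genes
  the family-level pass rates should be read as screening, not inference.
* MST-over-centroids cannot represent within-cluster branching or curved
  trajectories; pseudotime is piecewise linear along centroid segments.
* The log-log least-squares power-law fit is known to be a biased estimator
  of heavy-tail exponents; it is used because it is the convention of the
  network tool being mirrored, and both γ and R² are reported.
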