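# Methods

## Data model and binning

Analyses are intra-chromosomal at a fixed resolution (default 25 kb,
configurable). Bin *b* covers the half-open interval
[b·res, (b+1)·res) in 0-based coordinates; deposited 1-based read positions
map to bin ⌊(pos−1)/res⌋, so a position exactly on a bin boundary belongs
to the lower bin. SPRITE cluster files are parsed one cluster per line
(`cluster_id` + TAB-separated `chrom:position[:mapq]` tokens); reads with a
MAPQ below the threshold (default 30) are dropped, and reads without a MAPQ
field pass, since deposited cluster files are already alignment-filtered.
Within a cluster, reads in the same bin count once, so a cluster's order
*k* is the number of distinct occupied bins. Clusters need at least two
reads on the chromosome to qualify; clusters whose reads all collapse to
one bin are kept and counted as 2-mers (*k* = 2, flagged). Such single-bin
clusters touch only the diagonal entry of the contact matrix — the only
pair available to them — and the diagonal is excluded from reconstruction,
so the choice affects summaries only. Reads on other chromosomes within a
cluster are silently ignored.

## Contact matrices and weighting schemes

A cluster with bins b₁<…<b_m (m ≥ 2) adds w(k) to both symmetric entries
of every unordered pair, where w(k) is 2/k (under-weighting), 1 (neutral),
or k(k−1) (over-weighting). For k = 2 all schemes coincide up to the exact
factor 2 for O-W; consequently, on purely pairwise data the U-W and N-W
matrices are identical and the O-W matrix is exactly doubled.

Before distance conversion the pipeline rescales each matrix to unit mean
nonzero off-diagonal contact. A global count scale carries no shape
information (the power transform maps it to a global distance scale, which
similarity Procrustes removes), and the rescaling makes reconstructions
exactly invariant to sequencing depth. Because multiplication by powers of
two is exact in IEEE arithmetic, matrices differing by such a factor — the
O-W vs N-W case on pairwise data — become bitwise identical and produce
bitwise-identical reconstructions; for other factors the invariance holds
to the numerical precision of the optimizer.

Normalization (optional, off by default so that primary analyses are free
of normalization-dependent artifacts) is a generic symmetric iterative
row/column balancing: each sweep divides by the square root of the outer
product of row sums, which preserves symmetry and converges to equal (unit
mean) row sums; all-zero rows are excluded and left untouched. Defaults:
relative tolerance 1e−6, at most 200 sweeps, error on non-convergence.

## Distances and weighted MDS

Observed contacts become dissimilarities D_ij = C_ij^α with α = −1/3 by
default (−1.08 available); zero-contact pairs and the diagonal are
*unobserved* rather than imputed, which keeps the stress well defined.
MDS weights are w_ij = D_ij^(−p) with p = 1 (inversely proportional to
distance; exposed for sensitivity runs, p = 0 gives the unweighted
variant).

The embedding minimizes raw weighted stress
σ(X) = Σ_{i<j, observed} w_ij (D_ij − d_ij(X))² over X ∈ R^{n×3} by
majorization (SMACOF): each iteration applies the Guttman transform
X ← V⁺ B(X) X, where V is the weight Laplacian (pseudo-inverse computed
once per matrix) and B(X) the usual ratio matrix. Majorization guarantees a
non-increasing stress sequence; iteration stops when the relative stress
decrease falls below 1e−6 (default) or after 1000 iterations. Raw stress
rather than normalized stress-1 is minimized; fixed monotone variants share
the same minimizers and raw stress keeps the update standard.

The default start is classical (Torgerson) scaling after completing missing
dissimilarities with graph shortest paths over observed edges; the top
three eigenvectors (signs canonicalized so the largest-magnitude entry is
positive, making the fit equivariant under bin permutations) seed the
iteration. A deterministic start makes scheme comparisons reproducible;
random restarts are available (`n_restarts`, default 1), and the lowest-
stress result is returned. The observation graph must be connected —
disconnected inputs raise an error listing component sizes. Stress
majorization can stall on non-global stationary points; with noisy partial
distance data, reruns from restarts are the remedy, and the pipeline's
matched seeds ensure that any such stall affects all schemes identically
only insofar as their inputs are bitwise equal.

## Comparing reconstructions

Reconstructions are compared under reflection-similarity shape: the query
configuration is superposed onto a fixed target over rotation (reflection
permitted), translation and scaling, and the residual
RMSE = √(Σᵢ‖targetᵢ − T(queryᵢ)‖²/n) is reported. The query-onto-target
(asymmetric) convention matches the pipeline's use of the neutral-weighting
reconstruction as referent; the convention is recorded in run provenance.
Identical inputs short-circuit to an exact zero.

Per-chromosome features: percentage of clusters with k > 3 and k > 10;
percentage of "long-distance" clusters, defined as genomic span (max bin −
min bin, times resolution — bin-level spans keep the feature reproducible
from binned clusters alone) strictly above the pooled upper quintile (and
upper decile) of spans across all chromosomes. Quantiles use linear
interpolation between order statistics at p(n−1)+1, fixed because quintile
membership defines a headline feature. RMSEs are regressed on one feature
at a time by OLS, optionally adding chromosome length as a covariate, with
two-sided t-tests per slope; no multiple-testing correction is applied (raw
p-values are reported), and chromosomes with zero clusters are excluded
and logged. The span-by-order cross-tabulation counts each cluster once in
left-closed 25 Mb span bins (0–250 Mb) and order strata {2}, {3}, {4–10},
{11–100}, {>100}; spans beyond the last break fall in the final row and are
logged.

Region-of-interest dominance: a designated rectangular sub-region of the
contact matrix is ranked by total contact count against every equally sized
window placement inside a locus whose minimum |row−col| offset exceeds a
diagonal-exclusion band; the designated window's sum, rank and
strict-maximum status are returned (integral-image window sums, exhaustive
placement scan).

## Synthetic data generator

The generator instantiates the latent structure the analysis assumes, with
defaults chosen once as the study conditions.

**Backbone.** A Gaussian random walk (unit step variance per axis) confined
to a territory sphere with a soft-core exclusion radius r_min = 1: step
candidates are rejected outside the sphere or within r_min of an earlier
bin (after 200 candidates the least-crowded in-sphere candidate is
accepted, so generation terminates). The sphere radius follows from the bin
count and a packing fraction of 0.1, R = (n_bins/0.1)^{1/3}·r_min/2 —
about 6.3 step units at 200 bins. Confinement emulates a chromosome
territory: the walk folds back repeatedly (so spatially close bins are
often genomically distant), and no two bins come arbitrarily close. The
latter matters numerically: under the d⁻³ contact law the closest pair
dominates total contact mass, and an unconfined walk's near-coincident
revisits would require orders of magnitude more clusters before distant
pairs are observed at all. An optional moving-average smoothing of the path
is available but off by default for exactly that reason.

**Clusters.** Cluster order k is drawn from a distribution with mass 0.75
on k = 2, 0.12 on k = 3, and a power-law tail (exponent 2.2) on
4 ≤ k ≤ k_max; k_max defaults to n_bins/10 (capped at 150), mirroring the
ratio of the largest cluster orders to chromosome bin counts in real 25 kb
data. A seed bin *pair* is drawn with probability proportional to the
contact kernel (d² + ε²)^{−γ/2} with decay γ = 3 — the inverse of the −1/3
transform — and soft-core ε = 0.5; the remaining k − 2 members are drawn
without replacement around the seed under the same kernel (Gumbel top-k).
One read per member bin is emitted at the bin midpoint. Because membership
follows spatial, not genomic, proximity, multi-way clusters straddle larger
genomic spans than 2-mers wherever the backbone folds back — the
characteristic multi-way pattern emerges from the model rather than being
hard-coded.

**Hi-C.** Independent Poisson counts with mean c·d_ij^{−3}, c calibrated so
the expected upper-triangle total equals the configured coverage (default
1e6 for a 5 Mb chromosome — a deep-coverage regime); diagonal zero,
coincident points an error.

All randomness derives from a single seed via per-stage derived streams
(SeedSequence spawn keys 0 = backbone, 1 = clusters, 2 = Hi-C), so each
stage is reproducible independently.

**What the generator does and does not emulate.** It reproduces the
2-mer-dominated order distribution, the growth of genomic span with cluster
order, inverse-power pairwise contact decay with Poisson noise, and
coverage-limited observation (zero-contact pairs unobserved). It does not
model polymer physics, TADs/loops/compartment blocks, ligation noise,
barcode collisions, or inter-chromosomal contacts. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and the recovery of
smooth confined structures under the assumed contact law — not performance
on real data, where model misspecification (the contact decay is not a
clean power law genome-wide) dominates.

## Pipeline

Per chromosome: bin clusters → per-scheme contact matrices (optionally
balanced) → unit-mean rescale → power-law distances → weighted MDS with the
same seed across schemes (derived stably from the run seed and the
chromosome *name*, so adding or removing chromosomes never changes another
chromosome's numbers) → Procrustes RMSE against the referent scheme
(N-W default; the referent-vs-itself RMSE is reported as an exact-zero
self-check). Pooled span thresholds are computed across chromosomes before
any per-chromosome features. Failures (e.g. disconnected observation graph)
skip the chromosome with a logged reason and never abort the run. The Hi-C
comparison sends the Hi-C matrix down the identical distance/MDS path
(same α and MDS settings as the SPRITE runs) and uses it as the Procrustes
target; the per-chromosome winner is the scheme with the smallest RMSE.
Reports are TSV tables plus a provenance block (config, seeds, versions).

## Problem sizes and expected magnitudes

The test suite and the acceptance script run at sizes chosen to exercise
every property comfortably on a single CPU: backbones of 40–200 bins;
5,000–20,000 clusters for pipeline-level checks; 200,000 clusters at 200
bins for the dense-coverage recovery check, where every bin pair's expected
contact count is well above one (at sparser coverage, distant pairs are
censored at small counts and the power-law transform understates their
distances, degrading recovery — density, not iteration count, is the
binding constraint). Under those dense conditions the reconstruction-vs-
truth Procrustes RMSE is a few percent of the backbone's RMS radius for
U-W/N-W and ~11–13% for O-W, with distance correlations above 0.98;
scheme-vs-scheme RMSEs are an order of magnitude smaller than RMSEs
between reconstructions of unrelated backbones.

## Known limitations

- Stress majorization converges to stationary points; global optimality is
  not guaranteed. Restarts mitigate; the exact-collapse guarantee holds
  only where inputs are bitwise equal after unit-mean rescaling.
- The −1/3 power law treats counts as noise-free; censoring of low-count
  pairs biases their distances downward (toward 1 in transformed units).
  Zero-count pairs are dropped rather than modeled.
- Matrix balancing is a generic symmetric scheme standing in the same role
  as dedicated Hi-C correctors; it is not a reimplementation of any
  specific tool.
- Regressions across 22 (or fewer) chromosomes have limited power, and raw
  p-values are reported without multiplicity adjustment.
- Single-cell data, diploid phasing, inter-chromosomal assembly and
  tensor-based multi-way scaling are out of scope.
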