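# spritemds

3D chromosome reconstruction from SPRITE multi-way chromatin contact data,
with tools to quantify how the choice of multi-way-to-pairwise weighting
scheme affects the reconstructed structures.

## The problem

Distance-based 3D genome reconstruction takes a symmetric contact matrix
*C* (counts of contacts between fixed-width genomic bins, 25 kb by
default), converts counts to dissimilarities by a power law
*D<sub>ij</sub> = C<sub>ij</sub><sup>α</sup>* (α = −1/3 by default,
−1.08 as an alternative), and embeds the bins in 3D. Hi-C yields strictly
pairwise contacts, so *C* is immediate. SPRITE instead captures *clusters*
(*k*-mers): sets of *k* bins that co-occupied one spatial complex. Mapping
a *k*-mer onto its C(k,2) bin pairs requires a weighting choice:

| scheme | per-pair increment w(k) |
|---|---|
| under-weighting (U-W) | 2/k |
| neutral-weighting (N-W) | 1 |
| over-weighting (O-W) | k(k−1) |

High-order clusters straddle much greater genomic distances than pairwise
contacts, so the weighting might be expected to reshape reconstructions.
This package measures that effect: per chromosome it builds the three
weighted matrices, reconstructs each by weighted multidimensional scaling
(stress majorization with weights inversely proportional to distance,
solved in 3D), aligns reconstructions by reflection-similarity Procrustes
(rotation, reflection, translation, scaling removed), and reports the
between-structure RMSE with the N-W reconstruction as the referent target.
RMSEs are then regressed on per-chromosome features — chromosome length,
percentage of many-contact clusters (k > 3 or k > 10), percentage of
long-distance clusters (pooled upper span quintile or decile) — with and
without adjustment for chromosome length. A Hi-C reconstruction can serve
as an external Procrustes target, and contact-count dominance of designated
sub-regions (e.g. simultaneously interacting loci) can be ranked against
all equally sized windows after diagonal exclusion.

A synthetic-data module generates territory-confined backbones, SPRITE-like
cluster files (2-mer-dominated order distribution with a power-law tail;
membership driven by spatial proximity under an inverse-power contact law)
and Hi-C-like Poisson counts with known ground truth, so the whole pipeline
is testable end to end without downloads.

## Worked example

```python
from spritemds import (
    RunConfig, SyntheticConfig,
    generate_backbone, run_comparison, simulate_sprite_clusters,
)

clusters, lengths = {}, {}
for i, chrom in enumerate(["chr1", "chr2", "chr3", "chr4"]):
    cfg = SyntheticConfig(n_bins=80 - 10 * i, n_clusters=6000,
                          seed=10 + i, chromosome=chrom)
    truth = generate_backbone(cfg)
    clusters[chrom] = simulate_sprite_clusters(truth)
    lengths[chrom] = cfg.n_bins * cfg.resolution

report = run_comparison(RunConfig(chromosomes=lengths, seed=1),
                        clusters_by_chrom=clusters)
print(report.rmse_table.round(4))
```

prints the per-chromosome Procrustes RMSEs of the U-W and O-W
reconstructions against the N-W referent (the referent-vs-itself column is
an exact-zero self-check):

```
               U-W  N-W     O-W
chromosome
chr1        0.1481  0.0  0.3207
chr2        0.0773  0.0  0.1897
chr3        0.0835  0.0  0.1755
chr4        0.0754  0.0  0.2343
```

RMSE is in the referent configuration's coordinate units; here the
reconstructions disagree by roughly 8–32% of the structure's size, more for
O-W than U-W because over-weighting amplifies the noisy cliques contributed
by large clusters. `report.features_table` holds the per-chromosome cluster
features, `report.degree_distance` the span-by-order cross-tabulation, and
`report.regression_table` the RMSE-on-feature regressions, e.g.

```
comparison      feature      slope  p_value  r_squared
U-W vs N-W    length_bp  8.478e-08    0.215      0.617
U-W vs N-W pct_many_gt3 -3.152e-03    0.961      0.002
```

— on this small synthetic genome neither chromosome length nor the
many-contact percentage significantly predicts the scheme disagreement; the
2-mer-dominated cluster mass makes the schemes nearly interchangeable.

A command-line interface mirrors the library: `spritemds simulate`,
`build-matrices`, `reconstruct`, `compare`, `run-all`, `make-fixtures`
(see `spritemds --help`).

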