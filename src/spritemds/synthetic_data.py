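"""Ground-truth backbones and SPRITE-like / Hi-C-like synthetic data.

The generator instantiates the latent structure the analysis assumes: a
confined 3D chromosome backbone, SPRITE clusters whose members co-occur by
spatial (3D) proximity, and contact counts Poisson-distributed around an
inverse-power function of 3D distance (decay exponent 3 — the inverse of
the -1/3 contact-to-distance transform).

The backbone is a Gaussian random walk confined to a territory sphere with
a soft-core exclusion radius, emulating a chromosome territory: the walk
folds back on itself repeatedly, but no two bins come arbitrarily close.
Bounding the pairwise-distance range this way keeps the d**-3 contact law
well conditioned, so a finite cluster count can cover all bin pairs — with
an open walk, near-coincident bins would absorb virtually the entire
contact budget.

Cluster membership is driven by spatial, not genomic, proximity: a seed
bin *pair* is drawn with probability following the inverse-power contact
law, and any further members accrete around the seed under the same
kernel. Multi-way clusters therefore straddle large genomic distances
wherever the backbone folds back — the hallmark pattern of multi-way
contact assays emerges from the model instead of being hard-coded. The
cluster-size distribution is dominated by 2-mers (mass ~0.75) with a
power-law tail, matching the strongly skewed order distribution of real
cluster files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import pdist, squareform

from .cluster_io import GenomeBinning, SpriteCluster, SpriteRead
from .contacts import ContactMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_size_distribution",
    "generate_backbone",
    "simulate_sprite_clusters",
    "simulate_hic",
    "write_cluster_file",
    "write_triplet_file",
]


def default_size_distribution(
    p2: float = 0.75,
    p3: float = 0.12,
    tail_exponent: float = 2.2,
    k_max: int = 150,
) -> dict[int, float]:
    """Cluster-order probabilities: fixed mass on k=2 and k=3, the remainder
    spread over 4..k_max proportionally to k**(-tail_exponent)."""
    if k_max < 3:
        return {2: 1.0}
    if k_max == 3:
        return {2: p2, 3: 1.0 - p2}
    ks = np.arange(4, k_max + 1, dtype=float)
    tail = ks**-tail_exponent
    tail *= (1.0 - p2 - p3) / tail.sum()
    dist = {2: p2, 3: p3}
    dist.update({int(k): float(p) for k, p in zip(ks, tail)})
    return dist


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic chromosome.

    Lengths are in backbone units (the Gaussian step has unit variance per
    axis). ``proximity_bandwidth`` is the soft-core scale of the contact
    kernel (d**2 + bandwidth**2) ** (-decay/2); ``hic_coverage`` is the
    expected total pairwise count over the upper triangle;
    ``contact_decay_exponent`` 3 is the inverse of the -1/3 power law and
    governs both Hi-C counts and SPRITE cluster seeding. The default
    cluster-order tail runs to k_max = n_bins/10, mirroring the ratio of
    the largest real cluster orders to chromosome bin counts at 25 kb.
    """

    n_bins: int = 200
    seed: int = 0
    smoothing_window: int = 1
    n_clusters: int = 5000
    size_distribution: Optional[dict[int, float]] = None  # default: see __post_init__
    proximity_bandwidth: float = 0.5
    hic_coverage: float = 1_000_000.0
    contact_decay_exponent: float = 3.0
    chromosome: str = "chr1"
    resolution: int = 25_000
    exclusion_radius: float = 1.0
    packing_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.size_distribution is None:
            self.size_distribution = default_size_distribution(
                k_max=min(150, max(4, self.n_bins // 10))
            )
        total = sum(self.size_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"size_distribution must sum to 1, sums to {total}")
        if min(self.size_distribution) < 2:
            raise ValueError("cluster orders must be >= 2")
        if any(
            v <= 0
            for v in (
                self.smoothing_window,
                self.proximity_bandwidth,
                self.hic_coverage,
                self.contact_decay_exponent,
                self.resolution,
                self.exclusion_radius,
                self.packing_fraction,
            )
        ):
            raise ValueError("all scale parameters must be positive")

    @property
    def binning(self) -> GenomeBinning:
        return GenomeBinning(self.chromosome, self.n_bins * self.resolution, self.resolution)

    @property
    def territory_radius(self) -> float:
        """Confinement sphere radius from bin count and packing fraction."""
        return float(
            (self.n_bins / self.packing_fraction) ** (1.0 / 3.0)
            * self.exclusion_radius
            / 2.0
        )


@dataclass
class GroundTruth:
    backbone: np.ndarray  # n_bins x 3
    config: SyntheticConfig

    @property
    def rms_radius(self) -> float:
        centered = self.backbone - self.backbone.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # documented splitting rule: every stage derives its stream from
    # (seed, stage) so stages are independent yet reproducible
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def generate_backbone(cfg: SyntheticConfig) -> GroundTruth:
    """Territory-confined random walk with soft-core exclusion.

    Unit-variance Gaussian steps; a candidate step is rejected when it
    leaves the territory sphere or comes within ``exclusion_radius`` of an
    earlier bin. After 200 rejected candidates the least-crowded candidate
    inside the sphere is accepted, so generation always terminates. An
    optional moving average (``smoothing_window`` > 1) smooths the path —
    note it re-creates near-contacts and with them a badly conditioned
    contact law.
    """
    rng = _stage_rng(cfg.seed, 0)
    R = cfg.territory_radius
    pts = np.empty((cfg.n_bins, 3))
    pts[0] = 0.0
    max_tries = 200
    for i in range(1, cfg.n_bins):
        best, best_clearance = None, -np.inf
        for _ in range(max_tries):
            cand = pts[i - 1] + rng.standard_normal(3)
            if np.linalg.norm(cand) > R:
                continue
            clearance = float(np.min(np.linalg.norm(pts[:i] - cand, axis=1)))
            if clearance >= cfg.exclusion_radius:
                best = cand
                break
            if clearance > best_clearance:
                best, best_clearance = cand, clearance
        if best is None:  # all candidates left the sphere; step back inward
            best = pts[i - 1] * (1.0 - 1.0 / max(np.linalg.norm(pts[i - 1]), 1.0))
        pts[i] = best
    if cfg.smoothing_window > 1:
        pts = uniform_filter1d(pts, size=cfg.smoothing_window, axis=0, mode="nearest")
    return GroundTruth(backbone=pts, config=cfg)


def _contact_kernel(truth: GroundTruth, cfg: SyntheticConfig) -> np.ndarray:
    d2 = squareform(pdist(truth.backbone)) ** 2
    K = (d2 + cfg.proximity_bandwidth**2) ** (-cfg.contact_decay_exponent / 2.0)
    np.fill_diagonal(K, 0.0)
    return K


def simulate_sprite_clusters(
    truth: GroundTruth, cfg: Optional[SyntheticConfig] = None
) -> list[SpriteCluster]:
    """Draw SPRITE-like clusters from the backbone.

    Per cluster: order k from the size distribution; a seed bin pair
    (i, j) drawn with probability proportional to the contact kernel
    (d^2 + bandwidth^2)^(-decay/2); then k-2 further distinct members
    accreted around the seed with probability proportional to the same
    kernel evaluated from the seed (sequential sampling without
    replacement, realized via Gumbel top-k). One read is emitted per
    member bin, at the bin midpoint.
    """
    cfg = cfg or truth.config
    rng = _stage_rng(cfg.seed, 1)
    n = cfg.n_bins
    k_values = np.array(sorted(cfg.size_distribution), dtype=int)
    if k_values.max() > n:
        raise ValueError(f"k_max {k_values.max()} exceeds n_bins {n}")
    probs = np.array([cfg.size_distribution[int(k)] for k in k_values])

    K = _contact_kernel(truth, cfg)
    log_K = np.log(np.where(K > 0, K, np.finfo(float).tiny))
    np.fill_diagonal(log_K, -np.inf)
    iu = np.triu_indices(n, k=1)
    pair_p = K[iu] / K[iu].sum()

    ks = rng.choice(k_values, size=cfg.n_clusters, p=probs)
    pair_idx = rng.choice(pair_p.size, size=cfg.n_clusters, p=pair_p)
    seed_i, seed_j = iu[0][pair_idx], iu[1][pair_idx]

    binning = cfg.binning
    midpoints = np.array([binning.bin_midpoint(b) for b in range(n)])

    clusters: list[SpriteCluster] = []
    for ci in range(cfg.n_clusters):
        k = int(ks[ci])
        members = [int(seed_i[ci]), int(seed_j[ci])]
        if k > 2:
            keys = log_K[members[0]] + rng.gumbel(size=n)
            keys[members] = -np.inf
            extra = np.argpartition(keys, n - (k - 2))[n - (k - 2):]
            members.extend(int(b) for b in extra)
        reads = tuple(SpriteRead(cfg.chromosome, int(midpoints[b])) for b in members)
        clusters.append(SpriteCluster(f"SYN{ci:07d}", reads))
    return clusters


def simulate_hic(truth: GroundTruth, cfg: Optional[SyntheticConfig] = None) -> ContactMatrix:
    """Poisson pairwise counts with mean c * d_ij**(-decay), c calibrated so
    the expected upper-triangle total equals ``hic_coverage``."""
    cfg = cfg or truth.config
    rng = _stage_rng(cfg.seed, 2)
    d = pdist(truth.backbone)
    if np.any(d == 0):
        raise ValueError("backbone has coincident points; distances must be positive")
    lam = d**-cfg.contact_decay_exponent
    lam *= cfg.hic_coverage / lam.sum()
    counts = rng.poisson(lam).astype(float)
    C = squareform(counts)
    return ContactMatrix(C, cfg.chromosome, cfg.resolution, "hic-raw")


def write_cluster_file(clusters: Sequence[SpriteCluster], path: str | Path) -> None:
    """Emit the TAB-separated cluster dialect (chrom:position[:mapq])."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# sprite clusters: cluster_id<TAB>chrom:position[:mapq] ...\n")
        for c in clusters:
            tokens = [
                f"{r.chromosome}:{r.position}"
                + (f":{r.mapq}" if r.mapq is not None else "")
                for r in c.reads
            ]
            fh.write("\t".join([c.cluster_id, *tokens]) + "\n")


def write_triplet_file(C: ContactMatrix, path: str | Path) -> None:
    """Emit the 3-column raw-observed dialect: bin start coordinates and
    count, upper triangle including the diagonal, zeros omitted."""
    path = Path(path)
    n = C.n_bins
    with path.open("w") as fh:
        for i in range(n):
            for j in range(i, n):
                v = C.values[i, j]
                if v != 0:
                    fh.write(f"{i * C.resolution} {j * C.resolution} {v:.12g}\n")
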