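"""Contact matrices under multi-way weighting schemes, balancing, and
power-law conversion to MDS-ready distance matrices.

A SPRITE cluster of order k touches C(k,2) unordered bin pairs. Three
schemes map the cluster onto pairwise contact counts, differing in the
per-pair increment w(k):

* under-weighting  (U-W): w(k) = 2/k
* neutral-weighting (N-W): w(k) = 1
* over-weighting   (O-W): w(k) = k(k-1)

Contacts become dissimilarities by the power law D_ij = C_ij ** alpha with
alpha = -1/3 by default (-1.08 is the common alternative); MDS weights are
inversely proportional to distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

from .cluster_io import BinnedCluster, GenomeBinning

logger = logging.getLogger(__name__)

__all__ = [
    "WeightingScheme",
    "ContactMatrix",
    "DistanceMatrix",
    "BalanceError",
    "increment_weight",
    "build_contact_matrix",
    "balance_matrix",
    "power_law_distance",
    "save_matrix",
    "load_matrix",
]


class WeightingScheme(str, Enum):
    UW = "U-W"
    NW = "N-W"
    OW = "O-W"


class BalanceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"matrix balancing did not converge in {max_iter} iterations "
            f"(last residual {residual:.3e})"
        )


@dataclass
class ContactMatrix:
    """Symmetric non-negative bin-by-bin matrix of weighted contact counts."""

    values: np.ndarray
    chromosome: str
    resolution: int
    scheme: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("contact matrix must be finite")
        if (v < 0).any():
            raise ValueError("contact matrix must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("contact matrix must be symmetric")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class DistanceMatrix:
    """Partial pairwise dissimilarities with observation mask and MDS weights.

    Unobserved entries (zero contacts and the diagonal) carry weight zero so
    they do not enter the stress.
    """

    values: np.ndarray
    observed: np.ndarray
    mds_weights: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        obs = np.asarray(self.observed, dtype=bool)
        w = np.asarray(self.mds_weights, dtype=float)
        if not (d.shape == obs.shape == w.shape) or d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("values, observed and mds_weights must be square, same shape")
        if obs.diagonal().any():
            raise ValueError("diagonal must be unobserved")
        if not np.array_equal(obs, obs.T):
            raise ValueError("observation mask must be symmetric")
        if not np.all(np.isfinite(d[obs])) or not np.all(np.isfinite(w)):
            raise ValueError("observed distances and weights must be finite")
        if (d[obs] < 0).any() or (w < 0).any():
            raise ValueError("distances and weights must be non-negative")
        if (w[~obs] != 0).any():
            raise ValueError("weights must be zero on unobserved entries")
        self.values, self.observed, self.mds_weights = d, obs, w

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


def increment_weight(scheme: WeightingScheme | str, k: int) -> float:
    """Per-pair contact increment w(k) for a cluster of order k (k >= 2)."""
    if k < 2:
        raise ValueError(f"cluster order must be >= 2, got {k}")
    scheme = WeightingScheme(scheme)
    if scheme is WeightingScheme.UW:
        return 2.0 / k
    if scheme is WeightingScheme.NW:
        return 1.0
    return float(k * (k - 1))


def build_contact_matrix(
    clusters: Iterable[BinnedCluster],
    scheme: WeightingScheme | str,
    binning: GenomeBinning,
) -> ContactMatrix:
    """Accumulate binned clusters into a contact matrix under one scheme.

    Every unordered bin pair of a cluster adds ``increment_weight(scheme, k)``
    to both symmetric entries; single-bin clusters add the k=2 increment once
    to their diagonal entry (they carry no pairwise shape information but are
    retained for bookkeeping).
    """
    scheme = WeightingScheme(scheme)
    n = binning.n_bins
    C = np.zeros((n, n), dtype=float)
    # pair indices are accumulated per cluster and flushed with np.add.at in
    # batches, so dense inputs (10^5+ clusters) stay fast
    pair_templates: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    pending = 0

    def flush() -> None:
        nonlocal pending
        if not rows:
            return
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        w = np.concatenate(wts)
        np.add.at(C, (r, c), w)
        np.add.at(C, (c, r), w)
        rows.clear(), cols.clear(), wts.clear()
        pending = 0

    for cluster in clusters:
        if cluster.bins[-1] >= n or cluster.bins[0] < 0:
            raise ValueError(
                f"bin index out of range for {binning.chromosome} "
                f"(n={n}): {cluster.bins}"
            )
        w = increment_weight(scheme, cluster.k)
        if cluster.single_bin_flag:
            C[cluster.bins[0], cluster.bins[0]] += w
            continue
        m = len(cluster.bins)
        if m not in pair_templates:
            pair_templates[m] = np.triu_indices(m, k=1)
        ti, tj = pair_templates[m]
        b = np.asarray(cluster.bins)
        rows.append(b[ti])
        cols.append(b[tj])
        wts.append(np.full(ti.size, w))
        pending += ti.size
        if pending >= 500_000:
            flush()
    flush()
    return ContactMatrix(C, binning.chromosome, binning.resolution, scheme.value)


def balance_matrix(
    C: ContactMatrix, tol: float = 1e-6, max_iter: int = 200
) -> ContactMatrix:
    """Iterative row/column balancing toward equal (unit) row sums.

    Symmetric variant of iterative correction: each sweep divides by the
    square root of the outer product of row sums, so symmetry is preserved.
    All-zero rows are excluded and stay zero.
    """
    V = C.values.copy()
    active = V.sum(axis=1) > 0
    A = V[np.ix_(active, active)]
    if A.size == 0:
        return ContactMatrix(V, C.chromosome, C.resolution, "balanced")
    residual = np.inf
    for _ in range(max_iter):
        r = A.sum(axis=1)
        residual = float(np.max(np.abs(r - r.mean())) / r.mean())
        if residual < tol:
            break
        s = np.sqrt(r)
        A = A / np.outer(s, s)
    else:
        raise BalanceError(residual, max_iter)
    # fixed point has row sums 1; rescale exactly to unit mean row sum
    A = A / A.sum(axis=1).mean()
    V[np.ix_(active, active)] = (A + A.T) / 2
    return ContactMatrix(V, C.chromosome, C.resolution, "balanced")


def scale_to_unit_mean(C: ContactMatrix) -> ContactMatrix:
    """Rescale so the mean nonzero off-diagonal contact is 1.

    A global count scale carries no shape information (the power transform
    maps it to a global distance scale, which Procrustes removes), so the
    reconstruction pipeline divides it out. Scaling by a power of two is
    exact in floating point, so matrices that differ by such a factor — as
    the over- and neutral-weighted matrices do on purely pairwise data —
    become bitwise identical and yield bitwise-identical reconstructions.
    """
    V = C.values
    mask = (V != 0) & ~np.eye(V.shape[0], dtype=bool)
    if not mask.any():
        return C
    mean = V[mask].sum() / mask.sum()
    return ContactMatrix(V / mean, C.chromosome, C.resolution, C.scheme)


def power_law_distance(
    C: ContactMatrix, alpha: float = -1.0 / 3.0, weight_power: float = 1.0
) -> DistanceMatrix:
    """Convert contacts to dissimilarities, D_ij = C_ij ** alpha (alpha < 0).

    Entries with zero contacts and the diagonal are unobserved. MDS weights
    are w_ij = D_ij ** (-weight_power) on observed entries — inversely
    proportional to distance with the default power 1 — and zero elsewhere.
    """
    if alpha >= 0:
        raise ValueError(f"power-law index must be negative, got {alpha}")
    V = C.values
    observed = (V > 0) & ~np.eye(V.shape[0], dtype=bool)
    D = np.zeros_like(V)
    W = np.zeros_like(V)
    D[observed] = V[observed] ** alpha
    W[observed] = D[observed] ** (-weight_power)
    return DistanceMatrix(D, observed, W)


def save_matrix(C: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (including diagonal) as bin-index triplets,
    with a ``<path>.meta`` sidecar holding chromosome, resolution and scheme."""
    path = Path(path)
    iu = np.triu_indices(C.n_bins)
    with path.open("w") as fh:
        fh.write("# bin_i\tbin_j\tvalue\n")
        for i, j in zip(*iu):
            v = C.values[i, j]
            if v != 0:
                fh.write(f"{i}\t{j}\t{v:.12g}\n")
    with Path(f"{path}.meta").open("w") as fh:
        fh.write(f"chromosome: {C.chromosome}\n")
        fh.write(f"resolution: {C.resolution}\n")
        fh.write(f"scheme: {C.scheme}\n")
        fh.write(f"n_bins: {C.n_bins}\n")


def load_matrix(path: str | Path) -> ContactMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    for line in Path(f"{path}.meta").read_text().splitlines():
        key, _, value = line.partition(":")
        meta[key.strip()] = value.strip()
    n = int(meta["n_bins"])
    values = np.zeros((n, n), dtype=float)
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        i_s, j_s, v_s = line.split("\t")
        i, j, v = int(i_s), int(j_s), float(v_s)
        values[i, j] = v
        values[j, i] = v
    return ContactMatrix(values, meta["chromosome"], int(meta["resolution"]), meta["scheme"])
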