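"""Weighted multidimensional scaling by stress majorization (SMACOF).

Minimizes the raw weighted stress

    sigma(X) = sum_{i<j observed} w_ij (D_ij - d_ij(X))^2

over configurations X in R^{n x dim} using the Guttman-transform
majorization update, which guarantees a non-increasing stress sequence.
Unobserved dissimilarities carry weight zero; the observation graph must be
connected for the configuration to be identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import squareform, pdist

from .contacts import DistanceMatrix

__all__ = [
    "MdsConfig",
    "Reconstruction",
    "DisconnectedError",
    "smacof",
    "classical_init",
    "write_coords_tsv",
    "write_pdb",
]


class DisconnectedError(ValueError):
    """The observed-dissimilarity graph splits into several components."""

    def __init__(self, labels: np.ndarray):
        self.component_labels = labels
        n_comp = labels.max() + 1
        sizes = np.bincount(labels)
        super().__init__(
            f"observation graph has {n_comp} connected components "
            f"(sizes {sizes.tolist()}); a single component is required"
        )


@dataclass
class MdsConfig:
    dim: int = 3
    max_iter: int = 1000
    rel_tol: float = 1e-6
    init: str = "classical"  # "classical" or "random"
    seed: int = 0
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init not in ("classical", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class Reconstruction:
    """A fitted configuration: coordinates, final stress and its trace."""

    coords: np.ndarray
    stress: float
    stress_trace: np.ndarray = field(repr=False)
    converged: bool
    seed_used: int


def _check_connected(D: DistanceMatrix) -> None:
    graph = csr_matrix(D.observed.astype(np.int8))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        raise DisconnectedError(labels)


def _stress(X: np.ndarray, D: np.ndarray, W: np.ndarray) -> float:
    d = squareform(pdist(X))
    resid = D - d
    return float(np.sum(np.triu(W * resid * resid, k=1)))


def classical_init(D: DistanceMatrix, dim: int = 3) -> np.ndarray:
    """Classical (Torgerson) scaling start, with shortest-path completion.

    Missing dissimilarities are filled with graph shortest-path distances
    over the observed edges; the completed matrix is double-centered and the
    top-``dim`` eigenvectors give the starting coordinates. On a fully
    observed, exactly Euclidean input this is already the exact solution.
    """
    _check_connected(D)
    graph = np.where(D.observed, D.values, 0.0)
    full = shortest_path(csr_matrix(graph), directed=False)
    full = np.where(D.observed, D.values, full)
    np.fill_diagonal(full, 0.0)
    n = full.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (full**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dim]
    lam = np.clip(eigval[order], 0.0, None)
    V = eigvec[:, order]
    # canonical sign per eigenvector (largest-magnitude entry positive) so the
    # start — and with it the whole fit — is equivariant under permutations
    for c in range(V.shape[1]):
        pivot = np.argmax(np.abs(V[:, c]))
        if V[pivot, c] < 0:
            V[:, c] = -V[:, c]
    return V * np.sqrt(lam)


def _majorize(
    X0: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    Vp: np.ndarray,
    max_iter: int,
    rel_tol: float,
) -> tuple[np.ndarray, list[float], bool]:
    X = X0.copy()
    trace = [_stress(X, D, W)]
    converged = False
    for _ in range(max_iter):
        d = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, D / np.where(d > 0, d, 1.0), 0.0)
        B = -W * ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = Vp @ (B @ X)
        s = _stress(X, D, W)
        trace.append(s)
        prev = trace[-2]
        if prev > 0 and (prev - s) / prev < rel_tol:
            converged = True
            break
        if prev == 0:
            converged = True
            break
    return X, trace, converged


def smacof(D: DistanceMatrix, cfg: MdsConfig | None = None) -> Reconstruction:
    """Fit coordinates to a weighted partial dissimilarity matrix.

    Runs ``cfg.n_restarts`` majorization passes (the first from the
    configured initialization, further ones from random starts) and returns
    the lowest-stress result, coordinates centered at the origin.
    """
    cfg = cfg or MdsConfig()
    n = D.n_points
    if n < cfg.dim + 1:
        raise ValueError(f"need at least dim+1={cfg.dim + 1} points, got {n}")
    if not D.mds_weights.any():
        raise ValueError("all MDS weights are zero")
    _check_connected(D)

    W = D.mds_weights
    Dv = D.values
    # weight Laplacian; its pseudo-inverse is computed once and reused
    V = -W.copy()
    np.fill_diagonal(V, 0.0)
    np.fill_diagonal(V, -V.sum(axis=1))
    Vp = np.linalg.pinv(V)

    ss = np.random.SeedSequence(cfg.seed)
    scale = Dv[D.observed].mean() if D.observed.any() else 1.0
    best: Reconstruction | None = None
    for r in range(cfg.n_restarts):
        if r == 0 and cfg.init == "classical":
            X0 = classical_init(D, cfg.dim)
        else:
            rng = np.random.default_rng(ss.spawn(1)[0] if r else ss)
            X0 = rng.standard_normal((n, cfg.dim)) * scale
        X, trace, converged = _majorize(X0, Dv, W, Vp, cfg.max_iter, cfg.rel_tol)
        rec = Reconstruction(
            coords=X - X.mean(axis=0),
            stress=trace[-1],
            stress_trace=np.asarray(trace),
            converged=converged,
            seed_used=cfg.seed,
        )
        if best is None or rec.stress < best.stress:
            best = rec
    assert best is not None
    return best


def write_coords_tsv(rec: Reconstruction, path) -> None:
    import pandas as pd

    cols = ["x", "y", "z"][: rec.coords.shape[1]]
    df = pd.DataFrame(rec.coords, columns=cols)
    df.insert(0, "bin", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def write_pdb(rec: Reconstruction, path, chain: str = "A") -> None:
    """Minimal pseudo-atom PDB export (one CA per bin) for viewers."""
    # rescale into a typical PDB coordinate range
    span = np.abs(rec.coords).max() or 1.0
    xyz = rec.coords / span * 99.0
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(xyz, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  GLY {chain}{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
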