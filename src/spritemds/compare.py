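"""Comparison of 3D reconstructions and cluster-feature statistics.

Reconstructions are coordinate-system free, so agreement is measured after
Procrustes alignment under reflection-similarity shape: two configurations
that differ only by rotation, reflection, translation and scaling are
equivalent. The query is superposed onto a fixed target and the residual
root-mean-square error (RMSE) is the disagreement measure.

Per-chromosome cluster features (percentage of many-contact k-mers,
percentage of long-distance clusters relative to pooled span quantiles) are
regressed on the RMSEs by ordinary least squares, optionally adjusting for
chromosome length. No multiple-testing correction is applied; raw p-values
are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import orthogonal_procrustes

from .cluster_io import BinnedCluster, GenomeBinning
from .contacts import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ProcrustesResult",
    "SpanThresholds",
    "ChromosomeFeatures",
    "RegressionResult",
    "DegreeDistanceTable",
    "RegionDominance",
    "procrustes_align",
    "cluster_span",
    "pooled_quantile_thresholds",
    "chromosome_features",
    "regress",
    "degree_distance_table",
    "region_dominance",
    "DEFAULT_DISTANCE_BREAKS_MB",
    "DEFAULT_K_STRATA",
]

DEFAULT_DISTANCE_BREAKS_MB: tuple[float, ...] = tuple(float(x) for x in range(0, 251, 25))
# (lo, hi) inclusive bounds on k; None = unbounded above
DEFAULT_K_STRATA: tuple[tuple[int, Optional[int]], ...] = (
    (2, 2),
    (3, 3),
    (4, 10),
    (11, 100),
    (101, None),
)


@dataclass
class ProcrustesResult:
    rmse: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray


def _coords(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "coords", obj), dtype=float)


def procrustes_align(target, query, allow_scaling: bool = True) -> ProcrustesResult:
    """Superpose ``query`` onto ``target`` over rotation (reflection allowed),
    translation and (optionally) scaling; return the transform and RMSE.

    The target is held fixed: rmse = sqrt(min_T sum_i ||target_i - T(query_i)||^2 / n).
    """
    X = _coords(target)
    Y = _coords(query)
    if X.shape != Y.shape:
        raise ValueError(f"configuration shapes differ: {X.shape} vs {Y.shape}")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ynorm2 = float(np.sum(Yc**2))
    if ynorm2 == 0:
        raise ValueError("degenerate query: all points identical")
    if np.array_equal(X, Y):  # identity transform is optimal; rmse exactly 0
        dim = X.shape[1]
        return ProcrustesResult(rmse=0.0, rotation=np.eye(dim), scale=1.0,
                                translation=np.zeros(dim))
    R, sigma_sum = orthogonal_procrustes(Yc, Xc)
    scale = sigma_sum / ynorm2 if allow_scaling else 1.0
    fitted = scale * Yc @ R
    rmse = math.sqrt(float(np.sum((Xc - fitted) ** 2)) / n)
    translation = X.mean(axis=0) - scale * Y.mean(axis=0) @ R
    return ProcrustesResult(rmse=rmse, rotation=R, scale=float(scale), translation=translation)


def cluster_span(c: BinnedCluster, binning: GenomeBinning) -> int:
    """Genomic span in base pairs: (max bin - min bin) * resolution."""
    return (c.bins[-1] - c.bins[0]) * binning.resolution


def pooled_quantile_thresholds(
    spans: Sequence[float], probs: Sequence[float] = (0.2, 0.4, 0.6, 0.8)
) -> np.ndarray:
    """Empirical quantiles of the pooled span distribution.

    Linear interpolation between order statistics at p*(n-1)+1 — the common
    statistical default — fixed here because quintile membership defines the
    long-distance feature.
    """
    spans = np.asarray(spans, dtype=float)
    if spans.size == 0:
        raise ValueError("cannot compute quantiles of an empty span set")
    return np.quantile(spans, probs, method="linear")


@dataclass
class SpanThresholds:
    """Pooled span cut points defining the long-distance features."""

    upper_quintile: float
    upper_decile: float

    @classmethod
    def from_spans(cls, spans: Sequence[float]) -> "SpanThresholds":
        q80, q90 = pooled_quantile_thresholds(spans, (0.8, 0.9))
        return cls(upper_quintile=float(q80), upper_decile=float(q90))


@dataclass
class ChromosomeFeatures:
    chromosome: str
    length_bp: int
    n_clusters: int
    pct_many_gt3: float
    pct_many_gt10: float
    pct_long: float
    pct_long_decile: float


def chromosome_features(
    clusters: Sequence[BinnedCluster],
    thresholds: SpanThresholds,
    binning: GenomeBinning,
) -> ChromosomeFeatures:
    """Per-chromosome feature percentages against pooled span thresholds.

    Long-distance means span strictly above the pooled cut point; k uses the
    single-bin-as-2-mer convention carried by BinnedCluster. With zero
    clusters all percentages are NaN.
    """
    n = len(clusters)
    if n == 0:
        nan = float("nan")
        return ChromosomeFeatures(binning.chromosome, binning.chrom_length, 0, nan, nan, nan, nan)
    ks = np.array([c.k for c in clusters])
    spans = np.array([cluster_span(c, binning) for c in clusters], dtype=float)
    return ChromosomeFeatures(
        chromosome=binning.chromosome,
        length_bp=binning.chrom_length,
        n_clusters=n,
        pct_many_gt3=100.0 * int(np.sum(ks > 3)) / n,
        pct_many_gt10=100.0 * int(np.sum(ks > 10)) / n,
        pct_long=100.0 * int(np.sum(spans > thresholds.upper_quintile)) / n,
        pct_long_decile=100.0 * int(np.sum(spans > thresholds.upper_decile)) / n,
    )


@dataclass
class RegressionResult:
    slopes: dict[str, float]
    intercept: float
    p_values: dict[str, float]
    r_squared: float


def regress(
    y: Sequence[float],
    x: Sequence[float],
    adjust_length: bool = False,
    lengths: Optional[Sequence[float]] = None,
    feature_name: str = "feature",
) -> RegressionResult:
    """OLS of per-chromosome RMSEs on one feature, optionally adjusting for
    chromosome length; two-sided t-test p-values per slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope not identifiable")
    min_n = 4 if adjust_length else 3
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} chromosomes, got {y.size}")
    cols = {feature_name: x}
    if adjust_length:
        if lengths is None:
            raise ValueError("lengths required when adjust_length=True")
        cols["length_bp"] = np.asarray(lengths, dtype=float)
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(y, X).fit()
    slopes = {name: float(fit.params[name]) for name in cols}
    p_values = {name: float(fit.pvalues[name]) for name in cols}
    return RegressionResult(
        slopes=slopes,
        intercept=float(fit.params["const"]),
        p_values=p_values,
        r_squared=float(fit.rsquared),
    )


@dataclass
class DegreeDistanceTable:
    """Cluster counts cross-tabulated by genomic span (Mb, left-closed bins)
    and interaction degree stratum."""

    distance_breaks_mb: tuple[float, ...]
    k_strata: tuple[tuple[int, Optional[int]], ...]
    counts: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


def _stratum_label(lo: int, hi: Optional[int]) -> str:
    if hi is None:
        return f">{lo - 1}-mers"
    if lo == hi:
        return f"{lo}-mers"
    return f"{lo}-{hi}-mers"


def degree_distance_table(
    clusters: Iterable[BinnedCluster],
    resolution: int,
    distance_breaks_mb: Sequence[float] = DEFAULT_DISTANCE_BREAKS_MB,
    k_strata: Sequence[tuple[int, Optional[int]]] = DEFAULT_K_STRATA,
) -> DegreeDistanceTable:
    """Count each cluster once in the cell of its span bin and k stratum.

    Span bins are left-closed, right-open in Mb; spans at or beyond the last
    break fall in the final row (logged).
    """
    breaks = np.asarray(distance_breaks_mb, dtype=float)
    row_labels = [f"{breaks[i]:g}-{breaks[i + 1]:g}" for i in range(len(breaks) - 1)]
    col_labels = [_stratum_label(lo, hi) for lo, hi in k_strata]
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    n_overflow = 0
    for c in clusters:
        span_mb = (c.bins[-1] - c.bins[0]) * resolution / 1e6
        row = int(np.searchsorted(breaks, span_mb, side="right")) - 1
        if row >= len(row_labels):
            row = len(row_labels) - 1
            n_overflow += 1
        col = None
        for idx, (lo, hi) in enumerate(k_strata):
            if c.k >= lo and (hi is None or c.k <= hi):
                col = idx
                break
        if col is None:
            raise ValueError(f"cluster order k={c.k} matches no stratum")
        counts[row, col] += 1
    if n_overflow:
        logger.warning(
            "%d cluster span(s) beyond the last distance break; counted in the final row",
            n_overflow,
        )
    df = pd.DataFrame(counts, index=row_labels, columns=col_labels)
    df.index.name = "distance_mb"
    return DegreeDistanceTable(tuple(breaks), tuple(k_strata), df)


@dataclass
class RegionDominance:
    designated_sum: float
    rank: int
    is_strict_max: bool
    n_windows: int


def _window_gap(r0: int, h: int, c0: int, w: int) -> int:
    """Minimum |i-j| over a window spanning rows [r0,r0+h), cols [c0,c0+w)."""
    if c0 >= r0 + h:
        return c0 - (r0 + h - 1)
    if r0 >= c0 + w:
        return r0 - (c0 + w - 1)
    return 0


def region_dominance(
    C: ContactMatrix,
    row_window: tuple[int, int],
    col_window: tuple[int, int],
    locus: tuple[int, int],
    diag_exclusion: int = 0,
) -> RegionDominance:
    """Rank a designated sub-region's contact total among all equally sized
    windows inside a locus, after diagonal exclusion.

    Windows are half-open bin intervals. A placement is admissible when the
    minimum |row - col| over the window exceeds ``diag_exclusion``. Returns
    the designated window's sum, its rank (1 = largest) among admissible
    placements and whether it is the strict maximum.
    """
    r0, r1 = row_window
    c0, c1 = col_window
    l0, l1 = locus
    h, w = r1 - r0, c1 - c0
    if h <= 0 or w <= 0:
        raise ValueError("windows must be non-empty half-open intervals")
    if not (l0 <= r0 and r1 <= l1 and l0 <= c0 and c1 <= l1):
        raise ValueError("designated windows must lie within the locus")
    if h > l1 - l0 or w > l1 - l0:
        raise ValueError("window larger than locus")
    if _window_gap(r0, h, c0, w) <= diag_exclusion:
        raise ValueError("designated window intersects the diagonal exclusion band")

    V = C.values
    # integral image for O(1) window sums
    S = np.zeros((V.shape[0] + 1, V.shape[1] + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(V, axis=0), axis=1)

    def wsum(rr: int, cc: int) -> float:
        return float(S[rr + h, cc + w] - S[rr, cc + w] - S[rr + h, cc] + S[rr, cc])

    designated = wsum(r0, c0)
    n_windows = 0
    n_greater = 0
    strict = True
    for rr in range(l0, l1 - h + 1):
        for cc in range(l0, l1 - w + 1):
            if _window_gap(rr, h, cc, w) <= diag_exclusion:
                continue
            n_windows += 1
            if rr == r0 and cc == c0:
                continue
            s = wsum(rr, cc)
            if s > designated:
                n_greater += 1
                strict = False
            elif s == designated:
                strict = False
    return RegionDominance(
        designated_sum=designated,
        rank=1 + n_greater,
        is_strict_max=strict,
        n_windows=n_windows,
    )
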