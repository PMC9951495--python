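"""Parsing and binning of SPRITE cluster files and Hi-C triplet files.

SPRITE cluster files hold one cluster per line: a cluster identifier
followed by TAB-separated read tokens ``chrom:position`` or
``chrom:position:mapq`` (positions 1-based). Hi-C raw-observed files hold
three whitespace-separated columns: start coordinate of bin i, start
coordinate of bin j, contact count.

Reads are binned into fixed-width genomic bins (default 25 kb). Within a
cluster, multiple reads in the same bin count once, so a cluster's order k
is the number of distinct occupied bins — except that clusters collapsing
to a single bin are counted as 2-mers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeBinning",
    "SpriteRead",
    "SpriteCluster",
    "BinnedCluster",
    "ClusterParseError",
    "BinningError",
    "read_sprite_clusters",
    "bin_cluster",
    "read_hic_triplets",
]


class ClusterParseError(ValueError):
    """A malformed record in a SPRITE cluster file, carrying the line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class BinningError(ValueError):
    """A read that cannot be placed on the given binning."""


@dataclass(frozen=True)
class GenomeBinning:
    """A fixed-width binning of one chromosome.

    Bin ``b`` covers the half-open interval ``[b*resolution, (b+1)*resolution)``
    in 0-based coordinates; deposited 1-based positions map to bin
    ``floor((position - 1) / resolution)``.
    """

    chromosome: str
    chrom_length: int
    resolution: int = 25_000

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.chrom_length <= 0:
            raise ValueError(f"chrom_length must be positive, got {self.chrom_length}")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.chrom_length / self.resolution)

    def bin_of(self, position: int) -> int:
        """Bin index of a 1-based genomic position."""
        if position < 1 or position > self.chrom_length:
            raise BinningError(
                f"position {position} outside {self.chromosome} "
                f"(length {self.chrom_length})"
            )
        return (position - 1) // self.resolution

    def bin_start(self, bin_index: int) -> int:
        """1-based start coordinate of a bin (the first position it covers)."""
        return bin_index * self.resolution + 1

    def bin_midpoint(self, bin_index: int) -> int:
        return bin_index * self.resolution + self.resolution // 2


class SpriteRead(NamedTuple):
    chromosome: str
    position: int
    mapq: Optional[int] = None


@dataclass(frozen=True)
class SpriteCluster:
    cluster_id: str
    reads: tuple[SpriteRead, ...]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"cluster {self.cluster_id!r} has no reads")


@dataclass(frozen=True)
class BinnedCluster:
    """One SPRITE cluster reduced to unique bins on a single chromosome.

    ``k`` is the interaction order: the number of distinct bins, except that
    single-bin clusters carry k = 2 with ``single_bin_flag`` set.
    """

    chromosome: str
    bins: tuple[int, ...]
    k: int = field(default=-1)
    single_bin_flag: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("BinnedCluster requires at least one bin")
        if list(self.bins) != sorted(set(self.bins)):
            raise ValueError("bins must be strictly increasing and unique")
        if self.k == -1:  # derive from bins
            if len(self.bins) == 1:
                object.__setattr__(self, "k", 2)
                object.__setattr__(self, "single_bin_flag", True)
            else:
                object.__setattr__(self, "k", len(self.bins))
                object.__setattr__(self, "single_bin_flag", False)
        if len(self.bins) >= 2 and (self.k != len(self.bins) or self.single_bin_flag):
            raise ValueError("multi-bin cluster must have k = |bins| and flag unset")
        if len(self.bins) == 1 and (self.k != 2 or not self.single_bin_flag):
            raise ValueError("single-bin cluster must carry k = 2 and flag set")


def _parse_read_token(token: str, line_number: int) -> SpriteRead:
    parts = token.split(":")
    if len(parts) not in (2, 3) or not parts[0]:
        raise ClusterParseError(line_number, f"malformed read token {token!r}")
    try:
        position = int(parts[1])
        mapq = int(parts[2]) if len(parts) == 3 else None
    except ValueError:
        raise ClusterParseError(line_number, f"malformed read token {token!r}") from None
    if position < 1:
        raise ClusterParseError(line_number, f"position must be >= 1 in {token!r}")
    if mapq is not None and mapq < 0:
        raise ClusterParseError(line_number, f"negative mapq in {token!r}")
    return SpriteRead(parts[0], position, mapq)


def read_sprite_clusters(
    path: str | Path,
    mapq_min: int = 30,
    chromosome_filter: Optional[Iterable[str]] = None,
) -> Iterator[SpriteCluster]:
    """Stream clusters from a SPRITE cluster file, applying the MAPQ filter.

    Reads carrying a mapq below ``mapq_min`` are dropped; reads without a
    mapq field pass (deposited cluster files are already alignment-filtered).
    Clusters emptied by filtering are dropped. When ``chromosome_filter`` is
    given, reads on other chromosomes are removed first.
    """
    path = Path(path)
    chroms = set(chromosome_filter) if chromosome_filter is not None else None
    n_lines = 0
    with path.open() as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 2:
                raise ClusterParseError(line_number, "cluster line has no read tokens")
            cluster_id = fields[0]
            reads = []
            for token in fields[1:]:
                read = _parse_read_token(token, line_number)
                if chroms is not None and read.chromosome not in chroms:
                    continue
                if read.mapq is not None and read.mapq < mapq_min:
                    continue
                reads.append(read)
            if reads:
                yield SpriteCluster(cluster_id, tuple(reads))
    if n_lines == 0:
        logger.warning("cluster file %s contains no records", path)


def bin_cluster(cluster: SpriteCluster, binning: GenomeBinning) -> Optional[BinnedCluster]:
    """Reduce a cluster to its unique bins on ``binning.chromosome``.

    Reads on other chromosomes are ignored (analyses are intra-chromosomal).
    A cluster qualifies only with at least two reads on the chromosome;
    otherwise ``None`` is returned. Duplicate bins collapse; clusters whose
    reads all fall in one bin come back with k = 2 and ``single_bin_flag``.
    """
    positions = [r.position for r in cluster.reads if r.chromosome == binning.chromosome]
    if len(positions) < 2:
        return None
    bins = sorted({binning.bin_of(p) for p in positions})
    return BinnedCluster(binning.chromosome, tuple(bins))


def read_hic_triplets(path: str | Path, binning: GenomeBinning):
    """Load a raw-observed Hi-C triplet file into a symmetric ContactMatrix.

    Each line is ``coord_i coord_j count`` where coordinates are bin start
    offsets (multiples of the resolution, 0-based as deposited).
    """
    import numpy as np

    from .contacts import ContactMatrix

    path = Path(path)
    n = binning.n_bins
    values = np.zeros((n, n), dtype=float)
    n_records = 0
    with path.open() as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_number}: expected 3 columns, got {len(parts)}")
            ci, cj, count = int(parts[0]), int(parts[1]), float(parts[2])
            if ci % binning.resolution or cj % binning.resolution:
                raise ValueError(
                    f"{path}:{line_number}: coordinate not a multiple of "
                    f"resolution {binning.resolution}"
                )
            if count < 0:
                raise ValueError(f"{path}:{line_number}: negative count {count}")
            i, j = ci // binning.resolution, cj // binning.resolution
            if i >= n or j >= n:
                raise ValueError(f"{path}:{line_number}: bin beyond chromosome end")
            values[i, j] = count
            values[j, i] = count
            n_records += 1
    if n_records == 0:
        logger.warning("Hi-C triplet file %s is empty; returning all-zero matrix", path)
    return ContactMatrix(values, binning.chromosome, binning.resolution, "hic-raw")
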