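"""End-to-end comparison of multi-way weighting schemes.

For each chromosome: bin the SPRITE clusters, build a contact matrix under
each weighting scheme (optionally balanced), convert to distances by the
power law, reconstruct in 3D by weighted MDS with matched initialization
across schemes, and Procrustes-align each reconstruction to the referent
scheme (neutral weighting by default). Pooled span quantiles and
per-chromosome features feed OLS regressions of RMSE on chromosome length,
many-contact percentage and long-distance percentage. Optionally a Hi-C
reconstruction serves as an external Procrustes target.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster_io import (
    BinnedCluster,
    GenomeBinning,
    SpriteCluster,
    bin_cluster,
    read_hic_triplets,
    read_sprite_clusters,
)
from .compare import (
    SpanThresholds,
    chromosome_features,
    cluster_span,
    degree_distance_table,
    procrustes_align,
    regress,
)
from .contacts import (
    ContactMatrix,
    WeightingScheme,
    balance_matrix,
    build_contact_matrix,
    power_law_distance,
    scale_to_unit_mean,
)
from .mds3d import MdsConfig, Reconstruction, smacof

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_comparison", "run_hic_comparison"]

FEATURE_COLUMNS = ("length_bp", "pct_many_gt3", "pct_many_gt10", "pct_long", "pct_long_decile")


@dataclass
class RunConfig:
    chromosomes: dict[str, int]  # name -> length in bp
    cluster_path: Optional[str] = None
    hic_dir: Optional[str] = None  # triplet files named <chrom>.txt
    resolution: int = 25_000
    mapq_min: int = 30
    alpha: float = -1.0 / 3.0
    weight_power: float = 1.0
    schemes: tuple[WeightingScheme, ...] = (
        WeightingScheme.UW,
        WeightingScheme.NW,
        WeightingScheme.OW,
    )
    referent: WeightingScheme = WeightingScheme.NW
    normalize: bool = False
    mds: MdsConfig = field(default_factory=MdsConfig)
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.schemes = tuple(WeightingScheme(s) for s in self.schemes)
        self.referent = WeightingScheme(self.referent)
        if self.referent not in self.schemes:
            raise ValueError(f"referent {self.referent.value} not among schemes")

    def binning(self, chrom: str) -> GenomeBinning:
        return GenomeBinning(chrom, self.chromosomes[chrom], self.resolution)


@dataclass
class RunReport:
    rmse_table: pd.DataFrame  # chromosome x scheme (vs referent)
    features_table: pd.DataFrame
    regression_table: pd.DataFrame
    degree_distance: pd.DataFrame
    skipped: dict[str, str]
    provenance: dict
    hic_rmse_table: Optional[pd.DataFrame] = None
    hic_winners: Optional[pd.Series] = None
    reconstructions: dict[str, dict[str, Reconstruction]] = field(
        default_factory=dict, repr=False
    )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rmse_table.to_csv(outdir / "rmse_vs_referent.tsv", sep="\t")
        self.features_table.to_csv(outdir / "chromosome_features.tsv", sep="\t")
        self.regression_table.to_csv(outdir / "regressions.tsv", sep="\t", index=False)
        self.degree_distance.to_csv(outdir / "degree_distance_table.tsv", sep="\t")
        if self.hic_rmse_table is not None:
            self.hic_rmse_table.to_csv(outdir / "rmse_vs_hic.tsv", sep="\t")
        with (outdir / "run_summary.txt").open("w") as fh:
            fh.write("spritemds run summary\n=====================\n")
            for key, value in self.provenance.items():
                fh.write(f"{key}: {value}\n")
            if self.skipped:
                fh.write("skipped chromosomes:\n")
                for chrom, reason in self.skipped.items():
                    fh.write(f"  {chrom}: {reason}\n")
            if self.hic_winners is not None:
                fh.write("Hi-C-closest scheme per chromosome:\n")
                fh.write(self.hic_winners.to_string() + "\n")


def _chrom_seed(base_seed: int, chrom: str) -> int:
    # same MDS seed across schemes within a chromosome, stable under adding
    # or removing other chromosomes; kept below 2**31
    return (base_seed * 10_007 + zlib.crc32(chrom.encode())) % (2**31 - 1)


def _load_binned(
    cfg: RunConfig,
    clusters_by_chrom: Optional[Mapping[str, Sequence[SpriteCluster]]],
) -> dict[str, list[BinnedCluster]]:
    binned: dict[str, list[BinnedCluster]] = {c: [] for c in cfg.chromosomes}
    if clusters_by_chrom is None:
        if cfg.cluster_path is None:
            raise ValueError("either cluster_path or in-memory clusters are required")
        raw: dict[str, list[SpriteCluster]] = {c: [] for c in cfg.chromosomes}
        for cl in read_sprite_clusters(
            cfg.cluster_path, cfg.mapq_min, chromosome_filter=set(cfg.chromosomes)
        ):
            # a cluster may span chromosomes; it is considered on each
            chroms = {r.chromosome for r in cl.reads}
            for chrom in chroms:
                raw[chrom].append(cl)
        clusters_by_chrom = raw
    for chrom in cfg.chromosomes:
        binning = cfg.binning(chrom)
        for cl in clusters_by_chrom.get(chrom, []):
            bc = bin_cluster(cl, binning)
            if bc is not None:
                binned[chrom].append(bc)
    return binned


def _reconstruct_schemes(
    cfg: RunConfig,
    chrom: str,
    clusters: Sequence[BinnedCluster],
    seed: int,
) -> dict[str, Reconstruction]:
    binning = cfg.binning(chrom)
    recs: dict[str, Reconstruction] = {}
    for scheme in cfg.schemes:
        C = build_contact_matrix(clusters, scheme, binning)
        if cfg.normalize:
            C = balance_matrix(C)
        # global count scale carries no shape information; dividing it out
        # makes reconstructions exactly invariant to sequencing depth and to
        # power-of-two weighting factors (O-W vs N-W on pairwise data)
        D = power_law_distance(scale_to_unit_mean(C), cfg.alpha, cfg.weight_power)
        mds_cfg = dataclasses.replace(cfg.mds, seed=seed)
        recs[scheme.value] = smacof(D, mds_cfg)
    return recs


def run_comparison(
    cfg: RunConfig,
    clusters_by_chrom: Optional[Mapping[str, Sequence[SpriteCluster]]] = None,
) -> RunReport:
    """Run the full per-chromosome scheme comparison and regressions.

    Per-chromosome failures (e.g. a disconnected observation graph) are
    logged and the chromosome is skipped; they never abort the run.
    """
    binned = _load_binned(cfg, clusters_by_chrom)

    skipped: dict[str, str] = {}
    recons: dict[str, dict[str, Reconstruction]] = {}
    for chrom in cfg.chromosomes:
        clusters = binned[chrom]
        if len(clusters) == 0:
            skipped[chrom] = "no qualifying clusters"
            logger.warning("skipping %s: no qualifying clusters", chrom)
            continue
        try:
            recons[chrom] = _reconstruct_schemes(
                cfg, chrom, clusters, _chrom_seed(cfg.seed, chrom)
            )
        except Exception as exc:  # deliberate: a bad chromosome must not abort
            skipped[chrom] = str(exc)
            logger.warning("skipping %s: %s", chrom, exc)

    referent = cfg.referent.value
    rmse_rows = {}
    for chrom, recs in recons.items():
        row = {
            scheme: procrustes_align(recs[referent], rec).rmse
            for scheme, rec in recs.items()
        }
        rmse_rows[chrom] = row
    rmse_table = pd.DataFrame.from_dict(rmse_rows, orient="index")
    rmse_table.index.name = "chromosome"

    # pooled thresholds over all chromosomes before per-chromosome features
    pooled_spans = [
        cluster_span(c, cfg.binning(chrom))
        for chrom, cls in binned.items()
        for c in cls
        if chrom in recons
    ]
    feature_rows = []
    if pooled_spans:
        thresholds = SpanThresholds.from_spans(pooled_spans)
        for chrom in recons:
            feats = chromosome_features(binned[chrom], thresholds, cfg.binning(chrom))
            feature_rows.append(dataclasses.asdict(feats))
    features_table = pd.DataFrame(feature_rows)
    if not features_table.empty:
        features_table = features_table.set_index("chromosome")

    regression_table = _regressions(cfg, rmse_table, features_table)

    all_clusters = [c for chrom in recons for c in binned[chrom]]
    dd = degree_distance_table(all_clusters, cfg.resolution)

    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "resolution": cfg.resolution,
        "alpha": cfg.alpha,
        "weight_power": cfg.weight_power,
        "schemes": ",".join(s.value for s in cfg.schemes),
        "referent": referent,
        "normalize": cfg.normalize,
        "mapq_min": cfg.mapq_min,
        "procrustes_convention": "query onto fixed target, scaling allowed",
        "mds": repr(dataclasses.replace(cfg.mds)),
        "chromosomes": ",".join(cfg.chromosomes),
    }
    report = RunReport(
        rmse_table=rmse_table,
        features_table=features_table,
        regression_table=regression_table,
        degree_distance=dd.counts,
        skipped=skipped,
        provenance=provenance,
        reconstructions=recons,
    )
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report


def _regressions(
    cfg: RunConfig, rmse_table: pd.DataFrame, features_table: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    comparisons = [s.value for s in cfg.schemes if s is not cfg.referent]
    if features_table.empty:
        return pd.DataFrame(
            columns=["comparison", "feature", "adjusted_for_length", "slope", "p_value", "r_squared"]
        )
    lengths = features_table["length_bp"]
    for comp in comparisons:
        y = rmse_table.loc[features_table.index, comp]
        for feat in FEATURE_COLUMNS:
            x = features_table[feat]
            for adjust in (False, True) if feat != "length_bp" else (False,):
                min_n = 4 if adjust else 3
                if len(y) < min_n or np.ptp(x.values) == 0:
                    logger.warning(
                        "regression %s ~ %s skipped (n=%d or constant predictor)",
                        comp,
                        feat,
                        len(y),
                    )
                    continue
                res = regress(
                    y.values,
                    x.values,
                    adjust_length=adjust,
                    lengths=lengths.values if adjust else None,
                    feature_name=feat,
                )
                rows.append(
                    {
                        "comparison": f"{comp} vs {cfg.referent.value}",
                        "feature": feat,
                        "adjusted_for_length": adjust,
                        "slope": res.slopes[feat],
                        "p_value": res.p_values[feat],
                        "r_squared": res.r_squared,
                    }
                )
    return pd.DataFrame(rows)


def run_hic_comparison(
    cfg: RunConfig,
    report: Optional[RunReport] = None,
    clusters_by_chrom: Optional[Mapping[str, Sequence[SpriteCluster]]] = None,
    hic_by_chrom: Optional[Mapping[str, ContactMatrix]] = None,
) -> RunReport:
    """Extend a run with Hi-C-target Procrustes RMSEs.

    The Hi-C matrix takes the same power-law/MDS path as the SPRITE
    matrices and serves as the Procrustes target for each scheme's
    reconstruction; the per-chromosome winner is the scheme with the
    smallest RMSE.
    """
    if report is None:
        report = run_comparison(cfg, clusters_by_chrom)
    rows = {}
    winners = {}
    for chrom in cfg.chromosomes:
        if chrom not in report.reconstructions:
            continue
        binning = cfg.binning(chrom)
        if hic_by_chrom is not None:
            H = hic_by_chrom[chrom]
        elif cfg.hic_dir is not None:
            H = read_hic_triplets(Path(cfg.hic_dir) / f"{chrom}.txt", binning)
        else:
            raise ValueError("Hi-C matrices required: set hic_dir or pass hic_by_chrom")
        if H.n_bins != binning.n_bins:
            raise ValueError(
                f"{chrom}: Hi-C matrix has {H.n_bins} bins, SPRITE binning has {binning.n_bins}"
            )
        if cfg.normalize:
            H = balance_matrix(H)
        D = power_law_distance(scale_to_unit_mean(H), cfg.alpha, cfg.weight_power)
        mds_cfg = dataclasses.replace(cfg.mds, seed=_chrom_seed(cfg.seed, chrom))
        hic_rec = smacof(D, mds_cfg)
        row = {
            scheme: procrustes_align(hic_rec, rec).rmse
            for scheme, rec in report.reconstructions[chrom].items()
        }
        rows[chrom] = row
        winners[chrom] = min(row, key=row.get)
    report.hic_rmse_table = pd.DataFrame.from_dict(rows, orient="index")
    report.hic_rmse_table.index.name = "chromosome"
    report.hic_winners = pd.Series(winners, name="closest_scheme")
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report
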