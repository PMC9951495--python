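import numpy as np
import pytest

from spritemds import (
    GenomeBinning,
    MdsConfig,
    SyntheticConfig,
    bin_cluster,
    build_contact_matrix,
    generate_backbone,
    power_law_distance,
    simulate_sprite_clusters,
    smacof,
)
from spritemds.contacts import scale_to_unit_mean

SCHEMES = ("U-W", "N-W", "O-W")


@pytest.fixture
def binning25():
    """A 20-bin chromosome at 25 kb."""
    return GenomeBinning("chr1", 500_000, 25_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def dense_recovery():
    """Dense-coverage synthetic chromosome reconstructed under all schemes.

    200,000 clusters on 200 bins: every bin pair's expected contact count is
    well above one, so the -1/3 transform of the counts tracks true distance
    for all pairs. Shared across tests because the MDS runs dominate cost.
    """
    cfg = SyntheticConfig(n_bins=200, n_clusters=200_000, seed=7)
    truth = generate_backbone(cfg)
    clusters = simulate_sprite_clusters(truth)
    binned = [b for b in (bin_cluster(c, cfg.binning) for c in clusters) if b is not None]
    recs = {}
    for scheme in SCHEMES:
        C = scale_to_unit_mean(build_contact_matrix(binned, scheme, cfg.binning))
        recs[scheme] = smacof(power_law_distance(C), MdsConfig(seed=1))
    return {"cfg": cfg, "truth": truth, "binned": binned, "recs": recs}
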