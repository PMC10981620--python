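import numpy as np
import pytest

import mirimmune as mi


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down synthetic cohort with one planted regulator."""
    cfg = mi.CohortConfig(
        n_samples=200, n_genes=1500, n_mirnas=8, n_immune_sets=15,
        genes_per_set=10, planted_regulators=(0,), seed=11,
    )
    genes, mirnas, truth = mi.generate_cohort(cfg)
    return cfg, genes, mirnas, truth


@pytest.fixture(scope="session")
def small_universe(small_cohort):
    """GO universe + immune-term record matching the small cohort."""
    _, _, _, truth = small_cohort
    table, sets, immune_ids = mi.generate_go_universe(
        60, 1.0 / 3.0, mi.screen.DEFAULT_KEYWORDS, seed=12, truth=truth
    )
    return table, sets, immune_ids


@pytest.fixture()
def toy_ranked():
    """10-gene ranked list with scores 10..1 rescaled into [0, 1]."""
    ids = [f"g{i}" for i in range(1, 11)]
    scores = np.arange(10, 0, -1) / 10.0
    return mi.RankedGeneList("toy", ids, scores)
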