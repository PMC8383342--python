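import pytest

from phycotad import (classify, cluster_patterns, compute_rpkm,
                      relative_abundance, spearman_matrix)
from phycotad.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(default_cfg):
    """One full default synthetic bloom dataset, shared across tests."""
    return generate_dataset(default_cfg)


@pytest.fixture(scope="session")
def relabund(dataset):
    return relative_abundance(compute_rpkm(dataset.recruitment))


@pytest.fixture(scope="session")
def niche_labels(dataset, relabund):
    clusters = cluster_patterns(relabund)
    corr = spearman_matrix(relabund, dataset.diatoms)
    return classify(corr, clusters)
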