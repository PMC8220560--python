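import pytest

from hohla.catalog import parse_allele_name, positions_from_indices
from hohla.hierarchy import build_tree, extract_cluster, pairwise_distances
from hohla.simulate import (
    DR4_SCREEN_INDICES,
    MOTIF_INDICES,
    dr4_fixture_catalog,
    dr4_fixture_subjects,
)


@pytest.fixture(scope="session")
def catalog():
    return dr4_fixture_catalog()


@pytest.fixture(scope="session")
def tree(catalog):
    return build_tree(pairwise_distances(catalog))


@pytest.fixture(scope="session")
def dr4_cluster(tree):
    seeds = [parse_allele_name("DRB1*04:01"), parse_allele_name("DRB1*04:03")]
    return extract_cluster(tree, seeds, label="DR4")


@pytest.fixture(scope="session")
def subjects():
    return dr4_fixture_subjects()


@pytest.fixture(scope="session")
def subjects_dq():
    return dr4_fixture_subjects(with_dq=True)


@pytest.fixture(scope="session")
def screen_positions():
    return positions_from_indices(DR4_SCREEN_INDICES)


@pytest.fixture(scope="session")
def motif_positions():
    return positions_from_indices(MOTIF_INDICES)
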