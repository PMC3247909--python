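import pytest

from scatsurvey import datasets
from scatsurvey.individual_matching import attach_sex, cluster_individuals
from scatsurvey.popgen_stats import stats_from_clusters


@pytest.fixture(scope="session")
def genotype_table():
    return datasets.load_genotype_table()


@pytest.fixture(scope="session")
def clustering(genotype_table):
    return cluster_individuals(genotype_table.rows)


@pytest.fixture(scope="session")
def sexed_clusters(clustering):
    return attach_sex(clustering.clusters, datasets.load_sex_calls())


@pytest.fixture(scope="session")
def locus_stats_list(clustering, genotype_table):
    return stats_from_clusters(clustering.clusters, genotype_table.loci)


@pytest.fixture(scope="session")
def survey_samples():
    return datasets.survey_samples()
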