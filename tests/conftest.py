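import numpy as np
import pandas as pd
import pytest

from exonml import (
    SimulationConfig,
    build_feature_matrix,
    generate_exon_counts,
    load_mirna_fixture,
    test_differential_usage,
)
from exonml.features import FeatureMatrix, scale_matrix

# pytest would otherwise try to collect the library function as a test
test_differential_usage.__test__ = False


@pytest.fixture(scope="session")
def mirna_fixture():
    return load_mirna_fixture()


@pytest.fixture(scope="session")
def table4_raw(mirna_fixture):
    """22 x 6 miRNA exon matrix (outlier excluded), raw variables."""
    return mirna_fixture.matrix(drop_outlier=True)


@pytest.fixture(scope="session")
def table4_scaled(table4_raw):
    return scale_matrix(FeatureMatrix(data=table4_raw))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated experiment shared by read-only tests."""
    cfg = SimulationConfig(n_genes=40, exons_per_gene=(2, 5), frac_deu_exons=0.2,
                           deu_log2_effect=1.5, seed=11)
    counts, truth = generate_exon_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def small_deu(small_dataset):
    _, counts, truth = small_dataset
    return test_differential_usage(counts), truth


@pytest.fixture(scope="session")
def small_feature_matrix(small_deu):
    results, _ = small_deu
    return build_feature_matrix(results, scale=True)


@pytest.fixture
def blobs():
    """Three well-separated Gaussian blobs in 4-D."""
    rng = np.random.default_rng(3)
    centers = np.array([[0, 0, 0, 0], [10, 10, 0, 0], [0, 10, 10, 10]], float)
    X = np.vstack([rng.normal(c, 0.5, size=(30, 4)) for c in centers])
    labels = np.repeat([0, 1, 2], 30)
    return pd.DataFrame(X, columns=list("abcd")), labels
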