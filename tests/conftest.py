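import numpy as np
import pytest

import residualscope as rs


def make_matrix(values, gene_prefix="g", sample_prefix="s") -> rs.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return rs.ExpressionMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )


def random_matrix(n_genes, n_samples, seed=0) -> rs.ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return make_matrix(rng.normal(size=(n_genes, n_samples)))


@pytest.fixture(scope="session")
def compendium():
    """The default synthetic compendium (2000 genes x 600 samples) with truth."""
    return rs.generate(rs.preset("compendium"))


@pytest.fixture(scope="session")
def compendium_model(compendium):
    x, _ = compendium
    return rs.fit_pca(x, 10)


@pytest.fixture(scope="session")
def compendium_decomposition(compendium, compendium_model):
    x, _ = compendium
    return rs.decompose(x, compendium_model, 3)


@pytest.fixture(scope="session")
def sex_cohort():
    """The lymphoma-like cohort carrying a few-gene sex-analogue signal."""
    return rs.generate(rs.preset("sex_lymphoma"))


@pytest.fixture(scope="session")
def liver_cohort():
    """The compendium variant with the liver-analogue minority group."""
    return rs.generate(rs.preset("liver_scan"))
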