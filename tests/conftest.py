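import numpy as np
import pytest

from triomics.synthetic import SimulationConfig, simulate_cohort, random_support
from triomics.preprocess import log_transform


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


def make_cohort(
    n_samples=60,
    n_proteins=4,
    n_mirnas=12,
    support=None,
    noise_sd=0.0,
    seed=11,
    **kwargs,
):
    config = SimulationConfig(
        n_samples=n_samples,
        n_proteins=n_proteins,
        n_mirnas=n_mirnas,
        support=support if support is not None else [],
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )
    return simulate_cohort(config)


def cohort_logs(mirna, mrna, protein):
    """Log-raw matrices plus the identity gene map."""
    gene_map = dict(zip(protein.feature_ids, mrna.feature_ids))
    return (
        log_transform(protein),
        log_transform(mrna),
        log_transform(mirna),
        gene_map,
    )


@pytest.fixture
def sparse_cohort(rng):
    """Noisy cohort with a known 2-sparse support per protein."""
    support = random_support(rng, 5, 20, 2, (0.6, 1.0))
    mirna, mrna, protein, truth = make_cohort(
        n_samples=120, n_proteins=5, n_mirnas=20, support=support,
        noise_sd=0.15, seed=42,
    )
    return mirna, mrna, protein, truth
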