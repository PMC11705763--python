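import numpy as np
import pytest

from statecall import ExpressionVector, SimulationConfig
from statecall.simulate import simulate_cohorts


def make_mixture_sample(
    seed, n=2000, pi_e=0.55, mu_ne=-1.0, sigma_ne=0.8, mu_e=4.5, sigma_e=1.6,
    n_hk=30, sample_id="sim",
):
    """Draw one sample straight from the two-lognormal model (no zeros).

    Housekeeping gene ids are taken from the expressed component, matching
    their role as constitutively expressed anchors. Returns
    (ExpressionVector, latent_states, housekeeping_ids).
    """
    rng = np.random.default_rng(seed)
    latent = rng.random(n) < pi_e
    y = np.where(
        latent, rng.normal(mu_e, sigma_e, n), rng.normal(mu_ne, sigma_ne, n)
    )
    gene_ids = np.array([f"g{i:05d}" for i in range(n)], dtype=object)
    hk = list(gene_ids[np.flatnonzero(latent)[:n_hk]])
    return ExpressionVector(gene_ids, 2.0 ** y, sample_id), latent, hk


@pytest.fixture(scope="session")
def separable_config():
    """Well-separated components: mu_e - mu_ne = 5.5 log2 units, scales
    <= 1, high zero inflation — the regime where calls are near-perfect."""
    return SimulationConfig(
        seed=101,
        n_genes=1500,
        n_housekeeping=40,
        tissues=(("liver", 12), ("lung", 12), ("brain", 12), ("testis", 10)),
        tumor_cohorts=(("LIHC", 40, 0.25),),
        mu_ne=-1.0, sigma_ne=0.8, mu_e=4.5, sigma_e=1.0,
        zero_inflation=0.7,
        dormant_fraction=0.05,
        n_taa=25,
    )


@pytest.fixture(scope="session")
def separable_sim(separable_config):
    return simulate_cohorts(separable_config)
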