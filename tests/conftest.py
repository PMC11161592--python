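import numpy as np
import pytest

from tvegfuse import synthetic
from tvegfuse.collocation import CollocatedSeries

# study-condition defaults shared across tests: AR(1) truth with a seasonal
# cycle, affine product biases, and the realistic error covariance with one
# correlated pair (variances 0.36/0.29/0.13, cov12 = 0.10)
TRUE_ERR_VAR = np.array([0.36, 0.29, 0.13])
TRUE_COV12 = 0.10
TRUE_ECC = TRUE_COV12 / np.sqrt(TRUE_ERR_VAR[0] * TRUE_ERR_VAR[1])
BETAS = (1.0, 0.8, 1.2)


def make_triplet(n_steps=20000, seed=0, cov12=TRUE_COV12, phi=0.7, betas=BETAS):
    """Truth series plus a collocated triplet with the default error structure."""
    tcfg = synthetic.TruthConfig(n_steps=n_steps, ar1_coeff=phi, seed=seed)
    truth = synthetic.simulate_truth(tcfg)
    cov = np.diag(TRUE_ERR_VAR).astype(float)
    cov[0, 1] = cov[1, 0] = cov12
    pcfg = synthetic.ProductConfig(
        alphas=(0.0, 0.0, 0.0), betas=betas, error_cov=cov, seed=seed + 1
    )
    return truth, synthetic.simulate_products(truth, pcfg), pcfg


@pytest.fixture(scope="session")
def triplet():
    """One large collocated triplet with non-zero ECC between products 1-2."""
    return make_triplet(seed=42)


def series_from_values(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return CollocatedSeries(
        product_ids=[f"p{i}" for i in range(values.shape[0])],
        times=np.arange(values.shape[1]),
        values=values,
        valid_mask=np.asarray(valid, dtype=bool),
    )
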