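import numpy as np
import pytest

from funcqtl import synthetic


@pytest.fixture(scope="session")
def small_genotypes():
    """91 individuals, 20 linked + 10 unmapped markers."""
    gm, mm = synthetic.simulate_pedigree_genotypes(
        91, [(20, 12.0)], unmapped_count=10, seed=101
    )
    return gm


@pytest.fixture(scope="session")
def one_qtl_dataset():
    """n=200 individuals, p=40 unlinked markers, one strong intercept QTL."""
    gm, _ = synthetic.simulate_pedigree_genotypes(200, [], unmapped_count=40, seed=7)
    beta = np.zeros(40)
    beta[5] = 3.0
    params = synthetic.TrueModelParams(
        alpha0=10.0,
        alpha1=-1.0,
        Sigma=np.diag([1.0, 0.1]),
        sigma0_sq=1.0,
        beta=beta,
        gamma=np.zeros(40),
        time_grid=np.arange(-4.0, 5.0),
        missing_rate=0.0,
        seed=13,
    )
    phen, truth = synthetic.simulate_longitudinal_traits(gm, params)
    return gm, phen, truth
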