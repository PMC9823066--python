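import numpy as np
import pytest

import matcov as mc


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort with the default (mixed maternal/fetal) architecture."""
    cfg = mc.SimConfig(n_pairs=3000, n_own=3000, m_snps=2000, seed=11)
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fetal_only_cohort():
    """Birthweight driven purely by the fetal genome (h2 = 0.3)."""
    psi = np.zeros((4, 4))
    psi[0, 0] = 0.3
    cfg = mc.SimConfig(n_pairs=4000, n_own=4000, m_snps=2000, psi_true=psi, seed=21)
    return mc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def quartet_stack(small_cohort):
    """Sumstats quartet, LD scores and covariance stack for the small cohort."""
    from matcov.pipeline import gwas_quartet, ld_reference

    ss = gwas_quartet(small_cohort)
    ld = ld_reference(small_cohort, n_ref=1000, window=20)
    stack = mc.build_S_V([ss[k] for k in ("BW", "BW_M", "T", "T_M")], ld, n_blocks=40)
    return ss, ld, stack
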