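import numpy as np
import pytest

import socialgwas as sg


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """n=30 individuals (10 cages of 3), 60 variants; shared across tests."""
    rng = np.random.default_rng(7)
    genotypes = sg.simulate_genotypes(30, 60, (0.1, 0.5), rng)
    cages = sg.CageStructure.random(30, 3, rng)
    A = sg.compute_grm(genotypes)
    return genotypes, cages, A


@pytest.fixture(scope="session")
def small_panel():
    """n=150 (50 cages of 3) panel with GRM and component matrices."""
    rng = np.random.default_rng(99)
    genotypes = sg.simulate_genotypes(150, 200, (0.05, 0.5), rng)
    cages = sg.CageStructure.random(150, 3, rng)
    A = sg.compute_grm(genotypes)
    comps = sg.component_matrices(A, cages, collapsed=False)
    return genotypes, cages, A, comps


def random_valid_params(rng, collapsed=False, cage_size=3):
    """Random parameter point satisfying the PSD type invariants."""
    s2_AD, s2_AS = rng.uniform(0.05, 0.6, 2)
    rho = rng.uniform(-0.95, 0.95)
    s_ADS = rho * np.sqrt(s2_AD * s2_AS)
    if collapsed:
        return sg.SocialCovarianceParams(
            sigma2_AD=s2_AD,
            sigma_ADS=s_ADS,
            sigma2_AS=s2_AS,
            sigma2_E=rng.uniform(0.2, 1.0),
            rho_E=rng.uniform(-1.0 / (cage_size - 1) + 0.05, 0.9),
            collapsed=True,
        )
    s2_ED, s2_ES = rng.uniform(0.1, 0.6, 2)
    rho_e = rng.uniform(-0.95, 0.95)
    return sg.SocialCovarianceParams(
        sigma2_AD=s2_AD,
        sigma_ADS=s_ADS,
        sigma2_AS=s2_AS,
        sigma2_ED=s2_ED,
        sigma_EDS=rho_e * np.sqrt(s2_ED * s2_ES),
        sigma2_ES=s2_ES,
        sigma2_C=rng.uniform(0.0, 0.5),
    )
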