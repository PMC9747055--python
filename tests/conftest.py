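import numpy as np
import pandas as pd
import pytest

from hcdn import deconfound, synth
from hcdn.cca import fit_cca, transform_to_variates


@pytest.fixture(scope="session")
def demo_config():
    """Small cohort with the three planted leading canonical correlations."""
    return synth.SynthConfig(
        n_subjects=2000,
        k_planted=3,
        planted_rhos=(0.51, 0.42, 0.39),
        n_phenotypes=40,
        n_risk_factors=63,
        seed=7,
    )


@pytest.fixture(scope="session")
def demo_world(demo_config):
    """Cohort, planted structure, raw volume matrices and tables."""
    cohort = synth.generate_cohort(demo_config)
    structure = synth.make_planted_structure(cohort, demo_config)
    X, Y = synth.generate_brain_volumes(cohort, structure, demo_config)
    pheno, risk = synth.generate_phenotype_tables(cohort, structure, demo_config)
    return {
        "config": demo_config,
        "cohort": cohort,
        "structure": structure,
        "X": X,
        "Y": Y,
        "phenotypes": pheno,
        "risk": risk,
    }


@pytest.fixture(scope="session")
def demo_clean(demo_world):
    """Deconfounded, standardized volume matrices."""
    cohort = demo_world["cohort"]
    spec = deconfound.ConfoundSpec()
    Xc = deconfound.standardize_columns(
        deconfound.residualize_confounds(demo_world["X"], cohort, spec)
    )
    Yc = deconfound.standardize_columns(
        deconfound.residualize_confounds(demo_world["Y"], cohort, spec)
    )
    return Xc, Yc


@pytest.fixture(scope="session")
def demo_model(demo_clean):
    Xc, Yc = demo_clean
    return fit_cca(Xc, Yc, k=3)


@pytest.fixture(scope="session")
def demo_variates(demo_model, demo_clean):
    Xc, Yc = demo_clean
    return transform_to_variates(demo_model, Xc, Yc)


def make_small_volumes(n=200, p=4, q=3, seed=0):
    """Tiny correlated volume pair for fast structural tests."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    X = pd.DataFrame(
        z @ rng.standard_normal((2, p)) + rng.standard_normal((n, p)),
        columns=[f"dn_{i:03d}" for i in range(1, p + 1)],
    )
    Y = pd.DataFrame(
        z @ rng.standard_normal((2, q)) + rng.standard_normal((n, q)),
        columns=[f"hc_{i:03d}" for i in range(1, q + 1)],
    )
    return X, Y
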