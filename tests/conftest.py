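import numpy as np
import pandas as pd
import pytest

import edgeproject as ep


@pytest.fixture(scope="session")
def partition10():
    """Tiny two-network partition over 10 components."""
    return ep.NetworkPartition({i: ("A" if i < 5 else "B") for i in range(10)})


@pytest.fixture(scope="session")
def small_cohort():
    """Static cohort at reduced scale (n=300, C=10) with two planted edges."""
    spec = ep.StaticCohortSpec(
        n_subjects=300,
        n_components=10,
        planted_edges=((3, 0.30), (20, 0.30)),
        seed=314,
    )
    return ep.gen_static_cohort(spec)


@pytest.fixture(scope="session")
def dynamic_cohort():
    """Markov regime-switching cohort at reduced scale (n=40, C=9, k=3)."""
    spec = ep.DynamicCohortSpec(n_subjects=40, seed=271)
    return ep.gen_dynamic_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ref_pheno():
    """Reference-style covariates + continuous outcome for 200 subjects."""
    rng = np.random.default_rng(99)
    n = 200
    cov = pd.DataFrame(
        {
            "age": rng.uniform(45, 85, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "site": rng.choice(["siteA", "siteB"], n),
        },
        index=[f"S{i:04d}" for i in range(n)],
    )
    y = pd.Series(rng.standard_normal(n), index=cov.index, name="score")
    return cov, y
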