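import numpy as np
import pandas as pd
import pytest

import methpanel as mp
import methpanel.design as design_mod
import methpanel.synth as synth_mod


@pytest.fixture(scope="session")
def cohort():
    """Default study-composition cohort (433 subjects), seed-fixed."""
    return mp.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def discovery(cohort):
    return cohort.subset(cohort.df["cohort"] == "discovery")


@pytest.fixture(scope="session")
def small_plan():
    probes = [f"cg{i:06d}" for i in range(2000)]
    return mp.make_marker_plan(probes, n_planted=40, seed=7)


@pytest.fixture(scope="session")
def discovery_pools(discovery):
    return design_mod.build_pools(discovery, seed=3)


@pytest.fixture(scope="session")
def pool_data(discovery, discovery_pools, small_plan):
    """Small end-to-end discovery dataset: individuals, pools, classes."""
    meth = mp.generate_methylome(discovery, small_plan, seed=5)
    pool_beta = synth_mod.simulate_array_pools(meth, discovery_pools, seed=6)
    classes = pd.Series({p.pool_id: p.cls for p in discovery_pools})
    return meth, pool_beta, classes


@pytest.fixture(scope="session")
def dmp_results(pool_data):
    _, pool_beta, classes = pool_data
    return mp.DifferentialMethylation(pool_beta, classes).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
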