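import numpy as np
import pandas as pd
import pytest

from methylaging import simulate
from methylaging.methylome import BLOOD_CELL_TYPES

#: covariate columns used for the adjusted per-site models (one cell type
#: dropped to avoid sum-to-one collinearity)
ADJ_COVARS = ["sex", "bmi", *BLOOD_CELL_TYPES[:-1]]


@pytest.fixture(scope="session")
def small_cohort():
    """A modest confounded cohort shared by read-only tests."""
    spec = simulate.CohortSpec(n_samples=200, n_probes=600, seed=11)
    return simulate.generate_cohort(spec)


@pytest.fixture(scope="session")
def linked_cohort():
    """Cohort plus expression with planted probe-gene links (seed 2)."""
    spec = simulate.CohortSpec(n_samples=250, n_probes=800, seed=2)
    beta, samples, annot, truth = simulate.generate_cohort(spec)
    expr, gene_meta = simulate.generate_expression(
        truth, samples, beta, coupling=0.8, n_links=30, seed=2
    )
    return beta, samples, annot, truth, expr, gene_meta


@pytest.fixture()
def toy_beta():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 1, (8, 6))
    return pd.DataFrame(
        vals,
        index=[f"cg{i:03d}" for i in range(8)],
        columns=[f"S{i}" for i in range(6)],
    )
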