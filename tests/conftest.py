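import numpy as np
import pandas as pd
import pytest

from triplexnet import (ClinicalTable, ExpressionMatrix, SimConfig,
                        generate_cohort, preprocess)


def make_expr(rows: dict[str, list[float]], biotypes: dict[str, str] | None = None,
              samples: list[str] | None = None) -> ExpressionMatrix:
    """Hand-rolled expression matrix; biotype defaults to mRNA."""
    df = pd.DataFrame(rows).T
    df.columns = samples or [f"S{i}" for i in range(df.shape[1])]
    bt = pd.Series({k: (biotypes or {}).get(k, "mRNA") for k in rows})
    return ExpressionMatrix(df.astype(float), bt)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted cohort shared by read-only tests."""
    config = SimConfig(n_mrna=60, n_lncrna=30, n_mirna=10, n_samples=150,
                      n_triplets=4, n_survival_rnas=4, n_stage_rnas=4, seed=7)
    expr, clinical, truth = generate_cohort(config)
    return config, expr, clinical, truth


@pytest.fixture(scope="session")
def small_logged(small_cohort):
    _, expr, _, _ = small_cohort
    return preprocess(expr)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
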