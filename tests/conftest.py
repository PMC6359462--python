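import numpy as np
import pandas as pd
import pytest

from netpert.preprocess import ExpressionMatrix
from netpert.simulate import SimConfig, generate_expression


@pytest.fixture(scope="session")
def small_study():
    """A compact study with every kind of planted structure."""
    cfg = SimConfig(
        n_genes=500,
        n_normal=60,
        n_tumor=200,
        n_deg_up=50,
        n_deg_down=25,
        rewired_blocks=[(10, -0.5, 0.9), (10, 0.7, -0.7)],
        coexpr_modules=[(50, 0.8)] * 3,
        seed=1,
    )
    counts, norm, truth = generate_expression(cfg)
    return cfg, counts, norm, truth


@pytest.fixture()
def tiny_matrix():
    """A hand-sized counts matrix with a two-condition design."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.poisson(50, size=(20, 10)).astype(float),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(10)],
    )
    design = pd.Series(
        ["normal"] * 5 + ["tumor"] * 5, index=values.columns, name="condition"
    )
    return ExpressionMatrix(values, design, unit="counts")
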