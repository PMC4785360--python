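import numpy as np
import pandas as pd
import pytest

from dranet import simulate


@pytest.fixture(scope="session")
def small_panel():
    """A 200-gene, 150-sample panel with 20 planted DRA genes."""
    cfg = simulate.SimulationConfig(n_samples=150, n_genes=200, n_dra=20, seed=42)
    expr, samples, truth = simulate.simulate_panel(cfg)
    return expr, samples, truth


@pytest.fixture(scope="session")
def planted_module_panel():
    """Module expression with one differential and one null module."""
    specs = [
        simulate.ModuleSpec("DIFF", 40, 0.2, 0.7),
        simulate.ModuleSpec("NULL", 40, 0.5, 0.5),
    ]
    expr, classes, coll, truth = simulate.simulate_differential_modules(
        specs, n_sensitive=100, n_resistant=100, seed=7)
    return expr, classes, coll, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_sample_table(n, seed=0, drug="drugA", sens=None):
    """Minimal valid sample table for hand-built regression tests."""
    r = np.random.default_rng(seed)
    if sens is None:
        sens = 7.8 * r.beta(2, 5, n)
    return pd.DataFrame(
        {
            "sample": [f"S{i:03d}" for i in range(n)],
            "age": r.uniform(20, 80, n),
            "sex": r.choice(["male", "female"], n),
            "batch": r.choice(["b0", "b1"], n),
            "cancer": r.choice(["c0", "c1"], n),
            "tissue": r.choice(["t0", "t1"], n),
            "pc1": r.standard_normal(n),
            "pc2": r.standard_normal(n),
            "pc3": r.standard_normal(n),
            f"sens_{drug}": sens,
        }
    ).set_index("sample", drop=False)
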