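import numpy as np
import pandas as pd
import pytest

from npmrocc import PredictorSpec, infer_specs


def make_table(x, y, name="x", site_prefix="s"):
    """Tiny one-predictor survey table from parallel value/response lists."""
    return pd.DataFrame({
        "site_id": [f"{site_prefix}{i}" for i in range(len(y))],
        "occupancy": list(y),
        name: list(x),
    })


def random_table(rng, n, n_cont=2, n_cat=1, signal=False):
    """Random mixed-type survey table; optionally y depends on the first
    continuous covariate (a step effect), otherwise pure Bernoulli(0.4)."""
    data = {"site_id": [f"r{i}" for i in range(n)]}
    for j in range(n_cont):
        data[f"x{j}"] = rng.uniform(0, 10, size=n)
    for j in range(n_cat):
        data[f"c{j}"] = rng.choice(["a", "b", "c"], size=n)
    if signal:
        p = np.where(np.asarray(data["x0"]) > 5, 0.8, 0.1)
    else:
        p = np.full(n, 0.4)
    data["occupancy"] = (rng.uniform(size=n) < p).astype(int)
    df = pd.DataFrame(data)
    # guard against degenerate response
    if df["occupancy"].min() == df["occupancy"].max():
        df.loc[0, "occupancy"] = 1 - df.loc[0, "occupancy"]
    return df


def specs_for(table):
    cols = [c for c in table.columns if c not in ("site_id", "occupancy")]
    return infer_specs(table, cols)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
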