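import numpy as np
import pandas as pd
import pytest

from allohybrid.core import CountMatrix
from allohybrid.simulate import SimulationConfig, simulate_experiment


def build_count_matrix(values: np.ndarray, groups=None, lengths=None,
                       te_classes=None, tissue="flower", lanes=None) -> CountMatrix:
    """Hand-rolled CountMatrix around a plain array for unit tests."""
    g, n = values.shape
    if groups is None:
        groups = ["Co2"] * (n // 2) + ["Cg2"] * (n - n // 2)
    kinds = ["gene"] * g
    classes = [""] * g
    if te_classes:
        for i, c in te_classes.items():
            kinds[i] = "TE"
            classes[i] = c
    feats = pd.DataFrame({
        "feature_id": [f"g{i:04d}" for i in range(g)],
        "feature_kind": kinds,
        "te_class": classes,
        "length_bp": lengths if lengths is not None else [1000] * g,
    })
    per_group = {}
    rows = []
    for j, grp in enumerate(groups):
        per_group[grp] = per_group.get(grp, 0) + 1
        rows.append({
            "sample_id": f"s{j:02d}", "group": grp, "tissue": tissue,
            "line": per_group[grp],
            "lane": (lanes[j] if lanes is not None else "lane1"),
        })
    samples = pd.DataFrame(rows)
    vals = pd.DataFrame(values, index=feats["feature_id"].to_numpy(),
                        columns=samples["sample_id"].to_numpy())
    return CountMatrix(vals, feats, samples)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # scaled-down feature space and library size; full 7x6x2 sample design
    return SimulationConfig(n_genes=600, n_te=80, rng_seed=7,
                            library_size_logmean=float(np.log(1e6)))


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)
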