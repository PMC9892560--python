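import numpy as np
import pandas as pd
import pytest

from nichefx import synthetic_data


@pytest.fixture(scope="session")
def small_sim():
    """A small transplant simulation shared across tests (read-only)."""
    cfg = synthetic_data.SimConfig(n_genes=300, seed=101)
    counts, design, truth = synthetic_data.simulate_transplant_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_group_counts(group_means, reps=3, genes=1, jitter=None, rng=None):
    """Exact-replicate factorial counts for (young_T0, young_T21, aged_T0, aged_T21)."""
    y0, y21, a0, a21 = group_means
    rows = []
    cols = []
    for age, time, mean in (
        ("young", "T0", y0),
        ("young", "T21", y21),
        ("aged", "T0", a0),
        ("aged", "T21", a21),
    ):
        for r in range(1, reps + 1):
            cols.append((f"{age}_{time}_r{r}", age, time))
            rows.append(mean)
    counts = pd.DataFrame(
        np.tile(np.asarray(rows, dtype=np.int64), (genes, 1)),
        index=pd.Index([f"g{i}" for i in range(genes)], name="gene_id"),
        columns=[c[0] for c in cols],
    )
    if jitter is not None and rng is not None:
        counts = counts + rng.integers(0, jitter, size=counts.shape)
    design = pd.DataFrame(
        {
            "sample_id": [c[0] for c in cols],
            "age": [c[1] for c in cols],
            "time": [c[2] for c in cols],
            "batch": "b1",
        }
    )
    return counts, design
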