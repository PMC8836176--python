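from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spongescan import fixtures
from spongescan.expression import CountMatrix


@pytest.fixture(scope="session")
def mir486():
    return fixtures.mir486_5p()


@pytest.fixture(scope="session")
def linc():
    return fixtures.linc02802()


@pytest.fixture(scope="session")
def linc_mut():
    return fixtures.linc02802_mut()


@pytest.fixture(scope="session")
def maml3():
    return fixtures.maml3_3utr()


def make_counts(
    n_genes: int = 50,
    n: int = 3,
    base_mean: float = 200.0,
    log2fc: float | np.ndarray = 0.0,
    dispersion: float = 0.05,
    seed: int = 0,
    lengths: float = 1000.0,
) -> CountMatrix:
    """NB count matrix with a given per-gene log2 fold change."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(base_mean), 0.8, n_genes)
    lfc = np.broadcast_to(np.asarray(log2fc, dtype=float), (n_genes,))
    r = 1.0 / dispersion
    cols = {}
    for j in range(n):
        cols[f"ctrl_{j}"] = rng.negative_binomial(r, r / (r + base))
    for j in range(n):
        mu = base * 2.0**lfc
        cols[f"stim_{j}"] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=[f"g{i:04d}" for i in range(n_genes)])
    cond = pd.Series(["control"] * n + ["stimulated"] * n, index=counts.columns)
    return CountMatrix(counts, cond, pd.Series(lengths, index=counts.index))
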