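import numpy as np
import pandas as pd
import pytest

from cagflow import simulate
from cagflow.containers import OtuTable


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-mostly tests."""
    design = simulate.build_default_design()
    table, truth = simulate.simulate_otu_table(
        design, simulate.EffectSpec(), seed=20260927
    )
    return table, truth


@pytest.fixture()
def toy_table():
    """A tiny hand-checkable table: 4 samples x 5 OTUs, two groups."""
    counts = pd.DataFrame(
        [
            [50, 30, 10, 10, 0],
            [40, 40, 10, 5, 5],
            [5, 10, 40, 30, 15],
            [10, 5, 35, 40, 10],
        ],
        index=["a1", "a2", "b1", "b2"],
        columns=[f"OTU{i}" for i in range(1, 6)],
    )
    metadata = pd.DataFrame(
        {
            "group": ["A", "A", "B", "B"],
            "day": [0, 0, 0, 0],
            "subject": ["m1", "m2", "m3", "m4"],
        },
        index=counts.index,
    )
    return OtuTable(counts=counts, metadata=metadata)


def planted_block_counts(
    seed: int,
    n_samples: int = 100,
    n_otus: int = 50,
    rho: float = 0.8,
    n_blocks: int = 5,
    block_size: int = 10,
    depth: int = 20000,
) -> pd.DataFrame:
    """Compositional counts with latent block-correlated structure.

    The first n_blocks * block_size OTUs form blocks with latent
    correlation ``rho``; remaining OTUs are independent.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_samples, n_blocks))
    eps = rng.normal(size=(n_samples, n_otus))
    lat = eps.copy()
    for b in range(n_blocks):
        cols = slice(b * block_size, (b + 1) * block_size)
        lat[:, cols] = np.sqrt(rho) * z[:, [b]] + np.sqrt(1 - rho) * eps[:, cols]
    lat += rng.normal(0.0, 1.0, size=n_otus)
    f = np.exp(lat)
    f /= f.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, fi) for fi in f])
    return pd.DataFrame(counts, columns=[f"O{i:02d}" for i in range(n_otus)])


def null_lognormal_counts(
    seed: int, n_samples: int, n_otus: int, depth: int = 20000
) -> pd.DataFrame:
    """Counts from a fully uncorrelated log-normal basis."""
    return planted_block_counts(
        seed, n_samples=n_samples, n_otus=n_otus, rho=0.0, n_blocks=0,
        block_size=0, depth=depth,
    )


def noise_rho(seed: int, n_otus: int = 50, sd: float = 0.07) -> pd.DataFrame:
    """A near-zero correlation matrix: iid symmetric noise, unit diagonal."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=(n_otus, n_otus))
    noise = (noise + noise.T) / 2.0
    rho = np.clip(noise, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    ids = [f"O{i:02d}" for i in range(n_otus)]
    return pd.DataFrame(rho, index=ids, columns=ids)
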