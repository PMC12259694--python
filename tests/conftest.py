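import numpy as np
import pandas as pd
import pytest

from methanonet import network, synth


def small_config(seed: int = 0, **overrides) -> synth.SynthConfig:
    """A scaled-down survey used where full size is not the point."""
    base = dict(
        n_sites=4, plots_per_site=4, depths=("0-5", "5-10"), n_asvs=160,
        n_modules=2, site_module_offsets={}, n_cond_per_module=1,
        n_satellites=6, n_neg_satellites=2, seed=seed,
    )
    base.update(overrides)
    return synth.SynthConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic small synthetic dataset shared across tests."""
    return synth.generate_dataset(small_config(seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """One deterministic full-size dataset (128 samples, 300 ASVs)."""
    return synth.generate_dataset(synth.SynthConfig(seed=11))


@pytest.fixture()
def toy_counts():
    """Hand-written 4-sample x 5-ASV count table."""
    return pd.DataFrame(
        [[5, 0, 3, 1, 0],
         [2, 1, 0, 4, 0],
         [0, 2, 6, 0, 1],
         [3, 3, 3, 3, 3]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a1", "a2", "a3", "a4", "a5"],
    )


def net_from_adjacency(adj: np.ndarray, signs: np.ndarray | None = None,
                       ids=None) -> network.CoocNetwork:
    """Wrap a boolean adjacency (optionally signed) into a CoocNetwork."""
    n = adj.shape[0]
    rho = np.where(adj, 0.8, 0.0)
    if signs is not None:
        rho = rho * signs
    np.fill_diagonal(rho, 0.0)
    ids = ids or [f"n{i:03d}" for i in range(n)]
    return network.CoocNetwork(list(ids), rho)
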