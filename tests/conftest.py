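import numpy as np
import pytest

from emacat.bank import BankConfig, ItemBank, make_synthetic_bank


def make_toy_bank(
    n_domains: int = 3,
    items_per_domain: int = 10,
    seed: int = 0,
    cross_loading_prob: float = 0.3,
) -> ItemBank:
    """Small generic bank for oracle tests (exchangeable 0.4 prior)."""
    counts = {f"dom{g}": items_per_domain for g in range(n_domains)}
    cfg = BankConfig(domain_counts=counts, cross_loading_prob=cross_loading_prob)
    return make_synthetic_bank(cfg, seed=seed)


@pytest.fixture(scope="session")
def default_bank() -> ItemBank:
    """The full-shape synthetic bank: 189 risk + 18 SI items, 14 domains."""
    return make_synthetic_bank(seed=1)


@pytest.fixture(scope="session")
def toy_bank() -> ItemBank:
    return make_toy_bank(n_domains=3, items_per_domain=10, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
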