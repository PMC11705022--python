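import warnings

import pytest

from reformulate import classifier, npsc, synth

warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def dv():
    return classifier.load_dv_table()


@pytest.fixture(scope="session")
def npsc_tables():
    return npsc.load_npsc_tables()


@pytest.fixture()
def small_supply():
    cfg = synth.SupplyConfig(n_products=200, seed=11, unmatched_frac=0.1)
    return synth.generate_supply(cfg)


def make_pairs(n_products=600, seed=1, **overrides):
    """Matched, delta-computed pairs from a synthetic supply."""
    from reformulate import matching

    cfg = synth.SupplyConfig(n_products=n_products, seed=seed, **overrides)
    db1, db2, truth = synth.generate_supply(cfg)
    pairs, _ = matching.match_products(db1, db2)
    return pairs, truth
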