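import numpy as np
import pytest

from synlab.sim import make_grammar, oracle_predictor, simulate_genome, simulate_profiles


@pytest.fixture(scope="session")
def grammar():
    return make_grammar()


@pytest.fixture(scope="session")
def additive_grammar():
    """c=0, kappa=1: purely additive grammar."""
    cfg = _default_cfg()
    cfg["soft_rules"] = [dict(task="tead4", partner="tfap2c", c=0.0, tau=40.0)]
    cfg["strict_rules"] = [dict(name="tead_double", half_site="tead", spacing=2,
                                kappa=1.0, linker="GC")]
    return make_grammar(cfg)


def _default_cfg():
    from copy import deepcopy
    from synlab.sim import DEFAULT_CONFIG
    return deepcopy(DEFAULT_CONFIG)


@pytest.fixture()
def default_cfg():
    return _default_cfg()


@pytest.fixture(scope="session")
def small_genome(grammar):
    return simulate_genome(grammar, n_contigs=2, contig_len=50_000, density=0.1,
                           seed=11, pair_fraction=0.5, mismatch_prob=0.2)


@pytest.fixture(scope="session")
def small_profiles(grammar, small_genome):
    return simulate_profiles(small_genome, grammar, depth=0.05, seed=12)


@pytest.fixture(scope="session")
def oracle(grammar):
    return oracle_predictor(grammar)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
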