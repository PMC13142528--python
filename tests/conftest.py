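import numpy as np
import pandas as pd
import pytest

from multiword import design as dz
from multiword import simulate as sim


@pytest.fixture(scope="session")
def lexicon768():
    return sim.gen_lexicon(n=768, seed=1)


@pytest.fixture(scope="session")
def word_list768(lexicon768):
    cfg = dz.DesignConfig()
    sizes = dz.condition_group_sizes(cfg)
    return dz.balance_word_lists(
        lexicon768, n_lists=1, n_condition_groups=4, seed=2,
        group_sizes=sizes,
    )[0]


@pytest.fixture(scope="session")
def default_session(word_list768):
    cfg = dz.DesignConfig(seed=3)
    return dz.generate_session(cfg, word_list768, seed=3)


@pytest.fixture(scope="session")
def small_lexicon():
    return sim.gen_lexicon(n=192, seed=11)


@pytest.fixture(scope="session")
def small_word_list(small_lexicon):
    return dz.balance_word_lists(
        small_lexicon, n_lists=1, n_condition_groups=4, seed=12,
        group_sizes=[32, 32, 64, 64],
    )[0]


@pytest.fixture(scope="session")
def small_session(small_word_list):
    """Two runs of 64 trials: 32 trials per condition."""
    cfg = dz.DesignConfig(n_runs=2, trials_per_run=64, seed=13)
    return dz.generate_session(cfg, small_word_list, seed=13)
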