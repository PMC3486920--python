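import numpy as np
import pytest

from tonebias import (
    BlockDesign,
    ImplicitMemoryObserver,
    ImplicitMemoryParams,
    NaiveObserver,
    NaiveParams,
    blocks_to_frame,
    simulate_blocks,
)

IMM_SIGMA = 0.08
IMM_GAMMA = 0.6


@pytest.fixture(scope="session")
def imm_exp1_blocks():
    """60 Experiment-1 blocks driven by an implicit-memory observer."""
    design = BlockDesign()
    return simulate_blocks(
        design,
        lambda: ImplicitMemoryObserver(
            ImplicitMemoryParams(sigma=IMM_SIGMA, gamma=IMM_GAMMA)
        ),
        n_blocks=60,
        seed=101,
    )


@pytest.fixture(scope="session")
def imm_exp1_frame(imm_exp1_blocks):
    return blocks_to_frame(imm_exp1_blocks)


@pytest.fixture(scope="session")
def naive_exp1_blocks():
    """60 Experiment-1 blocks driven by a history-free probit observer."""
    design = BlockDesign()
    return simulate_blocks(
        design,
        lambda: NaiveObserver(NaiveParams(sigma=0.1)),
        n_blocks=60,
        seed=202,
    )


@pytest.fixture(scope="session")
def naive_exp1_frame(naive_exp1_blocks):
    return blocks_to_frame(naive_exp1_blocks)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
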