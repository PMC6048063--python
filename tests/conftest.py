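import numpy as np
import pytest

from mycostate import (
    Chronogram,
    RateModel,
    RepertoireState,
    SimulationSpec,
    StateSpace,
    TipData,
    build_state_space,
    simulate_tree,
)


def state(label: str) -> RepertoireState:
    return RepertoireState.from_label(label)


@pytest.fixture(scope="session")
def space4() -> StateSpace:
    """NM, G, M, G+M — the core entry-path state space."""
    return build_state_space([state(l) for l in ("NM", "M", "G", "G+M")])


@pytest.fixture(scope="session")
def space2() -> StateSpace:
    return build_state_space([state("NM"), state("M")])


@pytest.fixture(scope="session")
def space5() -> StateSpace:
    return build_state_space([state(l) for l in ("NM", "M", "G", "G+M", "B")])


@pytest.fixture()
def tree5() -> Chronogram:
    return Chronogram.from_newick("(((A:1,B:1):0.5,C:1.5):0.5,(D:1.2,E:1.2):0.8);")


@pytest.fixture()
def tree20() -> Chronogram:
    return simulate_tree(SimulationSpec(n_tips=20, seed=20))


def uniform_data(tree: Chronogram, space: StateSpace) -> TipData:
    return TipData({t: None for t in tree.tip_labels}, space)


def random_model(space: StateSpace, rng: np.random.Generator, scale: float = 0.3) -> RateModel:
    return RateModel(space, {mv: float(rng.exponential(scale)) for mv in space.moves})
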