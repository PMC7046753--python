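from __future__ import annotations

import numpy as np
import pytest

from cobindkit import Experiment, FixtureSpec, ExperimentSpec
from cobindkit.simulate import SLOT_GAP, SLOT_WIDTH


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def slot_starts(n_slots: int, width: int = SLOT_WIDTH, gap: int = SLOT_GAP) -> np.ndarray:
    """Accessible-slot layout matching the fixture generator's geometry."""
    return gap + np.arange(n_slots) * (width + gap)


def experiment_from_slots(
    slots: np.ndarray,
    chosen: np.ndarray,
    id: str,
    factor: str = "",
    offset: int = 75,
) -> Experiment:
    """Experiment with one summit per chosen slot at a fixed in-slot offset."""
    return Experiment.from_summits(id, factor or id, slots[chosen] + offset)


@pytest.fixture
def tether_spec() -> FixtureSpec:
    """Base TF with two partners jointly tethered to 30% of its peaks."""
    from cobindkit import TetherRelation

    return FixtureSpec(
        seed=7,
        n_slots=2000,
        experiments=(
            ExperimentSpec("base", "BASE", 500),
            ExperimentSpec("p1", "P1", 400),
            ExperimentSpec("p2", "P2", 400),
        ),
        tether=(TetherRelation("base", ("p1", "p2"), 0.3),),
    )
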