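import numpy as np
import pytest

import ehrlit as el


@pytest.fixture
def simple_item():
    return el.ItemParameters("i1", a=1.0, b=0.0, c=0.0)


@pytest.fixture
def small_bank():
    return el.ItemBank(
        [
            el.ItemParameters("i1", a=1.0, b=0.0, c=0.0),
            el.ItemParameters("i2", a=2.0, b=-1.0, c=0.2),
            el.ItemParameters("i3", a=0.8, b=0.5, c=0.1),
        ]
    )


@pytest.fixture
def default_design():
    return el.SimulationDesign(seed=7)


def simulate_complete(n_items, n_persons, seed, guessing_fixed_zero=False, **kw):
    """Complete-administration synthetic study used across test modules."""
    design = el.SimulationDesign(
        n_items=n_items,
        n_persons=n_persons,
        block_design=None,
        guessing_fixed_zero=guessing_fixed_zero,
        seed=seed,
        **kw,
    )
    bank = el.generate_item_bank(design)
    theta, labels = el.simulate_abilities(design)
    matrix = el.simulate_responses(bank, theta, seed=seed)
    return bank, theta, labels, matrix
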