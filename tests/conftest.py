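import numpy as np
import pandas as pd
import pytest

from devtempo import (
    EventTimingTable,
    SimConfig,
    SpeciesRegression,
    gen_event_table,
)
from devtempo.events import COLUMNS


def make_table(scores, species_params, noise_sd=0.0, rng=None, limbic=None):
    """Noise-controlled event table from known scores and (a, b) per species."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for name, x in scores.items():
        for sp, (a, b) in species_params.items():
            y = a + b * x + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            flag = bool(limbic and name in limbic)
            rows.append((sp, name, 10.0**y, flag, flag, ""))
    return EventTimingTable(pd.DataFrame(rows, columns=COLUMNS))


@pytest.fixture
def two_species_exact():
    """Noise-free table generated from known scores and two species."""
    scores = {f"e{i}": s for i, s in enumerate([0.0, 0.25, 0.5, 0.75, 1.0])}
    params = {"mouse": (1.0, 1.0), "human": (1.5, 2.0)}
    return make_table(scores, params), scores, params


@pytest.fixture
def human_reg():
    """The published human regression: log10 day = 1.53 + 2.44 * score."""
    return SpeciesRegression(species="human", slope=2.44, intercept=1.53)


@pytest.fixture
def mouse_reg():
    return SpeciesRegression(species="mouse", slope=1.0, intercept=1.0)


@pytest.fixture
def sim_table():
    table, truth = gen_event_table(SimConfig(seed=11))
    return table, truth
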