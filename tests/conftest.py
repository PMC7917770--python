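import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

# make the sibling oracles module importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

from susceptigene import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cfg():
    """Small planted screen used by several module tests."""
    return sd.planted_screen_config(7, n_genes=300, n_planted=10)


@pytest.fixture(scope="session")
def small_datasets(small_cfg):
    dep = sd.gen_dependency(small_cfg)
    expr = sd.gen_expression(small_cfg)
    surv = sd.gen_survival(small_cfg, expr)
    return dep, expr, surv


def toy_survival(times, events, index=None):
    from susceptigene.survival import SurvivalTable

    idx = index or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(
        time=pd.Series(times, index=idx, dtype=float),
        event=pd.Series(events, index=idx, dtype=int),
    )
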