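import numpy as np
import pandas as pd
import pytest

from famprs.panels import DosagePanel
from famprs.simulate import (
    SimulationConfig,
    make_effect_panel,
    simulate_family_cohort,
)
from famprs.sumstats import SummaryStatistics


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_variants=200, n_families=10, seed=42)


@pytest.fixture(scope="session")
def effect_panel(small_config):
    return make_effect_panel(small_config, seed=small_config.seed)


@pytest.fixture(scope="session")
def family_cohort(small_config, effect_panel):
    return simulate_family_cohort(small_config, effect_panel, seed=small_config.seed)


@pytest.fixture()
def tiny_panel():
    variants = pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": [1, 1, 2],
            "BP": [100, 200, 300],
            "A1": ["A", "C", "G"],
            "A2": ["G", "T", "A"],
        }
    )
    dosages = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 2.0, 0.0],
            [2.0, 0.0, 1.0],
            [0.0, 0.0, 0.0],
        ]
    )
    return DosagePanel(["s1", "s2", "s3", "s4"], variants, dosages)


def make_stats(**overrides) -> SummaryStatistics:
    base = dict(
        SNP=["rs1", "rs2", "rs3"],
        CHR=[1, 1, 2],
        BP=[100, 200, 300],
        A1=["A", "C", "G"],
        A2=["G", "T", "A"],
        BETA=[0.1, -0.2, 0.05],
        SE=[0.02, 0.03, 0.02],
        P=[0.001, 0.04, 0.5],
        INFO=[0.95, 0.7, 1.0],
        FRQ=[0.3, 0.6, 0.1],
        N=[1000, 1000, 1000],
    )
    base.update(overrides)
    return SummaryStatistics(pd.DataFrame(base))


@pytest.fixture()
def tiny_stats():
    return make_stats()
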