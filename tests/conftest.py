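import numpy as np
import pandas as pd
import pytest

from peamix import simulate as sim
from peamix import trial
from peamix.genomatrix import filter_markers_and_genotypes, knni_impute


@pytest.fixture(scope="session")
def default_scenario():
    """The shipped default synthetic study (144 lines, 1000 markers,
    two years), shared across test modules."""
    return sim.generate_scenario(sim.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_table(default_scenario):
    t = trial.derive_mixture_traits(default_scenario.trial)
    return trial.ms_ps_yield_ratio(t)


@pytest.fixture(scope="session")
def imputed_genotypes(default_scenario):
    gm, _ = filter_markers_and_genotypes(default_scenario.genotypes)
    return knni_impute(gm)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Desk-scale smoke fixture: 2 populations x 5 lines, 50 markers."""
    cfg = sim.SimulationConfig(
        seed=42, n_populations=2, lines_per_population=5, n_markers=50
    )
    return sim.generate_scenario(cfg)


@pytest.fixture
def toy_trial_table():
    """A tiny balanced hand-made split-plot table (2 years, 2 conditions,
    3 blocks, 4 lines) with deterministic values."""
    rng = np.random.default_rng(7)
    rows = []
    for year in ("Y1", "Y2"):
        for cond in ("MS", "PS"):
            for block in (1, 2, 3):
                for i, line in enumerate(["La", "Lb", "Lc", "Ld"]):
                    rows.append(
                        {
                            "year": year,
                            "condition": cond,
                            "block": block,
                            "population": "pop1",
                            "line": line,
                            "is_parent": line == "La",
                            "pea_yield": 1.0 + 0.3 * i + rng.normal(0, 0.1),
                            "cereal_yield": 5.0 - 0.1 * i + rng.normal(0, 0.1)
                            if cond == "MS"
                            else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
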