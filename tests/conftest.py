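import logging

import numpy as np
import pandas as pd
import pytest

from antagene.fitness import relative_fitness_from_values, select_lines
from antagene.simulate import (
    ExpressionSimConfig,
    FitnessSimConfig,
    simulate_expression_study,
    simulate_fitness_study,
)

logging.getLogger("antagene").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_fitness_study():
    """One default two-sex fitness study (100 lines) with truth."""
    cfg = FitnessSimConfig(seed=0)
    assays, truth = simulate_fitness_study(cfg)
    return cfg, assays, truth


@pytest.fixture(scope="session")
def fitness_15(default_fitness_study):
    """Sex-specific fitness covariate for the 15 selected lines."""
    _, assays, _ = default_fitness_study
    relfit = relative_fitness_from_values(assays)
    sel = select_lines(relfit)
    long = relfit.to_long()
    return long[long["line"].isin(sel.all_lines)].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_expression_study(fitness_15):
    """A 300-transcript default-design expression study with truth."""
    cfg = ExpressionSimConfig(seed=0, n_transcripts=300)
    matrix, samples, truth = simulate_expression_study(cfg, fitness_15)
    return cfg, matrix, samples, truth


@pytest.fixture()
def sample_sheet_120():
    """A deterministic 120-array sample sheet (2 sexes x 15 lines x 4 reps)."""
    rng = np.random.default_rng(7)
    rows = [
        (f"{sex}_{line}_r{r}", sex, f"L{line:02d}", r)
        for sex in ("F", "M")
        for line in range(1, 16)
        for r in range(1, 5)
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "sex", "line", "replicate"])
    df["batch"] = rng.permutation(np.repeat(np.arange(1, 9), 15))
    return df
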