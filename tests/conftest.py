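import numpy as np
import pandas as pd
import pytest

from devptn import (
    AnalysisThresholds,
    ExpressionMatrix,
    StageDesign,
    SyntheticConfig,
    generate_staged_expression,
    generate_tumor_cohorts,
)


@pytest.fixture(scope="session")
def small_matrix():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.normal(8, 1, size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(6)],
    )
    return ExpressionMatrix(df)


@pytest.fixture(scope="session")
def staged_data():
    """Planted-pattern developmental matrix at the default study shape."""
    cfg = SyntheticConfig(master_seed=11)
    matrix, design, truth = generate_staged_expression(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def signal_cohorts():
    """Three 100-patient cohorts with a planted 50-gene prognostic set."""
    cfg = SyntheticConfig(master_seed=11)
    _, _, truth = generate_staged_expression(cfg)
    cohorts, truth = generate_tumor_cohorts(cfg, truth)
    return cfg, cohorts, truth


@pytest.fixture(scope="session")
def null_cohorts():
    """Three cohorts whose survival is independent of expression."""
    cfg = SyntheticConfig(master_seed=13, hazard_coefficient=0.0)
    cohorts, truth = generate_tumor_cohorts(cfg)
    return cfg, cohorts, truth


@pytest.fixture(scope="session")
def default_thresholds():
    return AnalysisThresholds()


@pytest.fixture()
def four_stage_design():
    def make(samples_per_stage=(3, 3, 3, 3)):
        stages = ("WholeE", "EarlyL", "MiddleL", "MatureL")
        mapping = {}
        for st, n in zip(stages, samples_per_stage):
            for j in range(n):
                mapping[f"{st}_{j}"] = st
        return StageDesign(stages, mapping)

    return make
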