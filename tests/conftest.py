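import numpy as np
import pandas as pd
import pytest

from antheat import io, pipeline, simulate


@pytest.fixture(scope="session")
def study():
    """Default six-species synthetic study (audited on generation)."""
    return simulate.simulate_study(seed=1)


@pytest.fixture(scope="session")
def expression_results(study):
    """Thermal + expression stages of the default study (no Monte-Carlo)."""
    cfg = io.StudyConfig(seed=1)
    return pipeline.run_study(study, cfg, stages=("thermal", "expression"))


@pytest.fixture()
def small_survival():
    """Symmetric three-temperature assay with LT50 exactly at 45 degC."""
    from antheat.thermal import SurvivalObservation

    data = [(44.0, 2), (45.0, 5), (46.0, 8)]
    return [
        SurvivalObservation("sp", t, "1", 10, d) for t, d in data
    ]


@pytest.fixture()
def toy_counts():
    """Tiny deterministic count matrix with 4 HS + 4 NHS samples."""
    from antheat.expression import CountMatrix

    rng = np.random.default_rng(7)
    mu = rng.lognormal(4, 1.0, 200)
    samples = [f"HS_{i}" for i in range(1, 5)] + [f"NHS_{i}" for i in range(1, 5)]
    mat = np.column_stack(
        [rng.negative_binomial(10, 10 / (10 + mu)) for _ in samples]
    )
    counts = pd.DataFrame(mat, index=[f"t{i:04d}" for i in range(200)], columns=samples)
    conditions = pd.Series(["HS"] * 4 + ["NHS"] * 4, index=samples)
    return CountMatrix(counts=counts, conditions=conditions)
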