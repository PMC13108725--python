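import numpy as np
import pytest
from hypothesis import settings

from tamscreen import scoring, simulate

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One seeded default synthetic study: measurements, truth, expression."""
    scen = simulate.make_default_scenario(seed=12345)
    table, truth = simulate.simulate_cytokine_experiment(scen)
    bundle, truth = simulate.simulate_expression_bundle(scen, truth)
    return scen, table, bundle, truth


@pytest.fixture(scope="session")
def default_scores(default_study):
    """Scored default study (LLoQ filter + imputation + pooled z-scores)."""
    _, table, _, _ = default_study
    retained, _ = scoring.filter_analytes_by_lloq(table)
    imputed = scoring.impute_censored(table)
    return scoring.score_table(
        imputed, retained, control_units={simulate.CONTROL_UNIT}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
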