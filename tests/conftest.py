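"""Shared fixtures.

The expensive pieces — the full 120-member model grid on the bundled
synthetic scenario — are session-scoped so the structural, recovery and
importance checks share one fit.
"""

import numpy as np
import pytest

from phylosdm import sdm
from phylosdm.synthetic import (SyntheticScenario, gen_env_stack,
                                gen_true_suitability, sample_presences)


@pytest.fixture(scope="session")
def bundled_scenario() -> SyntheticScenario:
    """The default synthetic study: 5 smooth layers on a 40x40 planar grid,
    one collinear pair (r = 0.9), logistic truth driven by env1/env2."""
    return SyntheticScenario(seed=1)


@pytest.fixture(scope="session")
def bundled_stack(bundled_scenario):
    return gen_env_stack(bundled_scenario)


@pytest.fixture(scope="session")
def bundled_truth(bundled_scenario, bundled_stack):
    return gen_true_suitability(bundled_stack,
                                bundled_scenario.true_coefficients,
                                bundled_scenario.intercept)


@pytest.fixture(scope="session")
def bundled_presences(bundled_scenario, bundled_truth):
    records = sample_presences(bundled_truth, bundled_scenario.n_presences,
                               seed=7)
    return np.array([r.point for r in records])


@pytest.fixture(scope="session")
def bundled_pa_sets(bundled_stack, bundled_presences):
    return sdm.gen_pseudo_absences(bundled_stack, bundled_presences,
                                   n=500, n_sets=3, seed=2)


@pytest.fixture(scope="session")
def full_model_grid(bundled_stack, bundled_presences, bundled_pa_sets):
    """The complete 4-algorithm x 3-PA x 10-CV member grid (120 models)."""
    return sdm.fit_model_grid(bundled_stack, bundled_presences,
                              bundled_pa_sets, cv_runs=10, seed=3)
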