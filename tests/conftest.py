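"""Shared fixtures: phantom cohorts and the leave-one-out evaluation run.

Heavy fixtures are session-scoped so the expensive experiment runs once and
feeds all the tests that read different aspects of it.
"""

import warnings

import numpy as np
import pytest

import oculoseg as oc


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free default phantom parameters."""
    return oc.PhantomParams(noise_sd=(0.0, 0.0))


@pytest.fixture(scope="session")
def clean_case(clean_params):
    return oc.generate_eye(clean_params)


@pytest.fixture(scope="session")
def noisy_case():
    return oc.generate_eye(oc.PhantomParams(seed=5))


@pytest.fixture(scope="session")
def small_cohort():
    """Four pathological phantoms for structural tests."""
    return oc.generate_cohort(4, seed=21)


@pytest.fixture(scope="session")
def canon_cohort(small_cohort):
    config = oc.PipelineConfig()
    return [oc.prepare_case(c, config) for c in small_cohort]


@pytest.fixture(scope="session")
def loocv_report():
    """Leave-one-out experiment on the 12-phantom study cohort.

    Shared by the refinement, feature-contribution and size-trend checks.
    """
    cases = oc.generate_cohort(12, seed=7)
    config = oc.PipelineConfig(seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = oc.loocv_harness(cases, config)
    return report


def rng(seed=0):
    return np.random.default_rng(seed)
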