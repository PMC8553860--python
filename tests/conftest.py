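import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from cariescan.cohort import generate_cohort, study_config
from cariescan.scoring import fit_alg4, score_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: overrides that silence every stochastic component of the generator
QUIET = dict(
    tooth_effect_sd=0.0,
    plaque_prob_in_vivo=0.0,
    icdas_spread=0.0,
    noise_sd={"in_vivo": 0.0, "in_vitro": 0.0},
    p_missing={"in_vivo": 0.0, "in_vitro": 0.0},
)


@pytest.fixture(scope="session")
def study_cohort():
    """One realistic study-replica cohort (53 teeth / 118 sites)."""
    return generate_cohort(study_config(seed=11))


@pytest.fixture(scope="session")
def quiet_cohort():
    """Noise-free study-replica cohort: signals are deterministic in severity."""
    return generate_cohort(study_config(seed=11, **QUIET))


@pytest.fixture(scope="session")
def study_scores(study_cohort):
    model = fit_alg4(study_cohort)
    return score_cohort(study_cohort, alg4_model=model)


@pytest.fixture(scope="session")
def quiet_scores(quiet_cohort):
    model = fit_alg4(quiet_cohort)
    return score_cohort(quiet_cohort, alg4_model=model)


def quiet_config(seed, **overrides):
    return study_config(seed=seed, **{**QUIET, **overrides})


@pytest.fixture
def small_run_config():
    """A fast pipeline configuration for orchestration tests."""
    from cariescan.pipeline import study_run_config

    cohort = study_config(n_teeth=30, class_targets=(10, 20, 15, 5, 5, 5))
    cfg = study_run_config(seed=5, bootstrap_reps=30)
    return dataclasses.replace(cfg, calibration=cohort, validation=cohort)
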