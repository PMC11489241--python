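import pytest

from scacoms import (
    DerivationConfig,
    SimulationParams,
    TrialParams,
    default_config,
    derive_composite,
    filter_analytic_sample,
    generate_natural_history,
    generate_trial,
)

# Well-separated three-item design used by the ranking-recovery checks:
# sensitivities differ by ~1.6x steps against a common noise level.
RANKED_ITEMS = {"fsara_gait": 1.6, "fsara_stance": 1.0, "fsara_speech": 0.6}
RANKED_NOISE = {"fsara_gait": 0.5, "fsara_stance": 0.5, "fsara_speech": 0.5}


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def nh_cohort():
    return generate_natural_history(SimulationParams(n_subjects=300, seed=42))


@pytest.fixture(scope="session")
def analytic_cohort(nh_cohort):
    cohort, _ = filter_analytic_sample(nh_cohort, gait_min=1, gait_max=3)
    return cohort


@pytest.fixture(scope="session")
def composite_model(analytic_cohort):
    return derive_composite(
        analytic_cohort, config=DerivationConfig(n_components=2), label="nh-seed42"
    )


@pytest.fixture(scope="session")
def trial_cohort():
    return generate_trial(TrialParams(n_per_arm=150, slowing_fraction=0.5, seed=7))


def ranked_params(seed: int, n_subjects: int = 400) -> SimulationParams:
    return SimulationParams(
        n_subjects=n_subjects,
        seed=seed,
        item_sensitivity=dict(RANKED_ITEMS),
        item_noise_sd=dict(RANKED_NOISE),
        dropout_prob_per_visit=0.0,
    )
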