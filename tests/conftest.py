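import pytest

from abrkit import synthetic_cochlea as sc


@pytest.fixture(scope="session")
def quiet_params():
    """Wildtype phenotype with the noise floor switched off."""
    return sc.MousePhenotypeParams(noise_floor_sd_uV=0.0)


@pytest.fixture(scope="session")
def wt_threshold_cohort():
    """Noisy 20-mouse wildtype threshold battery with ground truth."""
    return sc.simulate_cohort(
        20, {"wildtype": sc.GenotypeEffect()}, "thresholds_only", seed=11,
        return_truth=True,
    )


@pytest.fixture(scope="session")
def wt_recovery_cohort():
    return sc.simulate_cohort(
        6, {"wildtype": sc.GenotypeEffect()}, "recovery", seed=7,
        return_truth=True,
    )


@pytest.fixture(scope="session")
def wt_tuning_cohort():
    return sc.simulate_cohort(
        6, {"wildtype": sc.GenotypeEffect()}, "tuning", seed=5,
        return_truth=True,
    )
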