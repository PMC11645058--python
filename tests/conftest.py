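import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from apneasiam.synth import SyntheticPatientConfig, generate_cohort, generate_patient
from apneasiam.pipeline import featurize_cohort, load_cohort
from apneasiam.tune import variant_config


@pytest.fixture(scope="session")
def small_patient():
    """One 120-s synthetic patient with default breathing/apnea structure."""
    cfg = SyntheticPatientConfig(duration_s=120.0, seed=42)
    return generate_patient(cfg, patient_id="p042")


@pytest.fixture(scope="session")
def tiny_feature_table():
    """Mel-8 features of a 3-patient, 120-s cohort (for quick training tests)."""
    base = SyntheticPatientConfig(duration_s=120.0, seed=5)
    manifest = generate_cohort(3, base)
    cohort = load_cohort(manifest)
    return featurize_cohort(cohort, variant_config("mel8"))


@pytest.fixture(scope="session")
def e2e_cohort():
    """The 10-patient, 600-s cohort used by the end-to-end evaluation."""
    base = SyntheticPatientConfig(seed=11)
    manifest = generate_cohort(10, base)
    cohort = load_cohort(manifest)
    table = featurize_cohort(cohort, variant_config("mel8"))
    return cohort, table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
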