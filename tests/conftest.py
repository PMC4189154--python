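import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def korea():
    from sf36map import korea_tariff

    return korea_tariff()


@pytest.fixture(scope="session")
def mixed_cohort():
    """One mid-sized mixed cohort shared across tests (deterministic)."""
    from sf36map import generate_cohort, preset

    df, truth = generate_cohort(preset("mixed", n=1500, seed=42))
    return df


@pytest.fixture(scope="session")
def mixed_design(mixed_cohort):
    """Validated profiles + m1 design for the shared cohort."""
    from sf36map import build_design_matrix, model_spec, validate_profiles

    prof, _ = validate_profiles(mixed_cohort)
    X, labels, clusters = build_design_matrix(prof, model_spec("m1"))
    y = prof["EQ5D"].to_numpy(dtype=float)
    return prof, X, labels, clusters, y
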