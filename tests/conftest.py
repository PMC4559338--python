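import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_2000():
    """A standard 2,000-person synthetic cohort, exclusions applied."""
    from dairyshift.data_model import apply_exclusions
    from dairyshift.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_participants=2000, seed=42)
    participants, days = generate_cohort(cfg)
    kept, _ = apply_exclusions(participants)
    ids = {p.id for p in kept}
    days = [d for d in days if d.participant_id in ids]
    return cfg, kept, days


@pytest.fixture(scope="session")
def calcium_fit(cohort_2000):
    """Fitted calcium usual-intake distribution on the standard cohort."""
    from dairyshift.pipeline import fit_nutrient_distribution

    cfg, kept, days = cohort_2000
    dist, params = fit_nutrient_distribution(kept, days, "calcium", m=100, seed=1)
    return dist, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
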