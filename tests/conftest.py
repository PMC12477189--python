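import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Zero-noise cohort: 20 scenes per treatment, fixed master seed."""
    from phenobox import scenes

    return scenes.generate_cohort(list(scenes.default_treatments().values()), 20, seed=7)
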