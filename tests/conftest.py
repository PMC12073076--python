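import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from milkpep import builtin_enzymes


@pytest.fixture(scope="session")
def enzymes():
    """Built-in enzyme specs keyed by id."""
    return {e.id: e for e in builtin_enzymes()}


@pytest.fixture(scope="session")
def all_enzymes(enzymes):
    return [enzymes["pepsin"], enzymes["trypsin"], enzymes["chymotrypsin"]]
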