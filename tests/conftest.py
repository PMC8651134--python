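import pytest

from payline import (
    DominantDonor,
    GeneratorConfig,
    generate_bundle,
    link_payments,
    normalize_vat,
    profile_practices,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale universe: 8 companies, 300 practices."""
    return GeneratorConfig(
        n_companies=8,
        n_practices=300,
        dominant_donor=DominantDonor(n_payments=80, n_practices=60),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """One full default-calibration bundle (34 companies, 7,500 practices)."""
    return generate_bundle(seed=1)


@pytest.fixture(scope="session")
def linked_default(default_bundle):
    payments = normalize_vat(default_bundle.payments)
    return link_payments(payments, default_bundle.registry)


@pytest.fixture(scope="session")
def profiles_default(linked_default, default_bundle):
    linked, _ = linked_default
    return profile_practices(linked, default_bundle.registry)
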