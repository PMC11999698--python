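import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_morphology():
    from octosim.morphology import build_octopus_morphology

    return build_octopus_morphology()


@pytest.fixture(scope="session")
def density_table():
    from octosim.synapses import load_default_density_table

    return load_default_density_table()


@pytest.fixture(scope="session")
def control_setup():
    """Calibrated control model and its resting state (shared; expensive)."""
    from octosim.protocols import calibrated_reference

    return calibrated_reference("control")


@pytest.fixture(scope="session")
def blocked_setup():
    """Kv+HCN-blocked model held at the control resting potential."""
    from octosim.protocols import calibrated_reference

    return calibrated_reference("kv_hcn_block")
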