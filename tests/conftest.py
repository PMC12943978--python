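import pytest
from hypothesis import HealthCheck, settings

import molprof as mp
from molprof.io import packaged_data_path, read_group_profile, read_orbitals

settings.register_profile(
    "molprof",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("molprof")


@pytest.fixture(scope="session")
def library() -> mp.FragmentLibrary:
    return mp.default_library()


@pytest.fixture(scope="session")
def b134_profile() -> mp.GroupCountProfile:
    return read_group_profile(packaged_data_path("b134_profile.json"))


@pytest.fixture(scope="session")
def b134_smiles() -> str:
    import json

    payload = json.loads(
        packaged_data_path("b134_profile.json").read_text(encoding="utf-8")
    )
    return payload["smiles"]


@pytest.fixture(scope="session")
def b134_orbitals() -> mp.FrontierOrbitalEnergies:
    return read_orbitals(packaged_data_path("b134_orbitals.json"))
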