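import pytest

from cloudamide.kinetics import CloudEnvironment, KineticParameters, UVClass
from cloudamide.profiles import load_packaged_profiles


@pytest.fixture(scope="session")
def library():
    """The packaged reaction-profile library (14 amide, 7 glycol, one 4-mer)."""
    return load_packaged_profiles()


@pytest.fixture()
def warm_cloud():
    """Reference warm dense cloud: 100 K, 1e7 H2 cm^-3, fraction 1e-7, dark-cloud UV."""
    return CloudEnvironment(temperature=100.0, n_h2=1e7, fractional_abundance=1e-7,
                            uv_class=UVClass.DC)


@pytest.fixture()
def dark_cloud_no_uv():
    """Same cloud with the UV channel switched off (closed-system runs)."""
    return CloudEnvironment(temperature=100.0, n_h2=1e7, fractional_abundance=1e-7,
                            uv_class=UVClass.NONE)


@pytest.fixture()
def params():
    """Reference kinetic parameters: k2 = 2e-11 cm^3/s, A in [1e12, 1e15] s^-1."""
    return KineticParameters()


def profile_by(library, pair, conformer=1):
    matches = [p for p in library if p.pair_id == pair and p.conformer_id == conformer]
    assert len(matches) == 1, f"no unique profile {pair}/c{conformer}"
    return matches[0]
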