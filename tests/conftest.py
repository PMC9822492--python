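import pytest

from dermadiff import (
    BrickMortarGeometry,
    CapillaryEquivalent,
    Fluid,
    ParticleSpec,
    build_capillary,
)

# Reference study conditions: 2 cm patch, 20 um keratinocytes, 50 nm lipid
# channels, 10 um keratinocyte height, 1 um capillary, mineral particles of
# 2200 kg/m^3 in liquids of 10/20/50 mPa s.
REF = dict(L=0.02, a=2e-5, d=5e-8, h_k=1e-5)
CAP_LENGTH = 1e-6


@pytest.fixture(scope="session")
def ref_geometry() -> BrickMortarGeometry:
    return BrickMortarGeometry.square(**REF)


@pytest.fixture(scope="session")
def ref_capillary(ref_geometry) -> CapillaryEquivalent:
    return build_capillary(ref_geometry, CAP_LENGTH)


@pytest.fixture(scope="session")
def short_capillary(ref_capillary) -> CapillaryEquivalent:
    """Same cross-section, 0.3 um long: fast passage for simulator tests."""
    return CapillaryEquivalent(
        epsilon=ref_capillary.epsilon,
        a_p=ref_capillary.a_p,
        r_h=ref_capillary.r_h,
        d_c=ref_capillary.d_c,
        length=3e-7,
    )


@pytest.fixture(scope="session")
def water_like() -> Fluid:
    return Fluid(eta=0.01, rho_f=1000.0, T=298.0)


@pytest.fixture(scope="session")
def particle_5nm() -> ParticleSpec:
    return ParticleSpec(d_p=5e-9, rho_p=2200.0)
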