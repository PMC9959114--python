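import pytest

import bilayermech as bm

# Printed reference conditions: DOPC (d0 = 2.69 nm) and DOPG (d0 = 2.84 nm)
# bilayers on a 0.9 mm aperture, dielectric constant 2.5.  The generator
# moduli are chosen so the thin-plate chain yields the published rigidities
# (1.9e-20 J and 0.8e-20 J respectively).
DOPC_KW = dict(zero_field_thickness=2.69e-9, zero_field_area=6.36e-7,
               young_modulus=1.757e7)
DOPG_KW = dict(zero_field_thickness=2.84e-9, zero_field_area=6.36e-7,
               young_modulus=6.29e6)


@pytest.fixture(scope="session")
def protocol():
    return bm.build_protocol()


@pytest.fixture(scope="session")
def dopc_params():
    return bm.SimulationParams(**DOPC_KW, metadata={"lipid": "DOPC"})


@pytest.fixture(scope="session")
def dopg_params():
    return bm.SimulationParams(**DOPG_KW, metadata={"lipid": "DOPG"})


@pytest.fixture(scope="session")
def dopc_trace(dopc_params, protocol):
    return bm.simulate_trace(dopc_params, protocol)


@pytest.fixture(scope="session")
def dopg_trace(dopg_params, protocol):
    return bm.simulate_trace(dopg_params, protocol)


@pytest.fixture(scope="session")
def dopc_report(dopc_trace):
    return bm.run_analysis(dopc_trace)


@pytest.fixture(scope="session")
def dopg_report(dopg_trace):
    return bm.run_analysis(dopg_trace)
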