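"""Shared fixtures: phantoms, probe, protocols and noise-free records.

Session scope keeps the simulated records shared across test modules;
everything is seeded, so the suite is fully deterministic.
"""

import pytest

from indentmap.model import DynamicIndentationModel
from indentmap.records import ProbeSpec, ProtocolSpec
from indentmap.rheology import RheologyModel
from indentmap.simulate import TissuePhantom, simulate_record


@pytest.fixture(scope="session")
def probe():
    return ProbeSpec(stiffness=0.3, tip_radius=60e-6, poisson_ratio=0.5)


@pytest.fixture(scope="session")
def elastic_phantom():
    return TissuePhantom(background=RheologyModel("elastic", 1500.0))


@pytest.fixture(scope="session")
def kv_phantom():
    return TissuePhantom(background=RheologyModel("kelvin_voigt", 1500.0, eta=20.0))


@pytest.fixture(scope="session")
def or_protocol():
    return ProtocolSpec(kind="oscillatory_ramp")


@pytest.fixture(scope="session")
def fs_protocol():
    return ProtocolSpec(kind="frequency_sweep")


@pytest.fixture(scope="session")
def clean_or_record(elastic_phantom, probe, or_protocol):
    return simulate_record(elastic_phantom, probe, or_protocol, seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_fs_record(elastic_phantom, probe, fs_protocol):
    return simulate_record(elastic_phantom, probe, fs_protocol, seed=1, noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_or_results(clean_or_record):
    return DynamicIndentationModel(clean_or_record).fit()


@pytest.fixture(scope="session")
def clean_fs_results(clean_fs_record):
    return DynamicIndentationModel(clean_fs_record).fit()
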