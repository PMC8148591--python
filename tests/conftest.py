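import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stcmix import (
    Direction,
    GeneratorConfig,
    LogisticCRC,
    Treatment,
    TrueScenario,
    equitoxic_design,
    reference_substances,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def substances():
    return reference_substances()


@pytest.fixture(scope="session")
def hyper_pair_design(substances):
    """Equitoxic chlorpyrifos + chlorpyrifos-oxon (both hyperactive)."""
    return equitoxic_design(
        [(n, substances[n].crc()) for n in ("chlorpyrifos", "chlorpyrifos-oxon")],
        label="hyper-pair",
    )


@pytest.fixture(scope="session")
def hyper_b_design(substances):
    """Equitoxic hexaconazole + chlorpyrifos (both hyperactive)."""
    return equitoxic_design(
        [(n, substances[n].crc()) for n in ("hexaconazole", "chlorpyrifos")],
        label="hyper-b",
    )


@pytest.fixture(scope="session")
def ternary_design(substances):
    """Equitoxic chlorpyrifos + hexaconazole + chlorpyrifos-oxon."""
    return equitoxic_design(
        [
            (n, substances[n].crc())
            for n in ("chlorpyrifos", "hexaconazole", "chlorpyrifos-oxon")
        ],
        label="ternary",
    )


@pytest.fixture(scope="session")
def recovery_treatment():
    """Single hyperactive substance with known truth, paper-style range."""
    crc = LogisticCRC(slope_b=1.5, inflection_e=2.0, direction=Direction.HYPERACTIVITY)
    return Treatment(
        "truth",
        ((1.0, crc),),
        (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
    )


@pytest.fixture(scope="session")
def opposing_treatment(substances):
    """Opposing-direction ternary: hyperactive pair plus low-EC50 abamectin."""
    comps = (
        (0.34, substances["chlorpyrifos"].crc()),
        (0.64, substances["hexaconazole"].crc()),
        (0.02, substances["abamectin"].crc()),
    )
    return Treatment("mix-d", comps, (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0))


@pytest.fixture()
def opposing_records(opposing_treatment):
    return simulate_dataset(
        TrueScenario((opposing_treatment,)), GeneratorConfig(seed=3)
    )
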