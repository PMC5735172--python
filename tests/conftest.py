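import pytest

from exorace import (
    AdapterSpec,
    AmpliconTarget,
    ReferenceIndex,
    SimulationConfig,
    generate_reference,
)


@pytest.fixture(scope="session")
def ets_reference():
    """Small random reference carrying the 5' ETS search sequence once."""
    return generate_reference(300, "ets_pp1", seed=7)


@pytest.fixture
def adapter():
    return AdapterSpec()


@pytest.fixture
def micro_ref():
    """20-nt toy reference for hand-checkable mapping examples."""
    sequence = "ACGTTGCAGGTCAATCGGAT"
    target = AmpliconTarget(name="ets_pp1", search_seq="ACGTT", anchor_position=1)
    return ReferenceIndex(sequence, target)


def make_config(reference, target, **overrides):
    defaults = dict(
        reference=reference,
        target=target,
        n_molecules=500,
        duplication_mean=1.0,
        error_rate=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
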