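import pytest

import ceatree as ct


@pytest.fixture(scope="session")
def finger_model():
    """The bundled calibrated phalangeal-fracture model (read-only in tests)."""
    return ct.build_model()


@pytest.fixture
def published_outcomes():
    """The published per-strategy (cost €, QALY) triple."""
    return [
        ct.StrategyOutcome("CR", 32.0, 7.9),
        ct.StrategyOutcome("CBCT", 67.33, 9.08),
        ct.StrategyOutcome("MSCT", 106.23, 8.18),
    ]
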