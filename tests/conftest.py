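import pytest

from flowrig import ColumnBed, FeedStream


@pytest.fixture
def bed() -> ColumnBed:
    """The 100 x 6.6 mm bed: 2.0 mL void, 2.5 g catalyst, 1.08 mmol water."""
    return ColumnBed(void_volume=2.0, n_tanks=20, water_capacity=1.08)


@pytest.fixture
def dry_feed() -> FeedStream:
    """0.06 M nitrile in rigorously dry solvent at 0.1 mL/min."""
    return FeedStream(flow_rate=0.1, nitrile=0.06, water=0.0)


@pytest.fixture
def aqueous_feed() -> FeedStream:
    """0.06 M nitrile with excess water at 0.1 mL/min."""
    return FeedStream(flow_rate=0.1, nitrile=0.06, water=0.6)
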