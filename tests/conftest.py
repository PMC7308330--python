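import numpy as np
import pytest

from paradiddle import CaptureWindow, DrumEvent, LimbMap, make_template


@pytest.fixture
def limb_map():
    return LimbMap()


@pytest.fixture
def quarter():
    return make_template("quarter_pattern", 120.0)


@pytest.fixture
def eighth():
    return make_template("eighth_pattern", 120.0)


@pytest.fixture
def window():
    return CaptureWindow()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def perfect_quarter_events(grid):
    """One event at every expected strike's exact nominal time."""
    return [
        DrumEvent(slot.nominal_ms, instrument, limb)
        for slot in grid.slots
        for limb, instrument in sorted(slot.expected)
    ]
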