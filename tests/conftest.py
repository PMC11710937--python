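import pytest

from socioscope import Component, Ethogram, Individual, ScanRecord


@pytest.fixture
def ears_ethogram():
    """Four components in two morphological groups plus two singletons."""
    return Ethogram([
        Component("ears_forward", "ears"),
        Component("ears_back", "ears"),
        Component("mouth_open", "mouth"),
        Component("mouth_closed", "mouth"),
        Component("squeal", "squeal", modality="acoustic"),
        Component("nose_touch", "nose_touch", modality="tactile"),
    ])


@pytest.fixture
def trio_roster():
    return [
        Individual("a", "H1", "stallion", 120.0),
        Individual("b", "H1", "lactating_female", 96.0),
        Individual("c", "H1", "nonlactating_female", 84.0),
    ]


def make_scans(period_pairs, harem_id="H1"):
    """Build scan records from {period: [(individual, neighbor), ...]}."""
    out = []
    for pid, rows in period_pairs.items():
        for ind, nbr in rows:
            out.append(ScanRecord(harem_id=harem_id, period_id=pid,
                                  individual_id=ind, neighbor_id=nbr))
    return out
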