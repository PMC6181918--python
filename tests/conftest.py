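import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import qsmlm


@pytest.fixture(scope="session")
def bt474_roi():
    """One simulated clustered ROI (table, ground truth), reused across tests."""
    return qsmlm.simulate_roi(qsmlm.preset("bt474"), seed=101)


@pytest.fixture(scope="session")
def random_roi():
    """One simulated monomer (unclustered) ROI."""
    return qsmlm.simulate_random_roi(qsmlm.preset("random"), seed=101)


@pytest.fixture(scope="session")
def bt474_analysis(bt474_roi):
    table, _ = bt474_roi
    return qsmlm.analyze_roi(table)


@pytest.fixture(scope="session")
def random_analysis(random_roi):
    table, _ = random_roi
    return qsmlm.analyze_roi(table)
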