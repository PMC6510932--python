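import numpy as np
import pandas as pd
import pytest

from replinet.contact_log import Phase, StudyDesign


@pytest.fixture
def small_design():
    """Two groups of three residents, three 2-day phases (fast event sims)."""
    return StudyDesign(
        n_groups=2, residents_per_group=3,
        phases=(Phase("1", 1, 2), Phase("2a", 3, 4), Phase("2b", 5, 6)))


@pytest.fixture
def full_design():
    """The exemplar cattle-study layout: 6 groups x 5 residents, three 6-day phases."""
    return StudyDesign()


@pytest.fixture
def tiny_roster():
    return pd.DataFrame({
        "group_id": ["g1", "g1", "g1", "g2", "g2", "g2"],
        "animal_id": ["g1c1", "g1c2", "g1u1", "g2c1", "g2c2", "g2u1"],
        "role": ["resident", "resident", "unfamiliar",
                 "resident", "resident", "unfamiliar"],
    })


def records_frame(rows):
    """Build a raw-records frame from (group, logger, partner, start, duration) tuples."""
    return pd.DataFrame(
        rows, columns=["group_id", "logger_animal", "partner_animal", "start_s", "duration_s"])


def intervals_frame(rows):
    """Build an interval frame from (group, a, b, start, end) tuples."""
    return pd.DataFrame(
        rows, columns=["group_id", "animal_a", "animal_b", "start_s", "end_s"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
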