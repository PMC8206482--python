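import numpy as np
import pytest

from wordingsim.datagen import SampleData


@pytest.fixture
def rng():
    return np.random.default_rng(20210602)


def make_sample(responses, polarity=None, flags=None, criterion=None):
    """SampleData from a plain response matrix, defaulting to a balanced scale."""
    responses = np.asarray(responses, dtype=int)
    n, k = responses.shape
    if polarity is None:
        polarity = np.array(["PW"] * (k // 2) + ["NW"] * (k - k // 2))
    if flags is None:
        flags = np.zeros(n, dtype=bool)
    if criterion is None:
        criterion = np.zeros(n)
    return SampleData(responses, criterion, np.asarray(polarity), np.asarray(flags, dtype=bool))


# Worked-example response patterns for a 10-item balanced scale (5 PW then
# 5 NW), for a hypothetical low- and high-trait examinee misresponding to 50%
# of the items under each wording effect.
PATTERNS = {
    "low_none": [1, 1, 1, 2, 2, 3, 3, 4, 4, 4],
    "low_careless": [1, 1, 1, 2, 2, 2, 2, 1, 1, 1],
    "low_ivd": [4, 4, 4, 3, 3, 3, 3, 4, 4, 4],
    "high_none": [4, 4, 4, 3, 3, 2, 2, 1, 1, 1],
    "high_careless": [4, 4, 4, 3, 3, 3, 3, 4, 4, 4],
    "high_ivd": [4, 4, 4, 3, 3, 3, 3, 4, 4, 4],
}


def reverse_coded_sum(row):
    """Raw sum score with the five NW items reverse-coded."""
    row = np.asarray(row)
    return int(row[:5].sum() + (5 - row[5:]).sum())
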