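import re

import numpy as np
import pytest


def nonwear_oracle(counts, window_min=60, allowance_max=2, allowance_ceiling=100):
    """Independent reference for non-wear detection.

    Encodes the day as symbols (0 = zero counts, i = tolerated interruption,
    b = breaker) and finds maximal runs with a regular expression: a run is
    zeros, with groups of at most `allowance_max` interruption minutes that
    must be followed by more zeros.  Runs of total length >= window_min are
    non-wear.
    """
    counts = np.asarray(counts)
    symbols = "".join(
        "0" if c == 0 else ("i" if c < allowance_ceiling else "b") for c in counts
    )
    pattern = re.compile(rf"0+(?:i{{1,{allowance_max}}}0+)*") if allowance_max else re.compile("0+")
    wear = np.ones(len(counts), dtype=bool)
    for m in pattern.finditer(symbols):
        if m.end() - m.start() >= window_min:
            wear[m.start():m.end()] = False
    return wear


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
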