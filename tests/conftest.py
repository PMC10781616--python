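import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231120)


@pytest.fixture
def three_gen_pedigree():
    """Three generations with a half-sib pair and an inbred mating.

    ids 0..7: founders 0 (M), 1 (F), 2 (F); 3 = 0x1 (M), 4 = 0x1 (F),
    5 = 0x2 (M) (half sib of 3/4); 6 = 3x4 (full-sib mating, inbred);
    7 = 5x4.
    """
    return pd.DataFrame(
        {
            "id": [0, 1, 2, 3, 4, 5, 6, 7],
            "sire": [-1, -1, -1, 0, 0, 0, 3, 5],
            "dam": [-1, -1, -1, 1, 1, 2, 4, 4],
            "sex": ["M", "F", "F", "M", "F", "M", "F", "M"],
            "line": [0] * 8,
            "regime": ["control"] * 8,
            "generation": ["parent"] * 3 + ["offspring"] * 5,
            "family": [0] * 8,
        }
    )
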