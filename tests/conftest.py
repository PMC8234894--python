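import numpy as np
import pandas as pd
import pytest

from ssgblup.pedigree import Pedigree


def random_pedigree(seed: int, n_founders: int = 10, n_extra: int = 40) -> Pedigree:
    """Small random pedigree where later animals draw parents (possibly
    unknown) from anything older — exercises overlapping generations and
    inbreeding loops."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_founders):
        rows.append(("X%03d" % i, "0", "0", 2000, "M" if i % 2 else "F"))
    for i in range(n_founders, n_founders + n_extra):
        s = rng.integers(0, i)
        d = rng.integers(0, i)
        rows.append(
            (
                "X%03d" % i,
                rows[s][0] if rng.random() < 0.9 else "0",
                rows[d][0] if rng.random() < 0.9 else "0",
                2001 + i // 10,
                "M" if rng.random() < 0.5 else "F",
            )
        )
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year", "sex"])
    return Pedigree(df)


@pytest.fixture
def trio_frame():
    return pd.DataFrame(
        {
            "animal": ["s", "d", "o"],
            "sire": ["0", "0", "s"],
            "dam": ["0", "0", "d"],
            "birth_year": [2000, 2000, 2001],
            "sex": ["M", "F", "M"],
        }
    )


@pytest.fixture
def fullsib_incest_frame():
    # two full sibs mated: their offspring has F = 0.25
    return pd.DataFrame(
        {
            "animal": ["s", "d", "a", "b", "o"],
            "sire": ["0", "0", "s", "s", "a"],
            "dam": ["0", "0", "d", "d", "b"],
            "birth_year": [2000, 2000, 2001, 2001, 2002],
            "sex": ["M", "F", "M", "F", "M"],
        }
    )
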