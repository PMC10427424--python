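import numpy as np
import pandas as pd
import pytest

from tcrtme.repertoire import ClonotypeTable


def make_table(counts, cdr3=None, v=None, j=None, **meta) -> ClonotypeTable:
    """Small helper: a clonotype table from a count vector (productive CDR3s)."""
    n = len(counts)
    cdr3 = cdr3 or [f"CASS{chr(65 + i % 26)}{i:03d}LF" for i in range(n)]
    df = pd.DataFrame(
        {
            "count": list(counts),
            "freq": 0.0,
            "cdr3nt": ".",
            "cdr3aa": cdr3,
            "v": v or ["TRBV1"] * n,
            "d": ".",
            "j": j or ["TRBJ1"] * n,
        }
    )
    return ClonotypeTable(df, **meta)


@pytest.fixture
def singleton_table():
    """1,000 distinct productive clonotypes, each seen exactly once."""
    return make_table([1] * 1000)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
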