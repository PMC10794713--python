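import numpy as np
import pandas as pd
import pytest

from capsidmorph.rnaquant import ReferenceSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def two_ref_set():
    """Two equal-length CDS references so read fractions equal TPM fractions."""
    return ReferenceSet(
        lengths={"CP": 807, "hns": 807},
        classes={"CP": "CP", "hns": "other"},
    )


def make_alignments(rows):
    """Build an alignment table from (read_id, ref_id, start, end, mapq) tuples."""
    return pd.DataFrame(rows, columns=["read_id", "ref_id", "start", "end", "mapq"])
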