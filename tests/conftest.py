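import numpy as np
import pandas as pd
import pytest

from nucleoscan import AmpliconDesign
from nucleoscan.variant_calling import annotate_variant
from nucleoscan.synthetic_data import synthetic_design


@pytest.fixture(scope="session")
def design():
    """Full-size (42-codon) synthetic amplicon design with 25-nt flanks."""
    return synthetic_design()


@pytest.fixture(scope="session")
def mini_design():
    """A 4-codon design for hand-checkable unit tests."""
    return AmpliconDesign(wt_coding_seq="ATGGCTTTTAAA", flank5="ACGTACGTAA", flank3="TTGGCCAACC")


def make_count_table(design, rows):
    """Build an annotated count table from (nt_seq, {sample: count}) pairs."""
    records = []
    for nt_seq, counts in rows:
        rec = annotate_variant(nt_seq, design)
        rec.pop("reject_reason")
        rec.update(counts)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
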