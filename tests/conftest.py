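import numpy as np
import pandas as pd
import pytest

from perihg.community import AsvTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_asv_table(counts: dict, lineages: dict, sites: dict) -> AsvTable:
    """Small AsvTable from plain dicts.

    ``counts``: sample -> {asv: count}; ``lineages``: asv -> (domain..family
    tuple, short tuples padded); ``sites``: sample -> site label.
    """
    counts_df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    ranks = ["domain", "phylum", "class", "order", "family"]
    lin_rows = {}
    for asv, names in lineages.items():
        names = list(names) + [""] * (5 - len(names))
        lin_rows[asv] = dict(zip(ranks, names))
    lineages_df = pd.DataFrame.from_dict(lin_rows, orient="index")
    metadata_df = pd.DataFrame(
        {
            "site": pd.Series(sites),
            "treatment": "t0",
            "molecule": "rDNA",
        }
    )
    return AsvTable(counts=counts_df, lineages=lineages_df, metadata=metadata_df)
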