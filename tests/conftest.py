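import numpy as np
import pandas as pd
import pytest

from ripscan.enrichment import CountTable

#: 13-nt stem-loop presenting GUG in the loop of a 5-bp stem; the shared
#: worked example for folding and variant classification.
TOY_HAIRPIN = "GGCACGUGGUGCC"


def make_count_table(
    counts: dict[str, list[int]],
    gene_ids: list[str] | None = None,
    gene_types: list[str] | None = None,
) -> CountTable:
    """Build a CountTable from {sample_label: counts}; labels follow the
    <strain>_<protocol>_<role> convention."""
    n = len(next(iter(counts.values())))
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    meta = {}
    for label in counts:
        strain, protocol, role = label.rsplit("_", 2)
        meta[label] = {"strain": strain, "protocol": protocol, "role": role}
    samples = pd.DataFrame(meta).T
    samples.index.name = "sample"
    types = (
        pd.Series(gene_types, index=df.index) if gene_types is not None else None
    )
    return CountTable(counts=df, samples=samples, gene_types=types)


@pytest.fixture
def paired_table() -> CountTable:
    """Four genes, tagged + untagged Input/Bound pairs, totals 100 each."""
    return make_count_table(
        {
            "HTS1_TAP_Input": [40, 30, 20, 10],
            "HTS1_TAP_Bound": [70, 10, 10, 10],
            "untagged_TAP_Input": [40, 30, 20, 10],
            "untagged_TAP_Bound": [40, 30, 20, 10],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)
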