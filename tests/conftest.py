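"""Shared fixtures: small deterministic trees, tables and metadata."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from assemblage import CommunityTable, SampleMetadata

# 10-tip ultrametric tree used by several oracle-checked tests; the
# Newick string is frozen so expected values stay valid verbatim.
TEN_TIP_NEWICK = (
    "((t0001:0.31755628862793367,(t0002:0.057162495376290326,"
    "t0003:0.057162495376290326):0.26039379325164336):0.6824437113720664,"
    "((t0004:0.3406509098925278,t0005:0.3406509098925278)"
    ":0.2624554495751643,(((t0006:0.14030573042801073,"
    "t0007:0.14030573042801073):0.0037400323203871325,"
    "t0008:0.14404576274839784):0.0775867828923306,"
    "(t0009:0.0971134151129119,t0010:0.0971134151129119)"
    ":0.12451913052781655):0.38147381382696366):0.39689364053230797);"
)

TEN_TAXA = [f"t{i:04d}" for i in range(1, 11)]


@pytest.fixture(scope="session")
def ten_tip_tree() -> TreeNode:
    return TreeNode.read([TEN_TIP_NEWICK])


@pytest.fixture
def small_table() -> CommunityTable:
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(6, 10)) * (rng.random((6, 10)) < 0.6)
    counts[:, 0] += 1  # guarantee a ubiquitous taxon
    ids = [f"s{i}" for i in range(6)]
    return CommunityTable(pd.DataFrame(counts, index=ids, columns=TEN_TAXA))


@pytest.fixture
def design_metadata() -> SampleMetadata:
    """2 datasets x 1 stage x 2 months (+pH) covering six samples s0..s5."""
    rows = []
    i = 0
    for ds in ("DNA", "RNA"):
        for month in ("May", "Jul"):
            for rep in (1, 2):
                if i >= 6:
                    break
                rows.append((f"s{i}", ds, 0, month, rep, 6.5 + 0.1 * i))
                i += 1
    df = pd.DataFrame(
        rows, columns=["sample_id", "dataset", "stage_year", "month",
                       "replicate", "pH"],
    ).set_index("sample_id")
    return SampleMetadata(df)


def random_tree(n_tips: int, seed: int) -> TreeNode:
    from assemblage import simulate_tree

    return simulate_tree(n_tips, seed)
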