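import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from dysbiome.core import FeatureTable, SampleMetadata


def make_table(counts, taxa=None, samples=None, lineages=None) -> FeatureTable:
    counts = np.asarray(counts)
    taxa = taxa or [f"T{i:04d}" for i in range(counts.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(counts.shape[1])]
    lin = None
    if lineages is not None:
        lin = pd.Series(lineages, index=taxa)
    return FeatureTable(pd.DataFrame(counts, index=taxa, columns=samples), lin)


def make_metadata(groups: dict) -> SampleMetadata:
    return SampleMetadata(pd.Series(groups))


@pytest.fixture
def tiny_table() -> FeatureTable:
    return make_table(
        [[5, 0, 3], [2, 8, 0], [1, 1, 7], [0, 4, 2]],
        lineages=[
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__;s__",
            "k__Bacteria;p__Bacteroidetes;c__;o__;f__;g__;s__",
            "k__Bacteria;p__Cyanobacteria;c__Chloroplast;o__;f__;g__;s__",
            "k__Bacteria;p__Proteobacteria;c__;o__;f__mitochondria;g__;s__",
        ],
    )


@pytest.fixture
def star_tree() -> TreeNode:
    """Effectively a star: four unit-length leaves, zero-length internals
    (kept bifurcating at the root, which phylogenetic metrics require)."""
    return TreeNode.read(["((T0000:1,T0001:1):0,(T0002:1,T0003:1):0):0;"])


def two_group_metadata(n1: int, n2: int, labels=("CD", "HC")) -> SampleMetadata:
    ids = [f"S{i:03d}" for i in range(n1 + n2)]
    return make_metadata(dict(zip(ids, [labels[0]] * n1 + [labels[1]] * n2)))
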