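import numpy as np
import pandas as pd
import pytest

from elevdiv.phylo import TreeIndex, read_tree
from elevdiv.traits import bundled_trait_matrix


@pytest.fixture(scope="session")
def table1():
    return bundled_trait_matrix()


@pytest.fixture()
def example_tree():
    """((A:1,B:1):1,C:2) — the module's hand-traceable reference tree."""
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def five_tip_index():
    tree = read_tree("((A:0.3,B:0.5):0.7,((C:0.4,D:0.6):0.2,E:0.9):0.3);")
    return TreeIndex(tree)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_community(counts, locations, **meta):
    """Small helper: counts dict-of-dicts / frame -> CommunityMatrix."""
    from elevdiv.community import CommunityMatrix

    counts = pd.DataFrame(counts).fillna(0).astype(int)
    md = pd.DataFrame(index=counts.index)
    md["location"] = locations
    md["habitat"] = meta.get("habitat", "forest")
    md["year"] = meta.get("year", 2018)
    return CommunityMatrix(counts=counts, metadata=md)
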