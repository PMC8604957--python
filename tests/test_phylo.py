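import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from elevdiv.phylo import (TreeIndex, faith_pd, mntd_weighted, mpd_weighted,
                           prune_tree, read_tree, tip_distance_matrix)

ABC_DIST = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]],
                        index=list("ABC"), columns=list("ABC"))


class TestPrune:
    def test_keep_all_is_identity(self, example_tree):
        pruned = prune_tree(example_tree, {"A", "B", "C"})
        assert tip_distance_matrix(pruned).equals(
            tip_distance_matrix(example_tree))

    def test_internal_node_collapsed_with_summed_lengths(self, example_tree):
        pruned = prune_tree(example_tree, {"A", "C"})
        d = tip_distance_matrix(pruned)
        assert d.loc["A", "C"] == pytest.approx(4.0)  # (A:2,C:2)
        depths = {l.taxon.label: l.distance_from_root()
                  for l in pruned.leaf_node_iter()}
        assert depths == {"A": pytest.approx(2.0), "C": pytest.approx(2.0)}

    def test_substitution_map_relabels_before_pruning(self):
        tree = read_tree("((Eptesicus_serotinus:1,B:1):1,C:2);")
        pruned = prune_tree(tree, {"EH", "C"},
                            substitutions={"EH": "Eptesicus_serotinus"})
        assert sorted(l.taxon.label for l in pruned.leaf_node_iter()) == ["C", "EH"]

    def test_missing_taxa_listed(self, example_tree):
        with pytest.raises(ValueError, match="Z"):
            prune_tree(example_tree, {"A", "Z"})


class TestFaithPD:
    def test_hand_summation(self, example_tree):
        assert faith_pd(example_tree, {"A", "B"}) == pytest.approx(3.0)

    def test_all_tips_is_total_branch_length(self, example_tree):
        assert faith_pd(example_tree, {"A", "B", "C"}) == pytest.approx(5.0)

    def test_single_taxon_root_path(self, example_tree):
        assert faith_pd(example_tree, {"C"}) == pytest.approx(2.0)
        assert faith_pd(example_tree, {"C"}, include_root=False) == 0.0

    def test_monotone_in_present_set(self, five_tip_index):
        taxa = five_tip_index.taxa
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = rng.integers(1, len(taxa))
            sub = list(rng.choice(taxa, size=k, replace=False))
            extra = [t for t in taxa if t not in sub][0]
            assert faith_pd(five_tip_index, sub + [extra]) >= \
                faith_pd(five_tip_index, sub) - 1e-12


class TestWeightedDistances:
    def test_mpd_equal_weights(self):
        w = pd.Series([1, 1, 1.0], index=list("ABC"))
        assert mpd_weighted(ABC_DIST, w) == pytest.approx(10 / 3)

    def test_mpd_weighted_hand_example(self):
        w = pd.Series([0.5, 0.25, 0.25], index=list("ABC"))
        assert mpd_weighted(ABC_DIST, w) == pytest.approx(3.2)

    def test_two_taxa_weights_cancel(self):
        d = ABC_DIST.loc[["A", "B"], ["A", "B"]]
        for wa in (0.9, 0.5, 0.2):
            w = pd.Series([wa, 1 - wa], index=["A", "B"])
            assert mpd_weighted(d, w) == pytest.approx(2.0)
            assert mntd_weighted(d, w) == pytest.approx(2.0)

    def test_mntd_equal_weights(self):
        w = pd.Series([1, 1, 1.0], index=list("ABC"))
        assert mntd_weighted(ABC_DIST, w) == pytest.approx(8 / 3)

    def test_zero_weight_taxa_dropped(self):
        w = pd.Series([1.0, 0.0, 0.0], index=list("ABC"))
        assert np.isnan(mpd_weighted(ABC_DIST, w))
        assert np.isnan(mntd_weighted(ABC_DIST, w))

    def test_weight_scale_invariance(self):
        w = pd.Series([2.0, 5.0, 3.0], index=list("ABC"))
        for c in (0.1, 7.0):
            assert mpd_weighted(ABC_DIST, c * w) == \
                pytest.approx(mpd_weighted(ABC_DIST, w))
            assert mntd_weighted(ABC_DIST, c * w) == \
                pytest.approx(mntd_weighted(ABC_DIST, w))


# ----------------------------------------------------------------------
# brute-force oracle: path-set arithmetic on random trees
# ----------------------------------------------------------------------

def _paths_to_root(tree):
    paths = {}
    for leaf in tree.leaf_node_iter():
        node, edges = leaf, []
        while node.parent_node is not None:
            edges.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    return paths


def test_indices_match_path_set_oracle():
    """PD/MPD/MNTD agree exactly with naive root-path set arithmetic on 50
    random birth trees."""
    from elevdiv.synthetic import _yule_subtree

    rng = np.random.default_rng(77)
    for rep in range(50):
        labels = [f"t{i}" for i in range(6)]
        tree = read_tree(_yule_subtree(labels, 1.0, rng) + ";")
        idx = TreeIndex(tree)
        paths = _paths_to_root(tree)
        length = lambda nodes: sum(n.edge.length or 0.0 for n in nodes)
        k = int(rng.integers(2, 6))
        present = list(rng.choice(labels, size=k, replace=False))
        # Faith PD: union of root paths
        union = set()
        for t in present:
            union |= set(paths[t])
        assert faith_pd(idx, present) == pytest.approx(length(union), rel=1e-9)
        # pairwise distances via symmetric difference of root paths
        d = pd.DataFrame(0.0, index=present, columns=present)
        for a in present:
            for b in present:
                if a != b:
                    d.loc[a, b] = length(set(paths[a]) ^ set(paths[b]))
        w = pd.Series(rng.dirichlet(np.ones(k)), index=present)
        sub = idx.distances.loc[present, present]
        np.testing.assert_allclose(sub.to_numpy(), d.to_numpy(), rtol=1e-9)
        num = sum(d.loc[a, b] * w[a] * w[b]
                  for a in present for b in present if a != b)
        den = sum(w[a] * w[b] for a in present for b in present if a != b)
        assert mpd_weighted(sub, w) == pytest.approx(num / den, rel=1e-9)
        mn = sum(w[a] * min(d.loc[a, b] for b in present if b != a)
                 for a in present)
        assert mntd_weighted(sub, w) == pytest.approx(mn / w.sum(), rel=1e-9)


def test_matches_picante_reference(five_tip_index):
    """Independent R/picante computation agrees on a fixed 5-tip tree.

    picante's abundance-weighted MPD averages over *all* ordered pairs
    including i=j, so its value equals ours times (1 - sum w~^2).
    """
    idx = five_tip_index
    present = ["A", "C", "E"]
    w = pd.Series([3.0, 1.0, 2.0], index=present)
    script = """
    suppressMessages(library(picante))
    tr <- read.tree(text="((A:0.3,B:0.5):0.7,((C:0.4,D:0.6):0.2,E:0.9):0.3);")
    comm <- matrix(c(3,0,1,0,2), nrow=1, dimnames=list("s1", c("A","B","C","D","E")))
    cat(pd(comm, tr, include.root=TRUE)$PD,
        pd(comm, tr, include.root=FALSE)$PD,
        mpd(comm, cophenetic(tr), abundance.weighted=TRUE),
        mntd(comm, cophenetic(tr), abundance.weighted=TRUE), sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    r_pd, r_pd_nr, r_mpd, r_mntd = map(float, out.stdout.split())
    assert faith_pd(idx, present) == pytest.approx(r_pd, rel=1e-6)
    assert faith_pd(idx, present, include_root=False) == \
        pytest.approx(r_pd_nr, rel=1e-6)
    wn = (w / w.sum()).to_numpy()
    factor = 1 - (wn ** 2).sum()
    assert mpd_weighted(idx.distances, w) * factor == \
        pytest.approx(r_mpd, rel=1e-5)
    assert mntd_weighted(idx.distances, w) == pytest.approx(r_mntd, rel=1e-6)


def test_negative_branch_length_rejected():
    with pytest.raises(ValueError, match="negative"):
        read_tree("((A:1,B:-0.5):1,C:2);")
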