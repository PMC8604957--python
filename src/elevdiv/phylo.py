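"""Phylogeny handling and phylogenetic diversity indices.

Trees are read with dendropy (newick or nexus).  Tip labels must map onto
community taxa; when published sequences are missing for a taxon, a
substitution map relabels its closest relative before pruning, mirroring
standard practice of standing in close relatives for unsequenced species.

Indices:

* Faith's PD — summed branch lengths of the minimal subtree spanning the
  taxa present; with ``include_root=True`` (the default convention of the
  community-phylogenetics packages this module mirrors) the path from the
  spanning subtree up to the root is included.
* MPD — abundance-weighted mean pairwise tip distance,
  sum_{i!=j} d_ij w_i w_j / sum_{i!=j} w_i w_j.
* MNTD — abundance-weighted mean nearest-taxon distance,
  sum_i w_i min_{j!=i} d_ij / sum_i w_i.

Zero-weight taxa are removed before MPD/MNTD (equivalent under both
formulas).  A :class:`TreeIndex` pre-extracts edge/descendant structure and
the tip distance matrix so the null-model loop can score thousands of
communities cheaply.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_tree", "prune_tree", "tip_distance_matrix", "TreeIndex",
    "faith_pd", "mpd_weighted", "mntd_weighted",
]


# ----------------------------------------------------------------------
# I/O and pruning
# ----------------------------------------------------------------------

def read_tree(source) -> dendropy.Tree:
    """Read a rooted tree from a newick/nexus path or a newick string."""
    if isinstance(source, dendropy.Tree):
        return source
    text = None
    path = Path(str(source))
    if path.exists():
        text = path.read_text()
    elif isinstance(source, str):
        text = source
    else:
        raise FileNotFoundError(source)
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    tree = dendropy.Tree.get(data=text, schema=schema,
                             preserve_underscores=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def _tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, keep, substitutions: dict | None = None
               ) -> dendropy.Tree:
    """Induced subtree on ``keep`` tips, after optional relabelling.

    ``substitutions`` maps desired taxon label -> label currently on the
    tree (e.g. a sonotype code to the stand-in species representing it);
    relabelling happens before pruning.  Degree-2 internal nodes created by
    the pruning are collapsed with their branch lengths summed; the root is
    retained.
    """
    tree = tree.clone(depth=1)
    if substitutions:
        reverse = {v: k for k, v in substitutions.items()}
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label in reverse:
                leaf.taxon.label = reverse[leaf.taxon.label]
    labels = set(keep)
    have = set(_tip_labels(tree))
    missing = sorted(labels - have)
    if missing:
        raise ValueError(f"taxa not on tree (after substitutions): {missing}")
    tree.retain_taxa_with_labels(sorted(labels))
    return tree


def read_substitution_map(path) -> dict:
    """Two-column CSV: taxon label used in the analysis, tree tip label."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("substitution map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ----------------------------------------------------------------------
# cached tree structure
# ----------------------------------------------------------------------

class TreeIndex:
    """Edge lengths, descendant masks and tip distances for fast queries."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.taxa = sorted(_tip_labels(tree))
        pos = {t: i for i, t in enumerate(self.taxa)}
        lengths, masks = [], []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            mask = np.zeros(len(self.taxa), dtype=bool)
            for leaf in node.leaf_iter():
                mask[pos[leaf.taxon.label]] = True
            lengths.append(node.edge.length or 0.0)
            masks.append(mask)
        self.edge_lengths = np.asarray(lengths, dtype=float)
        self.edge_masks = np.asarray(masks, dtype=bool)
        # tip-to-tip patristic distances
        pdm = tree.phylogenetic_distance_matrix()
        d = np.zeros((len(self.taxa), len(self.taxa)))
        taxa_objs = {t.label: t for t in tree.taxon_namespace
                     if t.label in pos}
        for a in self.taxa:
            for b in self.taxa:
                if a < b:
                    dist = pdm.patristic_distance(taxa_objs[a], taxa_objs[b])
                    d[pos[a], pos[b]] = d[pos[b], pos[a]] = dist
        self.distances = pd.DataFrame(d, index=self.taxa, columns=self.taxa)

    def presence_vector(self, present) -> np.ndarray:
        vec = np.zeros(len(self.taxa), dtype=bool)
        for t in present:
            vec[self.taxa.index(t)] = True
        return vec

    def faith_pd(self, present_mask: np.ndarray, include_root: bool = True) -> float:
        npres = int(present_mask.sum())
        if npres == 0:
            return 0.0
        counts = self.edge_masks[:, present_mask].sum(axis=1)
        touched = counts > 0
        if include_root:
            return float(self.edge_lengths[touched].sum())
        below_mrca = touched & (counts < npres)
        return float(self.edge_lengths[below_mrca].sum())


# ----------------------------------------------------------------------
# public index functions
# ----------------------------------------------------------------------

def tip_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (branch-length path) distances between all tip pairs."""
    return TreeIndex(tree).distances


def faith_pd(tree, present, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of the taxa in ``present``.

    Empty communities return 0; a single taxon contributes its root path
    when ``include_root`` (otherwise 0, the empty spanning tree).
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(read_tree(tree))
    missing = sorted(set(present) - set(idx.taxa))
    if missing:
        raise ValueError(f"taxa not on tree: {missing}")
    return idx.faith_pd(idx.presence_vector(present), include_root)


def _weight_arrays(dist: pd.DataFrame, weights: pd.Series):
    w = weights[weights > 0]
    d = dist.loc[w.index, w.index].to_numpy(dtype=float)
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return d, w.to_numpy(dtype=float)


def mpd_weighted(dist: pd.DataFrame, weights: pd.Series) -> float:
    """Abundance-weighted mean pairwise distance; NaN for < 2 taxa."""
    d, w = _weight_arrays(dist, weights)
    if len(w) < 2:
        return np.nan
    num = float(w @ d @ w)            # diagonal of d is zero
    den = float(w.sum() ** 2 - (w ** 2).sum())
    return num / den


def mntd_weighted(dist: pd.DataFrame, weights: pd.Series) -> float:
    """Abundance-weighted mean nearest-taxon distance; NaN for < 2 taxa."""
    d, w = _weight_arrays(dist, weights)
    if len(w) < 2:
        return np.nan
    np.fill_diagonal(d, np.inf)
    return float(w @ d.min(axis=1) / w.sum())
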