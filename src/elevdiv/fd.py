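"""Multivariate functional diversity indices.

Four community-level indices computed in a Euclidean trait space (normally
PC scores from :mod:`elevdiv.traits`):

* FRic — convex-hull volume of the taxa present, standardized by the hull
  volume of the full taxon pool, so it lies in (0, 1].
* FEve — regularity of abundance along the community's minimum spanning
  tree in trait space (Villeger et al. formulation), in [0, 1].
* FDiv — degree to which abundance sits on taxa far from the community's
  hull-vertex centre of gravity (Villeger et al.), in (0, 1].
* FDis — abundance-weighted mean distance of taxa to the abundance-weighted
  centroid (Laliberte & Legendre), >= 0 in trait-space distance units.

Communities too small or too degenerate for an index are flagged rather
than silently dropped.  When the smallest community has no more taxa than
the trait-space dimensionality, the axis set is reduced *globally* for the
whole comparison set so the FRic standardization stays coherent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .community import CommunityMatrix
from .traits import TraitSpace

__all__ = [
    "hull_volume", "fric", "feve", "fdiv", "fdis", "fd_all", "effective_axes",
]


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def hull_volume(points: np.ndarray):
    """Convex-hull volume and vertex indices; 1-D volume is the range.

    Returns ``(volume, vertices)``; raises :class:`scipy.spatial.QhullError`
    for degenerate (lower-dimensional) point sets in >= 2 dimensions.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-D (taxa x axes)")
    n, d = points.shape
    if d == 1:
        lo, hi = int(np.argmin(points[:, 0])), int(np.argmax(points[:, 0]))
        return float(points[hi, 0] - points[lo, 0]), np.unique([lo, hi])
    hull = ConvexHull(points)
    return float(hull.volume), hull.vertices


def _mst_edges(dist: np.ndarray):
    """Prim's minimum spanning tree on a dense distance matrix.

    Hand-rolled rather than csgraph because zero-length edges (duplicated
    trait positions) are legitimate here, while sparse-graph codes read a
    zero as "no edge".  Deterministic tie-break: lowest index wins.
    """
    s = dist.shape[0]
    in_tree = np.zeros(s, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    parent = np.zeros(s, dtype=int)
    edges = []
    for _ in range(s - 1):
        masked = np.where(in_tree, np.inf, best)
        j = int(np.argmin(masked))
        edges.append((parent[j], j))
        in_tree[j] = True
        closer = dist[j] < best
        best = np.where(closer, dist[j], best)
        parent = np.where(closer, j, parent)
    return edges


# ----------------------------------------------------------------------
# index kernels (array in, float out; NaN = undefined)
# ----------------------------------------------------------------------

def _fric(points: np.ndarray, global_volume: float) -> float:
    if global_volume <= 0:
        raise ValueError("global hull volume must be positive")
    if points.shape[0] <= points.shape[1]:
        return np.nan
    try:
        vol, _ = hull_volume(points)
    except QhullError:
        return np.nan
    return vol / global_volume


def _feve(points: np.ndarray, w: np.ndarray, dist: np.ndarray | None = None) -> float:
    s = len(w)
    if s < 3:
        return np.nan
    if dist is None:
        diff = points[:, None, :] - points[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
    edges = _mst_edges(dist)
    ew = np.array([dist[i, j] / (w[i] + w[j]) for i, j in edges])
    tot = ew.sum()
    if tot == 0:
        return np.nan
    pew = ew / tot
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def _fdiv(points: np.ndarray, w: np.ndarray) -> float:
    if points.shape[0] <= points.shape[1] or points.shape[0] < 3:
        return np.nan
    try:
        _, verts = hull_volume(points)
    except QhullError:
        return np.nan
    g = points[verts].mean(axis=0)
    dg = np.sqrt(((points - g) ** 2).sum(axis=1))
    dbar = dg.mean()
    if dbar == 0:
        return np.nan
    dev = dg - dbar
    delta_d = float(w @ dev)
    delta_abs = float(w @ np.abs(dev))
    return (delta_d + dbar) / (delta_abs + dbar)


def _fdis(points: np.ndarray, w: np.ndarray) -> float:
    if len(w) == 0:
        return np.nan
    c = w @ points
    return float(w @ np.sqrt(((points - c) ** 2).sum(axis=1)))


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("weights must have positive sum")
    if not np.isclose(tot, 1.0):
        w = w / tot
    return w


# ----------------------------------------------------------------------
# public single-community API
# ----------------------------------------------------------------------

def fric(space: TraitSpace, present, global_hull_volume: float,
         n_axes: int | None = None) -> float:
    """Standardized functional richness of the taxa in ``present``.

    ``global_hull_volume`` must be the hull volume of the full comparison
    pool on the same axis set, so the result is a proportion of the global
    trait volume.  NaN (with the degeneracy contract of the module) when
    the community has no more taxa than axes or its hull is degenerate.
    """
    return _fric(space.points(present, n_axes), global_hull_volume)


def feve(space: TraitSpace, weights: pd.Series, n_axes: int | None = None) -> float:
    """Functional evenness; NaN for communities of fewer than 3 taxa."""
    w = _check_weights(weights.to_numpy())
    return _feve(space.points(weights.index, n_axes), w)


def fdiv(space: TraitSpace, weights: pd.Series, n_axes: int | None = None) -> float:
    """Functional divergence; NaN for degenerate (hull-less) communities."""
    w = _check_weights(weights.to_numpy())
    return _fdiv(space.points(weights.index, n_axes), w)


def fdis(space: TraitSpace, weights: pd.Series, n_axes: int | None = None) -> float:
    """Functional dispersion; 0 for a single taxon by construction."""
    w = _check_weights(weights.to_numpy())
    return _fdis(space.points(weights.index, n_axes), w)


# ----------------------------------------------------------------------
# whole-community-set driver
# ----------------------------------------------------------------------

def effective_axes(space: TraitSpace, richness, n_axes: int | None = None) -> int:
    """Axis count usable by every community in a comparison set.

    FRic and FDiv need strictly more taxa than axes; the reduction is
    applied to all communities at once (never per community) so that the
    shared global-hull standardization remains meaningful.
    """
    limit = n_axes if n_axes is not None else space.n_axes
    min_s = int(min(richness))
    return max(1, min(limit, space.n_axes, min_s - 1))


@dataclass
class FDResult:
    """Per-community FD indices with degeneracy flags (tidy frame)."""

    table: pd.DataFrame
    n_axes_used: int
    global_hull_volume: float


def fd_all(space: TraitSpace, community: CommunityMatrix, exclude=(),
           n_axes: int | None = None) -> FDResult:
    """All four FD indices for every site of a community matrix.

    ``exclude`` removes taxa before anything else is computed: the global
    hull, the axis reduction and the relative abundances are all taken on
    the reduced pool, because dropping peripheral taxa shrinks the global
    trait space and legitimately changes every community's indices.
    """
    exclude = set(exclude)
    unknown = [t for t in community.taxa if t not in set(space.taxa)]
    if unknown:
        raise ValueError(f"community taxa missing from trait space: {unknown}")
    comm = community.drop_taxa(exclude) if exclude else community
    pool = [t for t in comm.taxa]
    richness = comm.richness()
    occupied = richness[richness > 0]
    if occupied.empty:
        raise ValueError("no occupied sites")
    m = effective_axes(space, occupied, n_axes)
    pool_pts = space.points(pool, m)
    try:
        gvol, _ = hull_volume(pool_pts)
    except QhullError as exc:
        raise ValueError("global taxon pool is degenerate in the reduced "
                         f"{m}-axis space") from exc
    rows = []
    for site in comm.sites:
        cnt = comm.counts.loc[site]
        present = cnt.index[cnt > 0]
        s = len(present)
        flags = []
        if s == 0:
            rows.append({"site": site, "n_taxa": 0, "FRic": np.nan,
                         "FEve": np.nan, "FDiv": np.nan, "FDis": np.nan,
                         "flags": "empty"})
            continue
        pts = space.points(present, m)
        w = cnt[present].to_numpy(dtype=float)
        w = w / w.sum()
        v_fric = _fric(pts, gvol)
        v_feve = _feve(pts, w)
        v_fdiv = _fdiv(pts, w)
        v_fdis = _fdis(pts, w)
        if s <= m:
            flags.append("too_few_taxa_for_hull")
        elif np.isnan(v_fric):
            flags.append("degenerate_hull")
        if s < 3:
            flags.append("fewer_than_3_taxa")
        if m < (n_axes or space.n_axes):
            flags.append(f"axes_reduced_to_{m}")
        rows.append({"site": site, "n_taxa": s, "FRic": v_fric,
                     "FEve": v_feve, "FDiv": v_fdiv, "FDis": v_fdis,
                     "flags": ";".join(flags)})
    table = pd.DataFrame(rows).set_index("site")
    table.insert(0, "location", comm.metadata["location"])
    table["abundance_source"] = comm.abundance_source
    return FDResult(table=table, n_axes_used=m, global_hull_volume=gvol)
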