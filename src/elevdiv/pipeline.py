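"""End-to-end orchestration: indices, null distributions, SES tables.

``ses_analysis`` is the workhorse: given a community matrix, a trait space
and (optionally) a phylogeny, it computes the four functional-diversity
indices and the three phylogenetic-diversity indices for every sampling
point, generates constrained independent-swap null distributions, and
returns a tidy SES table (one row per site x index).  ``run_pipeline``
wraps it for declarative configs: synthetic scenarios or CSV/newick inputs,
optional taxon-exclusion reruns, and incidence-based richness summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import richness as _richness
from .community import CommunityMatrix
from .fd import _fdis, _fdiv, _feve, _fric, effective_axes, hull_volume
from .nulls import NullSpec, null_draws, ses
from .phylo import TreeIndex, read_tree
from .traits import TraitSpace, trait_pca

FD_INDICES = ("FRic", "FEve", "FDiv", "FDis")
PD_INDICES = ("PD", "MPD", "MNTD")


# ----------------------------------------------------------------------
# fast per-site index evaluation
# ----------------------------------------------------------------------

class _IndexEngine:
    """Precomputed geometry so the null loop stays cheap."""

    def __init__(self, space: TraitSpace, taxa, tree=None,
                 n_axes: int | None = None, min_richness: int | None = None):
        self.taxa = list(taxa)
        if min_richness is None:
            min_richness = 2
        self.m = effective_axes(space, [max(min_richness, 2)], n_axes)
        self.points = space.points(self.taxa, self.m)
        vol, _ = hull_volume(self.points)
        if vol <= 0:
            raise ValueError("degenerate global trait space")
        self.global_volume = vol
        diff = self.points[:, None, :] - self.points[None, :, :]
        self.trait_dist = np.sqrt((diff ** 2).sum(-1))
        self.has_tree = tree is not None
        if self.has_tree:
            ti = tree if isinstance(tree, TreeIndex) else TreeIndex(read_tree(tree))
            missing = sorted(set(self.taxa) - set(ti.taxa))
            if missing:
                raise ValueError(f"community taxa missing from tree: {missing}")
            order = [ti.taxa.index(t) for t in self.taxa]
            self.phylo_dist = ti.distances.to_numpy()[np.ix_(order, order)]
            self.edge_masks = ti.edge_masks[:, order]
            self.edge_lengths = ti.edge_lengths
        self.index_names = list(FD_INDICES) + \
            (list(PD_INDICES) if self.has_tree else [])

    def site_indices(self, counts_row: np.ndarray, fd: bool = True) -> dict:
        present = np.nonzero(counts_row > 0)[0]
        out = {name: np.nan for name in self.index_names}
        if present.size == 0:
            return out
        w = counts_row[present].astype(float)
        w = w / w.sum()
        if fd:
            pts = self.points[present]
            out["FRic"] = _fric(pts, self.global_volume)
            out["FEve"] = _feve(pts, w,
                                self.trait_dist[np.ix_(present, present)])
            out["FDiv"] = _fdiv(pts, w)
            out["FDis"] = _fdis(pts, w)
        if self.has_tree:
            mask = np.zeros(self.points.shape[0], dtype=bool)
            mask[present] = True
            touched = (self.edge_masks[:, mask]).any(axis=1)
            out["PD"] = float(self.edge_lengths[touched].sum())
            if present.size >= 2:
                d = self.phylo_dist[np.ix_(present, present)]
                num = float(w @ d @ w)
                den = float(w.sum() ** 2 - (w ** 2).sum())
                out["MPD"] = num / den
                dd = d.copy()
                np.fill_diagonal(dd, np.inf)
                out["MNTD"] = float(w @ dd.min(axis=1) / w.sum())
        return out


# ----------------------------------------------------------------------
# SES analysis
# ----------------------------------------------------------------------

def ses_analysis(community: CommunityMatrix, space: TraitSpace,
                 tree=None, nullspec: NullSpec | None = None,
                 exclude=(), n_axes: int | None = None,
                 min_sites_per_location: int = 3) -> pd.DataFrame:
    """Observed indices, null distributions and SES for every site.

    ``exclude`` drops taxa from the analysis before anything else (global
    hull, weights, nulls).  Locations with fewer sampling points than
    ``min_sites_per_location`` are excluded from the FD randomization (too
    few points for a meaningful within-location randomization); their PD
    rows are still produced.  Returns a tidy frame, one row per
    site x index.
    """
    nullspec = nullspec or NullSpec()
    comm = community.drop_taxa(exclude) if exclude else community
    occupied = comm.richness()
    occupied = occupied[occupied > 0]
    engine = _IndexEngine(space, comm.taxa, tree=tree, n_axes=n_axes,
                          min_richness=int(occupied.min()))
    site_counts = comm.metadata.groupby("location").size()
    fd_ok_locations = set(site_counts[site_counts >= min_sites_per_location].index)
    skipped = sorted(set(site_counts.index) - fd_ok_locations)
    if skipped:
        warnings.warn(f"locations excluded from FD randomization "
                      f"(fewer than {min_sites_per_location} points): {skipped}")
    counts = comm.counts.to_numpy()
    observed = [engine.site_indices(counts[i]) for i in range(counts.shape[0])]
    nulls = np.full((nullspec.n_iterations, counts.shape[0],
                     len(engine.index_names)), np.nan)
    for it, draw in enumerate(null_draws(comm, nullspec)):
        arr = draw.counts.to_numpy()
        for i in range(arr.shape[0]):
            vals = engine.site_indices(arr[i])
            nulls[it, i] = [vals[name] for name in engine.index_names]
    rows = []
    for i, site in enumerate(comm.sites):
        loc = comm.metadata.loc[site, "location"]
        for j, name in enumerate(engine.index_names):
            if name in FD_INDICES and loc not in fd_ok_locations:
                row = {"observed": observed[i][name], "ses": np.nan,
                       "null_mean": np.nan, "null_sd": np.nan,
                       "n_null_valid": 0, "n_null_dropped": 0,
                       "flag": "location_excluded"}
            else:
                row = ses(observed[i][name], nulls[:, i, j])
            rows.append({"site": site, "location": loc, "index": name, **row})
    out = pd.DataFrame(rows)
    out["abundance_source"] = comm.abundance_source
    out["n_axes_used"] = engine.m
    return out


# ----------------------------------------------------------------------
# declarative pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineResult:
    ses_tables: dict            # (source, exclusion name) -> tidy SES frame
    fd_axes_used: int
    trait_space: TraitSpace
    richness: pd.DataFrame | None = None
    intermediates: dict = field(default_factory=dict)


def run_pipeline(config: dict | str | Path) -> PipelineResult:
    """Run the full analysis from a declarative config.

    The config is a mapping (or a path to a YAML file) with either a
    ``synthetic`` section (a :class:`~elevdiv.synthetic.ScenarioConfig`
    field mapping) or an ``inputs`` section with ``community``,
    ``metadata``, ``traits`` and ``tree`` paths; plus optional ``null``
    settings (iterations, constraint, seed), ``n_axes``, ``exclude``
    (mapping of rerun name -> taxon list) and ``min_sites_per_location``.
    Identical configs give byte-identical outputs.
    """
    if not isinstance(config, dict):
        import yaml
        config = yaml.safe_load(Path(config).read_text())
    exclude_sets = {"all": []}
    exclude_sets.update(config.get("exclude", {}))
    null_cfg = config.get("null", {})
    nullspec = NullSpec(
        n_iterations=int(null_cfg.get("iterations", 999)),
        method=null_cfg.get("method", "independent_swap"),
        constraint=null_cfg.get("constraint", "location"),
        swap_attempts=null_cfg.get("swap_attempts"),
        seed=int(null_cfg.get("seed", config.get("seed", 0))),
    )
    n_axes = int(config.get("n_axes", 4))
    floor = int(config.get("min_sites_per_location", 3))

    intermediates = {}
    if "synthetic" in config:
        from .synthetic import ScenarioConfig, generate_metacommunity
        syn = dict(config["synthetic"])
        syn.setdefault("seed", int(config.get("seed", 0)))
        if "richness_per_location" in syn:
            syn["richness_per_location"] = tuple(syn["richness_per_location"])
        meta = generate_metacommunity(ScenarioConfig(**syn))
        community, traits, tree = meta.community, meta.traits, meta.tree
        intermediates["truth"] = meta.truth
    else:
        paths = config["inputs"]
        community = CommunityMatrix.from_csv(
            paths["community"], paths.get("metadata"),
            abundance_source=config.get("abundance_source", "acoustic"))
        traits = pd.read_csv(paths["traits"], index_col=0)
        tree = read_tree(paths["tree"]) if "tree" in paths else None

    space = trait_pca(traits, n_axes=min(n_axes, len(traits) - 1,
                                         traits.shape[1]))
    tree_index = TreeIndex(tree) if tree is not None else None
    ses_tables = {}
    axes_used = None
    for name, taxa in exclude_sets.items():
        table = ses_analysis(community, space, tree=tree_index,
                             nullspec=nullspec, exclude=taxa,
                             n_axes=n_axes, min_sites_per_location=floor)
        table["exclusion"] = name
        ses_tables[(community.abundance_source, name)] = table
        if name == "all":
            axes_used = int(table["n_axes_used"].iloc[0])

    rich = None
    if "synthetic" in config:
        from .synthetic import ScenarioConfig, generate_detection_stream
        stream = generate_detection_stream(meta, ScenarioConfig(**syn))
        intermediates["events"] = stream
        if len(stream):
            rich_rows = []
            for loc, grp in stream.groupby("location"):
                inc = _richness.build_incidence(events=grp)
                t50 = int(config.get("target_units", 2 * inc.T))
                rich_rows.append({
                    "location": loc, "T": inc.T, "s_obs": inc.s_obs,
                    "jack1": _richness.jackknife1(inc) if inc.T >= 2 else np.nan,
                    "q0_at_target": _richness.rarefy_extrapolate(inc, 0, t50),
                    "q2_at_target": _richness.rarefy_extrapolate(inc, 2, t50),
                })
            rich = pd.DataFrame(rich_rows)
    return PipelineResult(ses_tables=ses_tables, fd_axes_used=axes_used or 0,
                          trait_space=space, richness=rich,
                          intermediates=intermediates)


def location_mean_ses(table: pd.DataFrame) -> pd.DataFrame:
    """Mean SES per location x index (sampling points averaged)."""
    return (table.dropna(subset=["ses"])
            .groupby(["location", "index"])["ses"].mean().unstack())
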