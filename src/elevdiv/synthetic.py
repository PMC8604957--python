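"""Synthetic metacommunities with known assembly structure.

The generator emulates a montane acoustic bat survey: a regional species
pool whose trait matrix contains one congeneric clade with peripheral trait
values (long constant-frequency calls, high tip-shape index, widely spread
peak frequencies — the rhinolophid pattern), an ultrametric pure-birth
phylogeny on which that clade is monophyletic, a richness gradient over a
small number of elevational locations, and Poisson detection counts per
occupied species and site.

Three assembly scenarios:

* ``neutral`` — every site draws its stated richness uniformly from the
  pool; abundances are trait-independent.
* ``filtering`` — at the harshest (highest) location the inclusion
  probability of a species decays as ``exp(-filter_strength * excess)``,
  where ``excess`` is how far its standardized trait distance from the
  community optimum (the centroid of the main trait cluster) exceeds the
  main cluster's own envelope.  Species within the envelope pass the filter
  unpenalized -- an environmental filter admits every phenotype within
  tolerance rather than ranking them -- so the filtered community is a
  plain subset of the main cluster and the signature disappears once the
  extreme clade is excluded from analysis.  All other locations assemble
  neutrally, so the occurrence frequencies preserved by the null model are
  not themselves shaped by the filter.  Expected abundance is tilted by the
  same excess at half strength.  Strength 0 reproduces the neutral
  scenario draw for draw.
* ``packing`` — the lowest location assembles sequentially, preferring
  species close in trait space to those already present, crowding the
  occupied region of niche space instead of expanding it.

Every output is a plain downstream object (community matrix, trait
DataFrame, dendropy tree, tidy event table) and is byte-deterministic in
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .acoustics import EVENT_COLUMNS, FEATURE_COLUMNS, LABEL_COLUMN
from .community import CommunityMatrix
from .traits import TRAIT_COLUMNS

SCENARIOS = ("neutral", "filtering", "packing")

# abundance responds to raw trait-optimum distance at a small fraction of
# the occupancy filter's rate: common species at a filtered site have the
# most central trait values, without re-ranking which species occur at all
_ABUNDANCE_TILT = 0.05

# three 5-min windows per recorded hour (minutes 0-5, 20-25, 40-45),
# indexed as 5-min bins from the start of the night: hour*12 + {0, 4, 8}
WINDOW_OFFSETS = (0, 4, 8)
BINS_PER_HOUR = 12


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design knobs for one synthetic metacommunity.

    Defaults mirror the four-location, two-night-per-point montane design:
    a pool of 16 species of which 4 form the extreme clade, a declining
    richness gradient, and a mean of 6 detections per occupied species per
    night.
    """

    scenario: str = "neutral"
    n_locations: int = 4
    richness_per_location: tuple = (13, 11, 9, 8)
    pool_size: int = 16
    filter_strength: float = 0.0
    extreme_clade_size: int = 4
    detection_rate: float = 6.0
    extreme_abundance_factor: float = 4.0
    nights_per_site: int = 2
    sites_per_location: int = 5
    hours_per_night: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if len(self.richness_per_location) != self.n_locations:
            raise ValueError("richness_per_location length != n_locations")
        if any(r > self.pool_size for r in self.richness_per_location):
            raise ValueError("location richness exceeds pool size")
        if any(r < 1 for r in self.richness_per_location):
            raise ValueError("location richness must be >= 1")
        if self.extreme_clade_size >= self.pool_size:
            raise ValueError("extreme clade must be smaller than the pool")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be non-negative")
        if min(self.nights_per_site, self.sites_per_location,
               self.hours_per_night) < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticMetacommunity:
    community: CommunityMatrix
    traits: pd.DataFrame
    tree: dendropy.Tree
    truth: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# trait pool
# ----------------------------------------------------------------------

def _pool_labels(config: ScenarioConfig):
    n_main = config.pool_size - config.extreme_clade_size
    main = [f"t{i + 1:02d}" for i in range(n_main)]
    extreme = [f"x{i + 1:02d}" for i in range(config.extreme_clade_size)]
    return main, extreme


def _generate_traits(main, extreme, rng) -> pd.DataFrame:
    """Field-realistic trait matrix: a main cluster plus a peripheral clade."""
    rows = {}
    for lab in main:
        fmaxe = rng.normal(48, 11)
        rows[lab] = {
            "FA": rng.normal(38, 4), "AR": rng.normal(6.8, 0.5),
            "WL": rng.normal(7.5, 1.8), "I": rng.normal(1.1, 0.25),
            "fmaxe": fmaxe, "pfc.min": fmaxe - abs(rng.normal(6, 2)),
            "pfc.max": fmaxe + abs(rng.normal(28, 12)),
            "Duration": rng.normal(5.2, 1.5),
        }
    # extreme congeners: narrowband constant-frequency callers with very
    # long calls, high tip-shape index and widely spread peak frequencies
    spread = np.linspace(31, 95, max(len(extreme), 2))[:len(extreme)]
    for lab, f0 in zip(extreme, spread):
        fmaxe = f0 + rng.normal(0, 2)
        rows[lab] = {
            "FA": rng.normal(52, 9), "AR": rng.normal(6.3, 0.3),
            "WL": rng.normal(9.2, 1.8), "I": rng.normal(2.25, 0.25),
            "fmaxe": fmaxe, "pfc.min": fmaxe * 0.88,
            "pfc.max": fmaxe * 1.01, "Duration": rng.normal(36, 8),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[TRAIT_COLUMNS]
    return df.clip(lower=0.3)


# ----------------------------------------------------------------------
# phylogeny
# ----------------------------------------------------------------------

class _Node:
    __slots__ = ("time", "children", "label")

    def __init__(self, time):
        self.time = time
        self.children = []
        self.label = None


def _yule_subtree(labels, depth, rng, compress: float = 1.0) -> str:
    """Newick subtree (no stem length) over >= 2 labels; crown depth ``depth``.

    ``compress`` < 1 pulls the internal split times toward the crown root
    (a basal radiation) while leaving the tips at full depth.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 labels for a crown")
    t = 0.0
    times = []
    for n_active in range(2, len(labels)):
        t += rng.exponential(1.0 / n_active)
        times.append(t)
    t_end = t + rng.exponential(1.0 / len(labels))
    scale = depth / t_end
    root = _Node(0.0)
    a, b = _Node(depth), _Node(depth)
    root.children = [a, b]
    active = [a, b]
    for tm in times:
        node = active.pop(int(rng.integers(len(active))))
        node.time = tm * scale * compress
        a, b = _Node(depth), _Node(depth)
        node.children = [a, b]
        active.extend([a, b])
    rng.shuffle(labels)
    for node, lab in zip(active, labels):
        node.label = lab

    def render(node, parent_time):
        length = node.time - parent_time
        if node.label is not None:
            return f"{node.label}:{length:.8f}"
        inner = ",".join(render(c, node.time) for c in node.children)
        return f"({inner}):{length:.8f}"

    return "(" + ",".join(render(c, 0.0) for c in root.children) + ")"


def generate_tree(main, extreme, rng, main_clade_size: int = 2,
                  crown_fraction: float = 0.9,
                  crown_compression: float = 0.15) -> dendropy.Tree:
    """Unit-depth pure-birth tree with the extreme taxa monophyletic.

    Main-pool species form small clades (congeneric pairs by default)
    while the extreme taxa form a single monophyletic clade -- a pool of
    many genera plus one within-genus radiation.  All clades diverge near
    the root (the backbone spans only the basal 10% of tree depth) and
    clade crowns are basally biased (``crown_compression`` pulls the
    within-clade splits toward the clade root), so within- and
    between-clade tip distances are comparable and each species' marginal
    branch-length contribution is similarly deep.  The tree then carries
    essentially no structure beyond the extreme clade's monophyly, and
    losing that clade perturbs phylogenetic diversity no more than losing
    as many random species.
    """
    import re

    crown = crown_fraction
    clades = [sorted(extreme)] if extreme else []
    main = list(main)
    n_chunks = max(1, round(len(main) / main_clade_size))
    for chunk in np.array_split(np.array(main, dtype=object), n_chunks):
        if len(chunk):
            clades.append(list(chunk))
    if len(clades) == 1:
        newick = _yule_subtree(clades[0], 1.0, rng)
    else:
        placeholders = [f"PH{i}" for i in range(len(clades))]
        newick = _yule_subtree(placeholders, 1.0 - crown, rng)
        for ph, members in zip(placeholders, clades):
            match = re.search(rf"{ph}:([0-9.]+)", newick)
            stem = float(match.group(1))
            if len(members) == 1:
                graft = f"{members[0]}:{stem + crown:.8f}"
            else:
                sub = _yule_subtree(members, crown, rng,
                                    compress=crown_compression)
                graft = f"{sub}:{stem:.8f}"
            newick = newick.replace(match.group(0), graft)
    tree = dendropy.Tree.get(data=newick + ";", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


# ----------------------------------------------------------------------
# occupancy and abundance
# ----------------------------------------------------------------------

def _weighted_sample(labels, log_w, size, rng):
    """Weighted sampling without replacement via Gumbel keys."""
    keys = log_w + rng.gumbel(size=len(labels))
    order = np.argsort(-keys)
    return [labels[i] for i in order[:size]]


def _z_scores(traits: pd.DataFrame) -> pd.DataFrame:
    return (traits - traits.mean()) / traits.std(ddof=1)


def generate_metacommunity(config: ScenarioConfig,
                           traits: pd.DataFrame | None = None,
                           extreme_taxa=None,
                           tree: dendropy.Tree | None = None
                           ) -> SyntheticMetacommunity:
    """Simulate one metacommunity under the configured assembly scenario.

    An externally supplied trait matrix (e.g. the packaged field trait
    table) replaces the simulated pool; occupancy and abundance are then
    the only simulated components.  ``extreme_taxa`` names the peripheral
    clade in that case (default: no forced clade).
    """
    rng = np.random.default_rng([config.seed, 0])
    if traits is None:
        main, extreme = _pool_labels(config)
        traits = _generate_traits(main, extreme, rng)
    else:
        if len(traits) != config.pool_size:
            raise ValueError("pool_size must equal the supplied trait matrix "
                             f"rows ({len(traits)})")
        extreme = sorted(extreme_taxa) if extreme_taxa else []
        unknown = set(extreme) - set(traits.index)
        if unknown:
            raise ValueError(f"extreme taxa not in trait matrix: {sorted(unknown)}")
        main = [t for t in traits.index if t not in set(extreme)]
    pool = list(traits.index)
    if tree is None:
        tree = generate_tree(main, extreme, rng)

    z = _z_scores(traits)
    main_centroid = z.loc[main].mean()
    dist = np.sqrt(((z - main_centroid) ** 2).sum(axis=1))  # per-species
    # the filter penalizes only the excess beyond the main cluster's radius
    envelope = float(dist.loc[main].max())
    excess = (dist - envelope).clip(lower=0.0)

    strengths = np.zeros(config.n_locations)
    strengths[-1] = config.filter_strength  # filter acts at the harshest location
    elevations = np.linspace(1600, 3500, config.n_locations).round().astype(int)
    habitats = ("forest", "edge", "open")

    counts, meta_rows = {}, []
    occupancy, packed = {}, {}
    d = excess.to_numpy()      # occupancy filter: envelope-excess distance
    d_raw = dist.to_numpy()    # abundance tilt: raw distance from optimum
    for j in range(config.n_locations):
        s_j = strengths[j] if config.scenario == "filtering" else 0.0
        richness = config.richness_per_location[j]
        for k in range(config.sites_per_location):
            site = f"L{j}S{k}"
            if config.scenario == "packing" and j == 0:
                chosen = _pack_site(z, pool, richness, config.filter_strength,
                                    rng)
                packed[site] = chosen[1:]
            else:
                chosen = _weighted_sample(pool, -s_j * d, richness, rng)
            # abundance: Poisson with a suitability tilt so filtered
            # communities are numerically as well as compositionally
            # central; neutral tilt is exactly 1.  Extreme-clade species
            # are intrinsically more detectable where they occur (the
            # loud, frequently-detected CF-bat pattern; they were among
            # the dominant sonotypes at low elevations in the field).
            idx = [pool.index(t) for t in chosen]
            suit = np.exp(-_ABUNDANCE_TILT * s_j * d_raw[idx])
            suit = suit / suit.mean()
            boost = np.array([config.extreme_abundance_factor
                              if t in set(extreme) else 1.0 for t in chosen])
            lam = config.detection_rate * config.nights_per_site * suit * boost
            c = rng.poisson(lam)
            counts[site] = dict(zip(chosen, c.astype(int)))
            occupancy[site] = [t for t, n in counts[site].items() if n > 0]
            meta_rows.append({"site": site, "location": f"loc{j}",
                              "elevation": int(elevations[j]),
                              "habitat": habitats[k % len(habitats)],
                              "year": 2018})
    counts_df = (pd.DataFrame.from_dict(counts, orient="index")
                 .reindex(columns=pool).fillna(0).astype(int))
    meta = pd.DataFrame(meta_rows).set_index("site")
    counts_df = counts_df.loc[meta.index]
    counts_df.index.name = "site"
    community = CommunityMatrix(counts=counts_df, metadata=meta)
    truth = {
        "scenario": config.scenario,
        "optimum": main_centroid,
        "trait_distance": dist,
        "envelope": envelope,
        "filter_excess": excess,
        "strength_by_location": {f"loc{j}": float(strengths[j])
                                 for j in range(config.n_locations)},
        "extreme_taxa": list(extreme),
        "occupancy": occupancy,
        "packed": packed,
    }
    return SyntheticMetacommunity(community=community, traits=traits,
                                  tree=tree, truth=truth)


def _pack_site(z: pd.DataFrame, pool, richness, strength, rng):
    """Sequential trait-proximity assembly (niche packing)."""
    arr = z.loc[pool].to_numpy()
    first = int(rng.integers(len(pool)))
    chosen_idx = [first]
    remaining = [i for i in range(len(pool)) if i != first]
    while len(chosen_idx) < richness:
        occupied = arr[chosen_idx]
        rem = np.array(remaining)
        nn = np.sqrt(((arr[rem][:, None, :] - occupied[None, :, :]) ** 2
                      ).sum(-1)).min(axis=1)
        logw = -strength * nn
        keys = logw + rng.gumbel(size=len(rem))
        pick = rem[int(np.argmax(keys))]
        chosen_idx.append(int(pick))
        remaining.remove(int(pick))
    return [pool[i] for i in chosen_idx]


# ----------------------------------------------------------------------
# call library and detection stream
# ----------------------------------------------------------------------

def generate_call_library(n_species: int, pulses_per_species: int,
                          separation: float, seed: int = 0) -> pd.DataFrame:
    """Gaussian call library with class means ``separation`` SDs apart.

    Nine acoustic parameters per pulse; per-feature SD is 10 units around a
    base of 100, and class means are placed on a mutually equidistant
    simplex so every pair of species is the same ``separation`` (in SD
    units) apart.  ``separation=0`` gives identical class distributions.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if pulses_per_species < 3:
        raise ValueError("need at least 3 pulses per species")
    if n_species > len(FEATURE_COLUMNS):
        raise ValueError(f"at most {len(FEATURE_COLUMNS)} species supported")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng([seed, 1])
    sd = 10.0
    base = 100.0
    # class means sit on a simplex of fixed orthonormal directions, so the
    # separation is spread over all features rather than concentrated in
    # one (a single informative feature would be swamped by the pooled
    # standardization downstream classifiers apply)
    k = len(FEATURE_COLUMNS)
    directions, _ = np.linalg.qr(
        np.random.default_rng(197).standard_normal((k, k)))
    rows = []
    for s in range(n_species):
        # ||u_i - u_j|| = sqrt(2) for orthonormal rows
        mu = separation * sd / np.sqrt(2) * directions[s]
        pulses = base + mu + sd * rng.standard_normal(
            (pulses_per_species, len(FEATURE_COLUMNS)))
        for p in pulses:
            rows.append({LABEL_COLUMN: f"sp{s + 1:02d}",
                         **dict(zip(FEATURE_COLUMNS, p))})
    return pd.DataFrame(rows)[[LABEL_COLUMN, *FEATURE_COLUMNS]]


def generate_detection_stream(meta: SyntheticMetacommunity,
                              config: ScenarioConfig) -> pd.DataFrame:
    """Scatter each site's counts over the sampled 5-min intervals.

    Each of a species' simulated detections lands in a random night, hour
    and one of the three 5-min windows sampled per hour; the activity index
    recovered from the stream therefore saturates at three occupied
    intervals per recorded hour and grows stochastically with abundance.
    """
    rng = np.random.default_rng([config.seed, 2])
    comm = meta.community
    rows = []
    for site in comm.sites:
        md = comm.metadata.loc[site]
        cnt = comm.counts.loc[site]
        for taxon in comm.taxa:
            c = int(cnt[taxon])
            if c == 0:
                continue
            nights = rng.integers(config.nights_per_site, size=c)
            hours = rng.integers(config.hours_per_night, size=c)
            windows = rng.integers(len(WINDOW_OFFSETS), size=c)
            intervals = hours * BINS_PER_HOUR + np.take(WINDOW_OFFSETS, windows)
            for n, iv in zip(nights, intervals):
                rows.append({"sonotype": taxon, "site": site,
                             "location": md["location"],
                             "habitat": md["habitat"], "year": md["year"],
                             "night": int(n), "interval": int(iv)})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
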