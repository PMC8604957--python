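"""Constrained independent-swap null models and standardized effect sizes.

The independent-swap algorithm randomizes the presence structure of a
community matrix while preserving, exactly, the species richness of every
site and the number of sites occupied by every species.  It repeatedly
locates 2x2 submatrices of the presence matrix with a checkerboard pattern
([[1,0],[0,1]] or [[0,1],[1,0]]) and exchanges them; abundance values
travel with their presences, so a species' count simply moves to its new
site.  Randomization can be constrained to groups of sites (by default the
elevational location), in which case the marginals are preserved within
every group independently and no occurrence ever crosses a group boundary.

The standardized effect size of an index is
``SES = (observed - mean(null)) / sd(null)``; following the significance
convention used with these community nulls, ``|SES| > 1`` is flagged, and
the conventional ``|SES| > 1.96`` cut is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityMatrix

__all__ = ["NullSpec", "independent_swap", "shuffle_abundances", "ses",
           "null_draws"]


@dataclass(frozen=True)
class NullSpec:
    """Randomization settings.

    ``swap_attempts`` is the number of *successful* swaps per chain
    (default 10x the presence-matrix fill), and an equal burn-in is run
    first; every null draw is an independent chain started from the
    observed matrix and seeded from the master seed.
    ``constraint=None`` randomizes the whole matrix as one group.
    """

    n_iterations: int = 999
    method: str = "independent_swap"
    constraint: str | None = "location"
    swap_attempts: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.method not in ("independent_swap", "abundance_shuffle"):
            raise ValueError(f"unknown method {self.method!r}")


def _swap_chain(counts: np.ndarray, n_swaps: int, rng: np.random.Generator,
                batch: int = 256) -> int:
    """Run ``n_swaps`` successful checkerboard swaps in place; counts move
    with presences.  Returns the number of swaps achieved (may fall short
    when the matrix admits no checkerboard)."""
    r, c = counts.shape
    if r < 2 or c < 2:
        return 0
    done = 0
    attempts = 0
    max_attempts = max(200 * n_swaps, 20_000)
    while done < n_swaps and attempts < max_attempts:
        r1 = rng.integers(0, r, batch)
        r2 = rng.integers(0, r, batch)
        c1 = rng.integers(0, c, batch)
        c2 = rng.integers(0, c, batch)
        attempts += batch
        a = counts[r1, c1] > 0
        b = counts[r1, c2] > 0
        d = counts[r2, c1] > 0
        e = counts[r2, c2] > 0
        ok = (r1 != r2) & (c1 != c2) & (a == e) & (b == d) & (a != b)
        for i in np.nonzero(ok)[0]:
            i1, i2, j1, j2 = r1[i], r2[i], c1[i], c2[i]
            # re-verify against the current state (earlier swaps in this
            # batch may have invalidated the candidate)
            p11 = counts[i1, j1] > 0
            p22 = counts[i2, j2] > 0
            p12 = counts[i1, j2] > 0
            p21 = counts[i2, j1] > 0
            if p11 == p22 and p12 == p21 and p11 != p12:
                counts[i1, j1], counts[i2, j1] = counts[i2, j1], counts[i1, j1]
                counts[i1, j2], counts[i2, j2] = counts[i2, j2], counts[i1, j2]
                done += 1
                if done == n_swaps:
                    break
    return done


def independent_swap(community: CommunityMatrix, spec: NullSpec,
                     rng: np.random.Generator | None = None
                     ) -> CommunityMatrix:
    """One randomized community matrix under the constrained swap null."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    counts = community.counts.to_numpy().copy()
    for rows in _constraint_groups(community, spec):
        sub = counts[rows]
        fill = int((sub > 0).sum())
        target = spec.swap_attempts if spec.swap_attempts is not None \
            else 10 * fill
        achieved = _swap_chain(sub, 2 * target, rng)  # burn-in + run
        if achieved == 0 and target > 0:
            warnings.warn("no checkerboard submatrix found in a constraint "
                          "group; group returned unchanged")
        counts[rows] = sub
    return CommunityMatrix(counts=pd.DataFrame(counts,
                                               index=community.counts.index,
                                               columns=community.counts.columns),
                           metadata=community.metadata.copy(),
                           abundance_source=community.abundance_source)


def shuffle_abundances(community: CommunityMatrix, spec: NullSpec,
                       rng: np.random.Generator | None = None
                       ) -> CommunityMatrix:
    """Alternative null: permute each species' counts across sites in-group.

    This reading of "abundances randomized among sampling points within
    each elevation" shuffles whole count columns within constraint groups;
    it preserves each species' within-group count multiset but not site
    richness.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    counts = community.counts.to_numpy().copy()
    for rows in _constraint_groups(community, spec):
        sub = counts[rows]
        for j in range(sub.shape[1]):
            sub[:, j] = sub[rng.permutation(sub.shape[0]), j]
        counts[rows] = sub
    return CommunityMatrix(counts=pd.DataFrame(counts,
                                               index=community.counts.index,
                                               columns=community.counts.columns),
                           metadata=community.metadata.copy(),
                           abundance_source=community.abundance_source)


def _constraint_groups(community: CommunityMatrix, spec: NullSpec):
    if spec.constraint is None:
        yield np.arange(len(community.sites))
        return
    groups = community.metadata[spec.constraint]
    for _, idx in groups.groupby(groups).groups.items():
        yield community.metadata.index.get_indexer(idx)


def null_draws(community: CommunityMatrix, spec: NullSpec):
    """Yield ``spec.n_iterations`` independent randomized matrices.

    Each draw runs its own swap chain from the observed matrix, seeded
    from the master seed, so draws are exchangeable and reproducible.
    """
    draw = independent_swap if spec.method == "independent_swap" \
        else shuffle_abundances
    master = np.random.SeedSequence(spec.seed)
    for child in master.spawn(spec.n_iterations):
        yield draw(community, spec, rng=np.random.default_rng(child))


def ses(observed: float, null_values) -> dict:
    """Standardized effect size of one observed index against its null.

    Degenerate null draws (NaN) are dropped and counted; a zero-variance
    or under-sampled null leaves the SES undefined (NaN) with a flag.
    """
    nulls = np.asarray(null_values, dtype=float)
    valid = nulls[np.isfinite(nulls)]
    n_valid = int(valid.size)
    out = {"observed": observed, "n_null_valid": n_valid,
           "n_null_dropped": int(nulls.size - n_valid)}
    if not np.isfinite(observed) or n_valid < 2:
        out.update({"null_mean": np.nan, "null_sd": np.nan, "ses": np.nan,
                    "flag": "undefined"})
        return out
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1))
    out["null_mean"] = mean
    out["null_sd"] = sd
    if sd == 0:
        out.update({"ses": np.nan, "flag": "zero_variance_null"})
        return out
    z = (observed - mean) / sd
    out["ses"] = float(z)
    out["significant"] = bool(abs(z) > 1)
    out["significant_195"] = bool(abs(z) > 1.96)
    out["flag"] = ""
    return out
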