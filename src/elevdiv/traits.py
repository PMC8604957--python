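"""Wing morphometrics and trait-space construction.

The functional trait matrix mixes morphological traits (forearm length in
mm, aspect ratio, wing loading in N/m^2, wing-tip shape index) with
echolocation-call traits (peak frequency and the extremes of the peak
frequency contour in kHz, call duration in ms).  Because the units are
incommensurable, traits are z-standardized before a principal component
analysis; functional-diversity indices are then computed on the leading PC
scores, where Euclidean distance is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

TRAIT_COLUMNS = ["FA", "AR", "WL", "I", "fmaxe", "pfc.min", "pfc.max", "Duration"]


# ----------------------------------------------------------------------
# Wing morphometrics (Norberg & Rayner conventions)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class WingMeasurement:
    """Field measurements of one outstretched wing (SI units).

    ``wing_area`` is the total lifting area S (both wings and the body
    strip); hand- and arm-wing areas are for one side each but only their
    ratios enter the tip-shape index, so any consistent convention works.
    """

    mass: float            # kg
    wingspan: float        # m
    wing_area: float       # m^2
    handwing_area: float   # m^2
    armwing_area: float    # m^2
    handwing_length: float  # m
    armwing_length: float   # m

    def __post_init__(self) -> None:
        for name in ("mass", "wingspan", "wing_area", "handwing_area",
                     "armwing_area", "handwing_length", "armwing_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WingMetrics:
    aspect_ratio: float   # B^2 / S, dimensionless
    wing_loading: float   # m g / S, N/m^2
    tip_shape_index: float  # I = T_s / (T_l - T_s)


def wing_metrics(m: WingMeasurement, g: float = 9.81) -> WingMetrics:
    """Aspect ratio, wing loading and tip-shape index from wing measurements.

    AR = B^2/S; WL = Mg/S; the tip-shape index uses the tip area ratio
    T_s = S_hw/S_aw and tip length ratio T_l = l_hw/l_aw, with
    I = T_s/(T_l - T_s).  Values of I at or above 1 indicate broad,
    triangular wing tips; values below 1 indicate acute tips.  When
    T_l == T_s the index is undefined and +inf is returned with a warning.
    """
    ar = m.wingspan ** 2 / m.wing_area
    wl = m.mass * g / m.wing_area
    t_s = m.handwing_area / m.armwing_area
    t_l = m.handwing_length / m.armwing_length
    if t_l == t_s:
        warnings.warn("tip length ratio equals tip area ratio; "
                      "tip-shape index undefined (+inf)")
        return WingMetrics(ar, wl, float("inf"))
    return WingMetrics(ar, wl, t_s / (t_l - t_s))


# ----------------------------------------------------------------------
# Trait matrix handling
# ----------------------------------------------------------------------

def load_trait_matrix(path) -> pd.DataFrame:
    """Read a taxa x traits CSV (first column = taxon label)."""
    df = pd.read_csv(path, index_col=0)
    validate_trait_matrix(df)
    return df


def bundled_trait_matrix() -> pd.DataFrame:
    """The packaged 13-sonotype x 8-trait Himalayan bat trait matrix."""
    with resources.files("elevdiv.fixtures").joinpath("table1_traits.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def validate_trait_matrix(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        raise ValueError("duplicate taxon labels in trait matrix")
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("trait matrix contains non-finite values")
    if {"pfc.min", "pfc.max"} <= set(df.columns):
        if (df["pfc.max"] < df["pfc.min"]).any():
            raise ValueError("pfc.max must be >= pfc.min")


def species_means(df: pd.DataFrame, sonotype_map: dict) -> pd.DataFrame:
    """Average species-level trait rows within each sonotype.

    ``sonotype_map`` maps species label -> sonotype label (many-to-one);
    every row of ``df`` must be mapped.
    """
    missing = [s for s in df.index if s not in sonotype_map]
    if missing:
        raise ValueError(f"species not in sonotype map: {missing}")
    groups = pd.Series({s: sonotype_map[s] for s in df.index}, name="sonotype")
    return df.groupby(groups).mean()


# ----------------------------------------------------------------------
# PCA trait space
# ----------------------------------------------------------------------

@dataclass
class TraitSpace:
    """Taxa x axes PC-score matrix with explained-variance fractions.

    Scores are ordered by decreasing eigenvalue; axes are orthogonal.  The
    sign of each axis is fixed so that its largest-magnitude trait loading
    is positive, which makes scores reproducible across linear-algebra
    backends.
    """

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame

    @property
    def taxa(self) -> list:
        return list(self.scores.index)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def points(self, taxa=None, n_axes=None) -> np.ndarray:
        sub = self.scores if taxa is None else self.scores.loc[list(taxa)]
        arr = sub.to_numpy(dtype=float)
        return arr if n_axes is None else arr[:, :n_axes]


def standardize(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column z-scores; raises naming any constant (zero-variance) trait."""
    sd = df.std(ddof=ddof)
    bad = sd.index[sd == 0].tolist()
    if bad:
        raise ValueError(f"constant trait column(s): {bad}")
    return (df - df.mean()) / sd


def trait_pca(traits: pd.DataFrame, n_axes: int = 4,
              standardize_traits: bool = True) -> TraitSpace:
    """Project the trait matrix onto its leading principal components.

    Traits are column-standardized by default (the matrix mixes mm, kHz and
    ms scales, so an unscaled PCA would be dominated by the frequency
    traits).  Requesting more axes than the matrix rank returns trailing
    zero-score axes with a warning rather than failing, so that a fixed
    dimensionality can be requested for degenerate inputs.
    """
    n, p = traits.shape
    if n_axes > min(n - 1, p):
        raise ValueError(f"n_axes={n_axes} exceeds min(n_taxa - 1, n_traits) "
                         f"= {min(n - 1, p)}")
    validate_trait_matrix(traits)
    x = standardize(traits) if standardize_traits else traits - traits.mean()
    xa = x.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(xa, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_axes > rank:
        warnings.warn(f"trait matrix rank {rank} < requested {n_axes} axes; "
                      "trailing axes are zero")
    # deterministic sign: largest-magnitude loading of each axis positive
    for j in range(len(s)):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    scores[:, rank:] = 0.0
    ev = s ** 2
    ratio = ev / ev.sum() if ev.sum() > 0 else ev
    cols = [f"PC{j + 1}" for j in range(n_axes)]
    return TraitSpace(
        scores=pd.DataFrame(scores[:, :n_axes], index=traits.index, columns=cols),
        explained_variance_ratio=ratio[:n_axes],
        loadings=pd.DataFrame(vt[:n_axes].T, index=traits.columns, columns=cols),
    )
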