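"""Incidence-based richness estimation and detectability summaries.

The sampling unit is one night at one sampling point, with acoustic
detections and mistnet captures pooled.  From the taxa x units binary
matrix this module computes the first-order jackknife richness estimate,
rarefaction/extrapolation of Hill numbers of order 0 (species richness)
and 2 (Simpson diversity, reported as the Hill number ^2D), and a
model-ready detection-history table for external mixed-model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "IncidenceData", "build_incidence", "jackknife1", "rarefy_extrapolate",
    "rarefaction_curve", "detectability_summary",
]


@dataclass
class IncidenceData:
    """Taxa x sampling-units binary incidence matrix."""

    matrix: pd.DataFrame  # taxa rows, unit columns, 0/1

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")

    @property
    def T(self) -> int:
        """Number of sampling units."""
        return self.matrix.shape[1]

    @property
    def Y(self) -> pd.Series:
        """Incidence frequency of each taxon (units in which it occurs)."""
        return self.matrix.sum(axis=1)

    @property
    def s_obs(self) -> int:
        return int((self.Y > 0).sum())

    @property
    def U(self) -> int:
        """Total incidence count."""
        return int(self.Y.sum())

    def Q(self, k: int) -> int:
        """Number of taxa occurring in exactly k units."""
        return int((self.Y == k).sum())


def build_incidence(events: pd.DataFrame | None = None,
                    captures: pd.DataFrame | None = None,
                    taxon_col: str = "sonotype") -> IncidenceData:
    """Pool detection events and captures into one incidence matrix.

    ``events`` needs columns (taxon, site, night); ``captures`` needs
    (taxon — under ``taxon_col`` or ``species`` —, site) and, if available,
    ``night``.  Capture rows without a night are treated as one extra
    netting unit per site.  A sampling unit is a (site, night) pair.
    """
    frames = []
    if events is not None and len(events):
        e = events.rename(columns={"species": taxon_col})
        frames.append(e[[taxon_col, "site", "night"]])
    if captures is not None and len(captures):
        c = captures.rename(columns={"species": taxon_col}).copy()
        if "night" not in c.columns:
            c["night"] = "net"
        frames.append(c[[taxon_col, "site", "night"]])
    if not frames:
        raise ValueError("no events or captures supplied")
    pooled = pd.concat(frames, ignore_index=True)
    pooled["unit"] = pooled["site"].astype(str) + "|" + pooled["night"].astype(str)
    mat = (pd.crosstab(pooled[taxon_col], pooled["unit"]) > 0).astype(int)
    return IncidenceData(matrix=mat)


# ----------------------------------------------------------------------
# estimators
# ----------------------------------------------------------------------

def jackknife1(inc: IncidenceData) -> float:
    """First-order jackknife richness estimate S_obs + Q1 (T-1)/T."""
    if inc.T < 2:
        raise ValueError("jackknife1 needs at least 2 sampling units")
    return inc.s_obs + inc.Q(1) * (inc.T - 1) / inc.T


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _q0_hat(inc: IncidenceData) -> float:
    """Chao2-style estimate of the number of undetected taxa."""
    t, q1, q2 = inc.T, inc.Q(1), inc.Q(2)
    if q2 > 0:
        return (t - 1) / t * q1 ** 2 / (2 * q2)
    return (t - 1) / t * q1 * (q1 - 1) / 2


def rarefy_extrapolate(inc: IncidenceData, q: int, t: int) -> float:
    """Expected Hill diversity of order ``q`` at ``t`` sampling units.

    Order 0 (richness): hypergeometric interpolation for t <= T and the
    Chao2-based extrapolation beyond; order 2 (Simpson, ^2D): the
    moment-based incidence estimator
    ``(t U/T)^2 / (t U/T + t (t-1) sum Y(Y-1) / (T (T-1)))``,
    a single expression valid on both sides of T.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if q not in (0, 2):
        raise ValueError("only Hill orders 0 and 2 are implemented")
    big_t, s_obs = inc.T, inc.s_obs
    if s_obs == 0:
        raise ValueError("empty incidence matrix")
    y = inc.Y[inc.Y > 0].to_numpy(dtype=float)
    if q == 0:
        if t <= big_t:
            with np.errstate(invalid="ignore"):
                log_absent = _log_choose(big_t - y, t) - _log_choose(big_t, t)
            absent = np.where(big_t - y >= t, np.exp(log_absent), 0.0)
            return float(s_obs - absent.sum())
        q0 = _q0_hat(inc)
        q1 = inc.Q(1)
        if q0 == 0 or q1 == 0:
            return float(s_obs)
        extra = t - big_t
        return float(s_obs + q0 * (1 - (1 - q1 / (q1 + big_t * q0)) ** extra))
    u = y.sum()
    pair = (y * (y - 1)).sum()
    num = (t * u / big_t) ** 2
    den = t * u / big_t + t * (t - 1) * pair / (big_t * (big_t - 1))
    return float(num / den)


def rarefaction_curve(inc: IncidenceData, q: int, t_max: int | None = None
                      ) -> pd.Series:
    """Diversity of order ``q`` for t = 1..t_max (default 2T)."""
    t_max = t_max or 2 * inc.T
    ts = np.arange(1, t_max + 1)
    return pd.Series([rarefy_extrapolate(inc, q, int(t)) for t in ts],
                     index=ts, name=f"q{q}")


# ----------------------------------------------------------------------
# detectability
# ----------------------------------------------------------------------

def detectability_summary(events: pd.DataFrame,
                          captures: pd.DataFrame | None = None,
                          metadata: pd.DataFrame | None = None,
                          taxon_col: str = "sonotype",
                          survey_nights=None):
    """Per site-year detectability ratios and detection-history pairs.

    ``survey_nights`` optionally lists every night actually surveyed (the
    sampling design); without it, only nights on which *something* was
    detected are knowable from the data and completely silent nights are
    omitted from the detection histories.

    Returns ``(summary, pairs)``:

    * ``summary`` — one row per sampling point x year with observed
      richness, the Jack1 estimate and mean detectability = S_obs / Jack1
      (site-years with fewer than two sampling events are excluded with a
      warning);
    * ``pairs`` — one row per (taxon, consecutive-event pair) where the
      taxon was detected at event i, with ``detected_next`` in {0, 1} and
      site covariates, ready for external mixed-model fitting.
    """
    ev = events.rename(columns={"species": taxon_col}).copy()
    if "year" not in ev.columns:
        ev["year"] = 0
    if captures is not None and len(captures):
        cap = captures.rename(columns={"species": taxon_col}).copy()
        if "year" not in cap.columns:
            cap["year"] = 0
        if "night" not in cap.columns:
            cap["night"] = "net"
        ev = pd.concat([ev[[taxon_col, "site", "night", "year"]],
                        cap[[taxon_col, "site", "night", "year"]]],
                       ignore_index=True)
    summaries, pair_rows = [], []
    for (site, year), grp in ev.groupby(["site", "year"]):
        nights = set(grp["night"].unique())
        if survey_nights is not None:
            nights |= set(survey_nights)
        nights = sorted(nights)
        if len(nights) < 2:
            warnings.warn(f"site-year ({site}, {year}) has fewer than 2 "
                          "sampling events; excluded")
            continue
        mat = (pd.crosstab(grp[taxon_col], grp["night"])
               .reindex(columns=nights, fill_value=0) > 0).astype(int)
        inc = IncidenceData(matrix=mat)
        est = jackknife1(inc)
        meta = {}
        if metadata is not None and site in metadata.index:
            meta = {k: metadata.loc[site, k] for k in ("habitat", "location")
                    if k in metadata.columns}
        summaries.append({"site": site, "year": year, "T": inc.T,
                          "s_obs": inc.s_obs, "jack1": est,
                          "mean_detectability": inc.s_obs / est, **meta})
        for taxon in mat.index:
            row = mat.loc[taxon].to_numpy()
            for i in range(len(nights) - 1):
                if row[i] == 1:
                    pair_rows.append({"species": taxon, "site": site,
                                      "year": year, "event": nights[i],
                                      "detected_next": int(row[i + 1]), **meta})
    return pd.DataFrame(summaries), pd.DataFrame(pair_rows)
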