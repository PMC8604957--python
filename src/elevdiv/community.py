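"""Shared site-by-taxon community container.

A community matrix holds non-negative integer counts (acoustic activity
index tallies or mistnet captures) for each sampling point (row) and taxon
(column), together with per-site metadata (elevational location, habitat,
year).  Rows are sampling points, not pooled locations: null-model
randomizations and standardized effect sizes operate at the sampling-point
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("location", "habitat", "year")


@dataclass
class CommunityMatrix:
    """Sites x taxa abundance matrix with site metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sampling-point id, one column per taxon,
        non-negative integer counts.
    metadata
        DataFrame indexed by the same sampling-point ids with at least a
        ``location`` column; ``habitat`` and ``year`` are carried along when
        present.
    abundance_source
        ``"acoustic"`` (activity-index counts) or ``"mistnet"`` (captures).
        Metadata only -- it never changes a computation.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    abundance_source: str = "acoustic"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            self.metadata = self.metadata.reindex(self.counts.index)
        if self.metadata["location"].isna().any():
            missing = self.metadata.index[self.metadata["location"].isna()]
            raise ValueError(f"metadata missing for sites: {list(missing)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("community counts must be non-negative")
        if self.abundance_source not in ("acoustic", "mistnet"):
            raise ValueError(f"unknown abundance_source {self.abundance_source!r}")

    # ------------------------------------------------------------------
    @property
    def sites(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        """Binary occurrence matrix (count > 0)."""
        return (self.counts > 0).astype(int)

    def richness(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    def drop_taxa(self, taxa) -> "CommunityMatrix":
        keep = [t for t in self.counts.columns if t not in set(taxa)]
        return replace(self, counts=self.counts[keep].copy(),
                       metadata=self.metadata.copy())

    def site_weights(self, site) -> pd.Series:
        """Within-site relative abundances (sum to 1 over taxa with count > 0)."""
        row = self.counts.loc[site].astype(float)
        total = row.sum()
        if total == 0:
            return row
        return row / total

    # ------------------------------------------------------------------
    def to_csv(self, counts_path, metadata_path=None) -> None:
        self.counts.to_csv(counts_path, index_label="site")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, index_label="site")

    @classmethod
    def from_csv(cls, counts_path, metadata_path=None,
                 abundance_source: str = "acoustic") -> "CommunityMatrix":
        counts = pd.read_csv(counts_path, index_col="site")
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, index_col="site")
        else:
            meta = pd.DataFrame(index=counts.index,
                                data={"location": "all", "habitat": "unknown",
                                      "year": 0})
            warnings.warn("no metadata file supplied; all sites placed in a "
                          "single location group")
        return cls(counts=counts, metadata=meta, abundance_source=abundance_source)
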