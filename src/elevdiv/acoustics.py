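"""Call classification, sonotype merging and acoustic activity indexing.

A labelled call library (pulses x 9 acoustic parameters) trains a
K-nearest-neighbour classifier whose cross-validated confusion matrix
drives the sonotype construction: any class whose per-class recall falls
below a threshold (default 85%) is merged with the class absorbing most of
its misclassifications, and the classifier is re-fitted, until every
remaining class is reliably identifiable.  Detection events are then
collapsed into the Acoustic Activity Index: the number of distinct 5-min
intervals in which a sonotype was recorded at a sampling point, a
detection-rate-robust abundance proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .community import CommunityMatrix

FEATURE_COLUMNS = [
    "pf_avg", "pf_max", "f_center", "pf_min", "pf_start", "pf_end",
    "bw90", "entropy_avg", "duration_ms",
]

LABEL_COLUMN = "species"

EVENT_COLUMNS = ["sonotype", "site", "location", "habitat", "year",
                 "night", "interval"]


# ----------------------------------------------------------------------
# classifier + confusion
# ----------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Pooled held-out confusion counts (rows = true, columns = predicted)."""

    counts: pd.DataFrame

    @property
    def labels(self) -> list:
        return list(self.counts.index)

    @property
    def recall(self) -> pd.Series:
        """Per-class recall: diagonal over row totals."""
        diag = pd.Series(np.diag(self.counts.to_numpy()),
                         index=self.counts.index, dtype=float)
        return diag / self.counts.sum(axis=1)


def _validate_library(library: pd.DataFrame) -> None:
    if LABEL_COLUMN not in library.columns:
        raise ValueError(f"library needs a {LABEL_COLUMN!r} column")
    feats = [c for c in library.columns if c != LABEL_COLUMN]
    if len(feats) < 1:
        raise ValueError("library has no feature columns")
    if library[LABEL_COLUMN].nunique() < 2:
        raise ValueError("call library needs at least 2 species")
    if not np.isfinite(library[feats].to_numpy(dtype=float)).all():
        raise ValueError("non-finite call parameters")


def cv_knn_confusion(library: pd.DataFrame, k: int = 1, folds: int = 5,
                     seed: int = 0) -> ConfusionMatrix:
    """Stratified k-fold cross-validated KNN confusion matrix.

    Features are standardized inside each fold (fitted on the training
    folds only, via a pipeline).  ``k=1`` is the "fine KNN" preset
    convention: a single Euclidean nearest neighbour on standardized
    features.
    """
    _validate_library(library)
    feats = [c for c in library.columns if c != LABEL_COLUMN]
    y = library[LABEL_COLUMN].to_numpy()
    smallest = pd.Series(y).value_counts().min()
    if smallest < folds:
        raise ValueError(f"every class needs >= {folds} pulses "
                         f"(smallest has {smallest})")
    x = library[feats].to_numpy(dtype=float)
    n_train = len(y) - int(np.ceil(len(y) / folds))
    if k >= n_train:
        raise ValueError(f"k={k} is not smaller than the training-fold size")
    model = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, x, y, cv=cv)
    labels = sorted(pd.unique(y))
    counts = _sk_confusion(y, pred, labels=labels)
    return ConfusionMatrix(counts=pd.DataFrame(counts, index=labels,
                                               columns=labels))


# ----------------------------------------------------------------------
# sonotype merging
# ----------------------------------------------------------------------

def merge_to_sonotypes(library: pd.DataFrame, k: int = 1, folds: int = 5,
                       threshold: float = 0.85, seed: int = 0,
                       confusion: ConfusionMatrix | None = None) -> dict:
    """Merge confusable call classes into sonotypes until all are reliable.

    Iteratively: while any class recall < ``threshold``, merge the
    lowest-recall class into the class that receives the largest share of
    its misclassifications (ties broken by label order), relabel the
    library and re-run the cross-validated classifier.  Stops when all
    recalls reach the threshold or a single class remains.  Returns the
    species -> sonotype map; merged sonotype labels join their member
    labels with ``+`` in sorted order.
    """
    _validate_library(library)
    species = sorted(library[LABEL_COLUMN].unique())
    mapping = {s: s for s in species}
    work = library.copy()
    conf = confusion
    for _ in range(len(species)):  # terminates in <= n_species - 1 merges
        if work[LABEL_COLUMN].nunique() < 2:
            break
        if conf is None:
            conf = cv_knn_confusion(work, k=k, folds=folds, seed=seed)
        recall = conf.recall
        if (recall >= threshold).all():
            break
        worst = recall.sort_index().idxmin()  # lowest recall, label-order ties
        row = conf.counts.loc[worst].drop(worst)
        if row.sum() == 0:
            break
        partner = row.sort_index().idxmax()
        members = sorted(set(worst.split("+")) | set(partner.split("+")))
        new_label = "+".join(members)
        for s in species:
            if mapping[s] in (worst, partner):
                mapping[s] = new_label
        work[LABEL_COLUMN] = work[LABEL_COLUMN].map(
            lambda lab: new_label if lab in (worst, partner) else lab)
        conf = None
    return mapping


def write_sonotype_map(mapping: dict, path) -> None:
    pd.DataFrame({"species": list(mapping), "sonotype": list(mapping.values())}
                 ).to_csv(path, index=False)


def read_sonotype_map(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["species"], df["sonotype"]))


# ----------------------------------------------------------------------
# activity index
# ----------------------------------------------------------------------

def acoustic_activity_index(events: pd.DataFrame,
                            sites: pd.DataFrame | None = None
                            ) -> CommunityMatrix:
    """Collapse detection events into per-site activity-index counts.

    Each (site, sonotype) cell is the number of distinct (night, 5-min
    interval) slots with at least one event: repeated passes inside one
    interval count once.  ``sites`` optionally supplies the full site
    metadata frame so that sites without any event still appear as all-zero
    rows.
    """
    if len(events):
        missing = [c for c in ("sonotype", "site", "night", "interval")
                   if c not in events.columns]
        if missing:
            raise ValueError(f"events missing columns: {missing}")
        if (events["interval"] < 0).any():
            raise ValueError("interval indices must be >= 0")
        uniq = events.drop_duplicates(["site", "sonotype", "night", "interval"])
        counts = (uniq.groupby(["site", "sonotype"]).size()
                  .unstack(fill_value=0))
    else:
        counts = pd.DataFrame()
    if sites is not None:
        counts = counts.reindex(index=sites.index, fill_value=0)
        meta = sites.copy()
    else:
        meta_cols = [c for c in ("location", "habitat", "year")
                     if c in events.columns]
        meta = (events[["site", *meta_cols]].drop_duplicates("site")
                .set_index("site").reindex(counts.index))
        if "location" not in meta.columns:
            meta["location"] = "all"
    counts = counts.fillna(0).astype(int)
    counts.columns.name = None
    counts.index.name = "site"
    return CommunityMatrix(counts=counts, metadata=meta,
                           abundance_source="acoustic")


def relative_abundance(community: CommunityMatrix, by: str = "location"
                       ) -> pd.DataFrame:
    """Proportion of detections per taxon within each location (rows sum to 1).

    All-zero locations are excluded with a warning.
    """
    totals = community.counts.groupby(community.metadata[by]).sum()
    row_sums = totals.sum(axis=1)
    empty = row_sums[row_sums == 0].index.tolist()
    if empty:
        warnings.warn(f"locations with no detections excluded: {empty}")
        totals = totals.drop(index=empty)
        row_sums = row_sums.drop(index=empty)
    return totals.div(row_sums, axis=0)
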