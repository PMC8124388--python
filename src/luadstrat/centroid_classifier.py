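"""Nearest-centroid classifier for cross-cohort cluster prediction.

The training cohort's panel genes are median-centered per gene; each
cluster's centroid is the mean centered profile of its members.  A new
sample is assigned to the cluster whose centroid has the highest Pearson
correlation with the sample's (centered) panel vector — the same mechanics
serve both the essential-gene clusters and published expression-subtype
centroids (TRU/PP/PI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

logger = logging.getLogger("luadstrat")


@dataclass
class CentroidModel:
    """Per-cluster centroids in median-centered space plus training medians."""

    centroids: pd.DataFrame  # index = panel genes, columns = cluster labels
    training_medians: pd.Series  # per-gene medians of the training cohort

    def __post_init__(self) -> None:
        if not self.centroids.index.equals(self.training_medians.index):
            raise ValueError("centroid genes and training medians must align")

    @property
    def panel(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def cluster_ids(self) -> list:
        return list(self.centroids.columns)

    def to_tsv(self, path: str) -> None:
        out = self.centroids.copy()
        out.insert(0, "median", self.training_medians)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str) -> "CentroidModel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        medians = df.pop("median")
        df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
        return cls(centroids=df, training_medians=medians)


@dataclass
class Prediction:
    """Assigned cluster plus the correlation to every centroid, per sample."""

    labels: pd.Series  # assigned cluster; NaN-free, but see `unclassified`
    correlations: pd.DataFrame  # samples x clusters
    tie: pd.Series  # bool, exact argmax tie (lowest cluster kept)
    unclassified: pd.Series  # bool, zero-variance sample vector


def build_centroids(
    expr: ExpressionMatrix, labels: pd.Series, panel: list[str]
) -> CentroidModel:
    """Median-center each panel gene, average per cluster."""
    missing = [g for g in panel if g not in expr.data.index]
    if missing:
        raise ValueError(f"panel genes missing from expression matrix: {missing}")
    sub = expr.data.loc[panel, labels.index]
    medians = sub.median(axis=1)
    centered = sub.sub(medians, axis=0)
    clusters = sorted(labels.unique())
    cols = {}
    for c in clusters:
        members = labels.index[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} has no samples")
        cols[c] = centered[members].mean(axis=1)
    centroids = pd.DataFrame(cols)
    return CentroidModel(centroids=centroids, training_medians=medians)


def predict(
    model: CentroidModel,
    expr_new: ExpressionMatrix,
    centering: str = "cohort_median",
) -> Prediction:
    """Assign each new sample to the max-Pearson-correlation centroid.

    ``cohort_median`` centers panel genes on the NEW cohort's own medians
    (removes platform location shifts); ``training_median`` reuses the
    training cohort's.  Panel genes absent from the new cohort are dropped
    from both sides with a warning; constant sample vectors are flagged
    unclassified.
    """
    if centering not in ("cohort_median", "training_median"):
        raise ValueError("centering must be cohort_median or training_median")
    present = [g for g in model.panel if g in expr_new.data.index]
    absent = [g for g in model.panel if g not in expr_new.data.index]
    if absent:
        logger.warning("dropping %d panel genes absent from cohort: %s", len(absent), absent)
    if len(present) < 2:
        raise ValueError("need >=2 panel genes present in the new cohort")

    sub = expr_new.data.loc[present]
    if centering == "cohort_median":
        centered = sub.sub(sub.median(axis=1), axis=0)
    else:
        centered = sub.sub(model.training_medians.loc[present], axis=0)
    cent = model.centroids.loc[present]

    x = centered.to_numpy().T  # samples x genes
    c = cent.to_numpy().T  # clusters x genes
    xm = x - x.mean(axis=1, keepdims=True)
    cm = c - c.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xm, axis=1)
    cn = np.linalg.norm(cm, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xm @ cm.T) / np.outer(xn, cn)

    unclassified = xn == 0
    corr_safe = np.where(np.isnan(corr), -np.inf, corr)
    best = np.argmax(corr_safe, axis=1)  # lowest cluster index wins exact ties
    maxval = corr_safe[np.arange(len(best)), best]
    tie = (corr_safe == maxval[:, None]).sum(axis=1) > 1

    clusters = model.cluster_ids
    labels = pd.Series(
        [clusters[b] for b in best], index=sub.columns, name="cluster", dtype=object
    )
    labels[unclassified] = pd.NA
    return Prediction(
        labels=labels,
        correlations=pd.DataFrame(corr, index=sub.columns, columns=clusters),
        tie=pd.Series(tie & ~unclassified, index=sub.columns),
        unclassified=pd.Series(unclassified, index=sub.columns),
    )


def subtype_assign(
    expr: ExpressionMatrix, published_centroids: CentroidModel, centering: str = "cohort_median"
) -> Prediction:
    """Assign published expression subtypes (e.g. TRU/PP/PI) to each sample.

    The user supplies the published centroid table; mechanics are identical
    to :func:`predict`.
    """
    return predict(published_centroids, expr, centering=centering)


def reduce_panel(panel: list[str], overlap: list[str]) -> list[str]:
    """Drop panel genes overlapping a published classifier's gene list."""
    overlap_set = set(overlap)
    return [g for g in panel if g not in overlap_set]
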