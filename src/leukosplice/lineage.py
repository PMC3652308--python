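"""Cell-lineage scoring by marker-restricted correlation Z-scores.

A lineage reference holds, per cell type, the markers most specifically
expressed in that lineage (typically 50-150 genes) and a centroid profile
over the union of all markers.  A sample is scored against every lineage
by Pearson correlation over shared markers; within each sample the
correlations are standardised across lineages into Z-scores, so the
dominant cellular composition of the sample stands out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LineageReference",
    "build_marker_db",
    "score_samples",
    "cluster_lineage_scores",
]


@dataclass
class LineageReference:
    """Per-lineage marker genes and centroid profiles.

    ``centroids`` is genes x lineages over the union of selected markers.
    """

    markers: dict[str, list[str]]
    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("need >= 2 lineages")
        if not np.isfinite(self.centroids.to_numpy()).all():
            raise ValueError("centroid profiles must be finite")

    def write_tsv(self, path) -> None:
        rows = []
        for lineage in sorted(self.markers):
            for rank, gene in enumerate(self.markers[lineage], start=1):
                rows.append((lineage, gene, rank, self.centroids.loc[gene, lineage]))
        pd.DataFrame(
            rows, columns=["lineage", "gene", "rank", "centroid_value"]
        ).to_csv(path, sep="\t", index=False)


def build_marker_db(
    compendium: pd.DataFrame,
    labels,
    markers_per_lineage: int = 100,
) -> LineageReference:
    """Select lineage markers by correlation with the ideal binary profile.

    For each lineage, genes are ranked by Pearson correlation between
    their compendium profile and the indicator of that lineage's columns
    (1 on its columns, 0 elsewhere); the top ``markers_per_lineage`` genes
    become its markers, with ties broken by gene name.  Centroids are the
    mean profile over the lineage's columns restricted to the union of all
    selected markers.
    """
    labels = pd.Series(labels).reindex(compendium.columns)
    lineages = sorted(pd.unique(labels.dropna()))
    if len(lineages) < 2:
        raise ValueError("need >= 2 lineages in the compendium")
    if markers_per_lineage > compendium.shape[0]:
        raise ValueError("more markers requested than genes available")
    x = compendium.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    markers: dict[str, list[str]] = {}
    for lineage in lineages:
        ind = (labels == lineage).to_numpy(dtype=float)
        ic = ind - ind.mean()
        denom = xs * np.sqrt((ic**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, xc @ ic / denom, 0.0)
        order = sorted(
            range(len(corr)), key=lambda i: (-corr[i], compendium.index[i])
        )
        markers[lineage] = [compendium.index[i] for i in order[:markers_per_lineage]]
    union = sorted({g for ms in markers.values() for g in ms})
    centroids = pd.DataFrame(
        {
            lineage: compendium.loc[union, labels.index[labels == lineage]].mean(axis=1)
            for lineage in lineages
        }
    )
    return LineageReference(markers=markers, centroids=centroids)


def score_samples(samples: pd.DataFrame, ref: LineageReference):
    """Correlate samples with lineage centroids; Z-standardise per sample.

    Requires >= 50% of the reference marker union to be present in the
    sample matrix.  Lineages with < 3 shared markers get undefined (NaN)
    scores.  Returns ``(pearson_r, z)`` DataFrames (samples x lineages).
    Degenerate within-sample spreads (sd = 0) yield z = 0 by definition.
    """
    union = list(ref.centroids.index)
    shared = [g for g in union if g in samples.index]
    if len(shared) < 0.5 * len(union):
        raise ValueError(
            f"only {len(shared)}/{len(union)} reference markers present in the samples"
        )
    dropped = len(union) - len(shared)
    if dropped:
        logger.info("%d reference markers absent from the sample matrix", dropped)
    lineages = list(ref.centroids.columns)
    r = pd.DataFrame(index=samples.columns, columns=lineages, dtype=float)
    for lineage in lineages:
        lmark = [g for g in ref.markers[lineage] if g in samples.index]
        if len(lmark) < 3:
            logger.warning("lineage %s has < 3 shared markers: score undefined", lineage)
            r[lineage] = np.nan
            continue
        cent = ref.centroids.loc[shared, lineage].to_numpy()
        sub = samples.loc[shared].to_numpy(dtype=float)
        cc = cent - cent.mean()
        sc = sub - sub.mean(axis=0, keepdims=True)
        denom = np.sqrt((sc**2).sum(axis=0)) * np.sqrt((cc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r[lineage] = np.where(denom > 0, sc.T @ cc / denom, 0.0)
    mean = r.mean(axis=1, skipna=True)
    sd = r.std(axis=1, ddof=1)
    z = r.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    z = z.where(sd > 0, 0.0).astype(float)
    z[r.isna()] = np.nan
    return r, z


def cluster_lineage_scores(z: pd.DataFrame, known_labels=None):
    """Hierarchically cluster samples by their lineage Z profiles.

    Delegates to the splice classifier machinery (city-block distance,
    average linkage) on the transposed Z matrix.
    """
    from .splicing import classify_samples

    data = z.T  # lineages x samples
    if data.shape[1] == 1:
        raise ValueError("need >= 2 samples to cluster")
    return classify_samples(data, list(data.index), known_labels=known_labels)
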