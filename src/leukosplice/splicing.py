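"""Alternative-splicing detection from junction/exon probe-set matrices.

Probe sets play one of four roles: constitutive (present in all isoforms;
their mean estimates gene-level expression), reciprocal inclusion /
exclusion junctions (probing mutually exclusive exon connectivity), and
exon/PSR probe sets.  Two detectors are provided:

* reciprocal-junction regression: gene-normalised inclusion intensity is
  regressed on gene-normalised exclusion intensity over the baseline
  group; the per-sample deviation from that fit is the splicing signal,
  and an event is called when the group-mean deviation shifts by at least
  log2(fold-change threshold) with a significant t-test while the raw
  inclusion and exclusion changes are opposite in sign (bi-directional
  gate);
* splicing index: exon probe intensity minus gene-level expression, with
  a group-difference threshold.

Sample classification by called features uses agglomerative clustering
with city-block distance and average linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeSetMatrix",
    "SpliceEvent",
    "summarize_gene_expression",
    "detect_junction_events",
    "detect_splicing_index_events",
    "classify_samples",
    "ClassificationResult",
    "annotate_events",
]

_ROLES = {"constitutive", "junction_inclusion", "junction_exclusion", "exon_psr"}


@dataclass
class ProbeSetMatrix:
    """Log2 probe-set x sample intensities plus per-probe-set annotations.

    ``annotations`` is indexed by probe set with columns gene, role,
    reciprocal_partner, sequence, event_annotation.  ``sample_conditions``
    maps sample -> condition label.
    """

    intensities: pd.DataFrame
    annotations: pd.DataFrame
    sample_conditions: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensities.to_numpy()).all():
            raise ValueError("intensities must be finite")
        missing = set(self.intensities.index) - set(self.annotations.index)
        if missing:
            raise ValueError(f"probe sets without annotations: {sorted(missing)[:5]}")
        bad = set(self.annotations["role"]) - _ROLES
        if bad:
            raise ValueError(f"unknown probe-set roles: {sorted(bad)}")
        ann = self.annotations
        incl = ann[ann["role"] == "junction_inclusion"]
        for probe, row in incl.iterrows():
            partner = row["reciprocal_partner"]
            if not partner or partner not in ann.index:
                raise ValueError(f"inclusion junction {probe} lacks a reciprocal partner")
            if ann.loc[partner, "gene"] != row["gene"]:
                raise ValueError(f"reciprocal pair {probe}/{partner} spans two genes")

    def conditions_of(self, samples) -> pd.Series:
        if self.sample_conditions is None:
            raise ValueError("no sample condition labels attached")
        return self.sample_conditions.reindex(samples)

    def write_tsv(self, matrix_path, annotation_path) -> None:
        self.intensities.to_csv(matrix_path, sep="\t", index_label="probe_set")
        self.annotations.to_csv(annotation_path, sep="\t", index_label="probe_set")

    @classmethod
    def read_tsv(cls, matrix_path, annotation_path, sample_conditions=None):
        x = pd.read_csv(matrix_path, sep="\t", index_col="probe_set")
        ann = pd.read_csv(annotation_path, sep="\t", index_col="probe_set").fillna("")
        return cls(intensities=x, annotations=ann, sample_conditions=sample_conditions)


@dataclass
class SpliceEvent:
    gene: str
    inclusion_probe_set: str
    exclusion_probe_set: str | None
    contrast: tuple[str, str]
    score: float  # signed splicing change, log2 units
    p_value: float
    direction: str  # "inclusion" | "exclusion"
    detection_method: str  # "junction_regression" | "splicing_index"
    annotations: dict = field(default_factory=dict)


def summarize_gene_expression(matrix: ProbeSetMatrix) -> pd.DataFrame:
    """Per-gene per-sample mean of constitutive probe-set intensities.

    Genes without constitutive probe sets are excluded (logged).
    """
    ann = matrix.annotations
    const = ann.index[ann["role"] == "constitutive"]
    skipped = sorted(set(ann["gene"]) - set(ann.loc[const, "gene"]))
    if skipped:
        logger.warning("%d genes without constitutive probe sets excluded", len(skipped))
    sub = matrix.intensities.loc[const]
    return sub.groupby(ann.loc[const, "gene"]).mean()


def _two_group_columns(matrix: ProbeSetMatrix, groups, contrast):
    g = pd.Series(groups) if groups is not None else matrix.sample_conditions
    if g is None:
        raise ValueError("sample groups required")
    g = g.reindex(matrix.intensities.columns)
    c1, c2 = contrast
    s1 = list(g.index[g == c1])
    s2 = list(g.index[g == c2])
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"contrast {contrast} needs >= 2 samples per group")
    return s1, s2


def detect_junction_events(
    matrix: ProbeSetMatrix,
    summary: pd.DataFrame,
    contrast: tuple[str, str],
    groups=None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score every reciprocal junction pair; call bi-directional changes.

    Returns one row per pair with the deviation score (group2 - group1
    mean deviation from the baseline-group regression of normalised
    inclusion on normalised exclusion), the Welch t-test p on the
    deviations, the raw inclusion/exclusion group-mean changes, and the
    ``called`` flag combining the |score| >= log2(fc_threshold), p <
    p_threshold and opposite-sign (reciprocity) gates.
    """
    s1, s2 = _two_group_columns(matrix, groups, contrast)
    ann = matrix.annotations
    x = matrix.intensities
    score_min = np.log2(fc_threshold)
    rows = []
    incl_probes = ann.index[ann["role"].isin(["junction_inclusion", "exon_psr"])]
    for probe in incl_probes:
        partner = ann.loc[probe, "reciprocal_partner"]
        if not partner or partner not in ann.index:
            continue  # PSRs only participate when explicitly paired
        gene = ann.loc[probe, "gene"]
        if gene not in summary.index:
            continue
        g_expr = summary.loc[gene]
        nI = x.loc[probe] - g_expr
        nE = x.loc[partner] - g_expr
        nI1, nE1 = nI[s1].to_numpy(), nE[s1].to_numpy()
        if np.var(nE1) < 1e-12:
            # degenerate baseline: unit-slope fallback
            a, b = 0.0, 1.0
            logger.debug("degenerate baseline regression for %s; d = nI - nE", probe)
        else:
            # Under the no-event baseline the population slope is the
            # variance ratio Var(g-noise)/(Var(g-noise)+Var(eE)) in [0, 1);
            # clamping the small-sample OLS estimate to that range keeps
            # the deviation score from exploding on noisy denominators.
            b = float(np.cov(nI1, nE1, ddof=1)[0, 1] / np.var(nE1, ddof=1))
            b = min(max(b, 0.0), 1.0)
            a = float(nI1.mean() - b * nE1.mean())
        d = nI - (a + b * nE)
        d1, d2 = d[s1].to_numpy(), d[s2].to_numpy()
        score = float(d2.mean() - d1.mean())
        t = stats.ttest_ind(d2, d1, equal_var=False)
        delta_incl = float(x.loc[probe, s2].mean() - x.loc[probe, s1].mean())
        delta_excl = float(x.loc[partner, s2].mean() - x.loc[partner, s1].mean())
        reciprocal = delta_incl * delta_excl < 0
        called = (
            abs(score) >= score_min
            and float(t.pvalue) < p_threshold
            and reciprocal
        )
        rows.append(
            {
                "gene": gene,
                "inclusion_probe_set": probe,
                "exclusion_probe_set": partner,
                "contrast": f"{contrast[0]}-vs-{contrast[1]}",
                "score": score,
                "p_value": float(t.pvalue),
                "delta_inclusion": delta_incl,
                "delta_exclusion": delta_excl,
                "reciprocal": reciprocal,
                "direction": "inclusion" if score > 0 else "exclusion",
                "detection_method": "junction_regression",
                "called": called,
            }
        )
    return pd.DataFrame(rows)


def detect_splicing_index_events(
    matrix: ProbeSetMatrix,
    summary: pd.DataFrame,
    contrast: tuple[str, str],
    groups=None,
    si_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Exon-level splicing-index detector.

    SI[p,s] = x[p,s] - gene_expression[gene(p), s]; an exon probe set is
    called when |mean(SI, group2) - mean(SI, group1)| >= si_threshold with
    Welch-t p < p_threshold.
    """
    s1, s2 = _two_group_columns(matrix, groups, contrast)
    ann = matrix.annotations
    x = matrix.intensities
    rows = []
    for probe in ann.index[ann["role"] == "exon_psr"]:
        gene = ann.loc[probe, "gene"]
        if gene not in summary.index:
            continue
        si = x.loc[probe] - summary.loc[gene]
        si1, si2 = si[s1].to_numpy(), si[s2].to_numpy()
        delta = float(si2.mean() - si1.mean())
        t = stats.ttest_ind(si2, si1, equal_var=False)
        called = abs(delta) >= si_threshold and float(t.pvalue) < p_threshold
        rows.append(
            {
                "gene": gene,
                "inclusion_probe_set": probe,
                "exclusion_probe_set": "",
                "contrast": f"{contrast[0]}-vs-{contrast[1]}",
                "score": delta,
                "p_value": float(t.pvalue),
                "direction": "inclusion" if delta > 0 else "exclusion",
                "detection_method": "splicing_index",
                "called": called,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClassificationResult:
    linkage_matrix: np.ndarray
    cluster_labels: pd.Series
    accuracy: float | None
    newick: str


def _to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def rec(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def classify_samples(
    data: pd.DataFrame,
    features,
    known_labels=None,
    distance: str = "cityblock",
    linkage_method: str = "average",
    n_clusters: int = 2,
) -> ClassificationResult:
    """Agglomerative clustering of samples restricted to ``features``.

    City-block distance and average linkage by default.  Accuracy against
    ``known_labels`` (when given) is the best matched fraction over the
    assignment of cluster ids to labels.
    """
    features = [f for f in features if f in data.index]
    if not features:
        raise ValueError("feature list disjoint from the matrix")
    sub = data.loc[features]
    if sub.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    # canonical feature order so clustering is invariant to input order
    sub = sub.sort_index()
    dist = pdist(sub.to_numpy().T, metric=distance)
    Z = linkage(dist, method=linkage_method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    cluster_labels = pd.Series(labels, index=sub.columns, name="cluster")
    accuracy = None
    if known_labels is not None:
        known = pd.Series(known_labels).reindex(sub.columns)
        uniq = list(pd.unique(known))
        if len(uniq) != 2:
            raise ValueError("known_labels must have exactly two classes")
        match_a = ((cluster_labels == 1) == (known == uniq[0])).mean()
        accuracy = float(max(match_a, 1.0 - match_a))
    return ClassificationResult(
        linkage_matrix=Z,
        cluster_labels=cluster_labels,
        accuracy=accuracy,
        newick=_to_newick(Z, list(sub.columns)),
    )


def annotate_events(
    events: pd.DataFrame,
    domain_table: pd.DataFrame | None = None,
    mirna_site_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join protein-domain and miRNA-binding-site flags onto events.

    Annotation tables need a ``probe_set`` column; rows referencing probe
    sets absent from the events are ignored (logged).  Missing tables leave
    all flags false with a warning.
    """
    out = events.copy()
    out["has_protein_domain"] = False
    out["has_mirna_site"] = False
    if out.empty:
        return out
    known = set(out["inclusion_probe_set"])
    for col, table, name in (
        ("has_protein_domain", domain_table, "protein-domain"),
        ("has_mirna_site", mirna_site_table, "miRNA-site"),
    ):
        if table is None:
            logger.warning("no %s annotation table: flags left false", name)
            continue
        probes = set(table["probe_set"])
        unknown = probes - known
        if unknown:
            logger.info("%d %s annotations reference unknown probe sets", len(unknown), name)
        out[col] = out["inclusion_probe_set"].isin(probes)
    return out
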