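"""Merge tumor-cell subclusters into three subtypes by transcriptome similarity.

Subcluster mean profiles are compared by Spearman correlation over the genes
with the highest between-cluster standard deviation; average-linkage
hierarchical clustering on 1 - rho merges the subclusters into k groups,
which are then named by canonical marker expression: ARG1/ALDOB for the
metabolism subtype, TOP2A/STMN1/MKI67 for the proliferative subtype, and
S100A6/S100A11 for the EMT subtype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

NAMING_MARKERS = {
    "metab": ["ARG1", "ALDOB"],
    "prol": ["TOP2A", "STMN1", "MKI67"],
    "emt": ["S100A6", "S100A11"],
}


@dataclass
class ClusterProfile:
    """Per-cluster mean log-expression and cluster sizes."""

    means: pd.DataFrame  # cluster x gene
    sizes: pd.Series     # cluster -> n cells


@dataclass
class SubtypeLabeling:
    cluster_to_subtype: dict
    cell_subtype: pd.Series | None
    naming_evidence: pd.DataFrame  # group x subtype marker means


def mean_profiles(expr: pd.DataFrame, labels: pd.Series) -> ClusterProfile:
    """Arithmetic mean expression per cluster per gene."""
    labels = labels.reindex(expr.index)
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    grouped = expr.groupby(labels, observed=True)
    sizes = grouped.size()
    if (sizes < 1).any():
        raise ValueError("empty cluster in labeling")
    return ClusterProfile(means=grouped.mean(), sizes=sizes)


def top_sd_genes(profiles: ClusterProfile, n: int = 50) -> list[str]:
    """Genes ranked by population SD of cluster means; stable ties, top ``n``."""
    means = profiles.means
    if means.shape[0] < 2:
        raise ValueError("need at least 2 clusters to rank between-cluster SD")
    if n > means.shape[1]:
        raise ValueError(f"requested {n} genes but only {means.shape[1]} available")
    sd = means.std(axis=0, ddof=0).to_numpy()
    order = np.argsort(-sd, kind="stable")
    return means.columns[order[:n]].tolist()


def spearman_matrix(profiles: ClusterProfile, genes: list[str]) -> pd.DataFrame:
    """Cluster-by-cluster Spearman correlation over the given genes.

    Ranks use average tie handling; a constant profile vector has no defined
    rank correlation and contributes 0 (with a warning).
    """
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    sub = profiles.means[genes].to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, sub)
    sd = ranks.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant profile vector(s); correlations recorded as 0",
                      stacklevel=2)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * ranks.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / denom
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    idx = profiles.means.index
    return pd.DataFrame(np.clip(rho, -1.0, 1.0), index=idx, columns=idx)


class TranscriptomeSimilarityMerger(BaseEstimator):
    """Agglomerate subclusters on 1 - Spearman rho and name groups by markers.

    Parameters
    ----------
    n_groups : int
        Number of merged groups (three for the metab/prol/emt scheme).
    linkage : str
        scipy linkage method on the correlation distance; average by default.

    Attributes
    ----------
    group_labels_ : pd.Series
        Merged group index per subcluster.
    cluster_to_subtype_ : dict
        Subcluster -> subtype name, filled when profiles are supplied.
    """

    def __init__(self, n_groups: int = 3, linkage: str = "average"):
        self.n_groups = n_groups
        self.linkage = linkage

    def fit(self, similarity: pd.DataFrame, profiles: ClusterProfile | None = None):
        sim = similarity.to_numpy(dtype=float)
        if sim.shape[0] != sim.shape[1] or not np.allclose(sim, sim.T, atol=1e-8):
            raise ValueError("similarity matrix must be square and symmetric")
        if self.n_groups == 1 or sim.shape[0] == 1:
            groups = np.ones(sim.shape[0], dtype=int)
        else:
            dist = 1.0 - sim
            np.fill_diagonal(dist, 0.0)
            Z = sch.linkage(ssd.squareform(dist, checks=False), method=self.linkage)
            groups = sch.fcluster(Z, t=self.n_groups, criterion="maxclust")
        self.group_labels_ = pd.Series(groups, index=similarity.index, name="group")
        self.cluster_to_subtype_ = None
        if profiles is not None:
            self.cluster_to_subtype_, self.naming_evidence_ = _name_groups(
                self.group_labels_, profiles)
        return self


def _name_groups(group_labels: pd.Series, profiles: ClusterProfile
                 ) -> tuple[dict, pd.DataFrame]:
    """Assign metab/prol/emt names to merged groups by marker mean expression."""
    evidence = {}
    for subtype, markers in NAMING_MARKERS.items():
        present = [g for g in markers if g in profiles.means.columns]
        if not present:
            raise ValueError(f"no naming markers for {subtype!r} in the profile genes")
        marker_mean = profiles.means[present].mean(axis=1)
        evidence[subtype] = marker_mean.groupby(group_labels).mean()
    table = pd.DataFrame(evidence)
    winners = table.idxmax(axis=0)
    if winners.duplicated().any():
        raise ValueError(
            "marker-based naming collision: group(s) "
            f"{sorted(winners[winners.duplicated()].unique())} win multiple subtype "
            "names; name the groups manually")
    group_to_subtype = {group: subtype for subtype, group in winners.items()}
    if len(set(group_labels)) > len(group_to_subtype):
        raise ValueError("more groups than subtype names; increase markers or lower k")
    mapping = {cluster: group_to_subtype[g] for cluster, g in group_labels.items()}
    return mapping, table


def hcluster_merge(similarity: pd.DataFrame, profiles: ClusterProfile | None = None,
                   k: int = 3, cell_labels: pd.Series | None = None
                   ) -> SubtypeLabeling:
    """Merge subclusters into ``k`` groups; name them by markers when profiles
    are supplied (k = 3), otherwise keep the raw group indices."""
    merger = TranscriptomeSimilarityMerger(n_groups=k).fit(similarity, profiles)
    if merger.cluster_to_subtype_ is not None:
        mapping = merger.cluster_to_subtype_
        evidence = merger.naming_evidence_
    else:
        mapping = merger.group_labels_.to_dict()
        evidence = pd.DataFrame(index=sorted(set(mapping.values())))
    cell_subtype = None
    if cell_labels is not None:
        cell_subtype = cell_labels.map(mapping).rename("subtype")
    return SubtypeLabeling(cluster_to_subtype=mapping, cell_subtype=cell_subtype,
                           naming_evidence=evidence)


def rank_markers(expr: pd.DataFrame, subtype_labels: pd.Series,
                 min_avg_logfc: float = 1.0, n_top: int = 50
                 ) -> dict[str, pd.Series]:
    """Per-subtype genes ranked by avg log fold change versus all other cells.

    avg_logFC(g, s) = mean log-expression of g in subtype s minus the mean in
    all remaining cells; only genes above ``min_avg_logfc`` are kept, ranked
    descending with stable ties, truncated to ``n_top``.
    """
    subtype_labels = subtype_labels.reindex(expr.index)
    present = subtype_labels.dropna().unique()
    if len(present) < 2:
        raise ValueError("need at least 2 subtypes to rank markers")
    out: dict[str, pd.Series] = {}
    values = expr.to_numpy(dtype=float)
    for subtype in present:
        mask = (subtype_labels == subtype).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"subtype {subtype!r} has fewer than 2 cells")
        logfc = values[mask].mean(axis=0) - values[~mask].mean(axis=0)
        order = np.argsort(-logfc, kind="stable")
        ranked = pd.Series(logfc[order], index=expr.columns[order], name="avg_logfc")
        out[subtype] = ranked[ranked > min_avg_logfc].head(n_top)
    return out
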