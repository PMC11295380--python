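"""Gene-signature scoring of cells, spots and bulk samples.

Two engines are provided: a rank-based single-sample enrichment score
(weighted ECDF running-sum statistic with exponent ``alpha``) and a simple
mean of per-gene z-scores. Subtype assignment takes the argmax score over
the three marker signatures; bulk cohorts are split by hierarchical
clustering over the combined metab/EMT marker space into metabolism-driven,
EMT-driven and mixed groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ConfigError

logger = logging.getLogger(__name__)

CSC_MARKERS = ("EPCAM", "CD24", "KRT19", "SOX9", "PROM1", "CD44", "THY1", "CD47")


@dataclass(frozen=True)
class ScoringConfig:
    ssgsea_alpha: float = 0.25
    normalize_ssgsea: bool = True
    csc_markers: tuple[str, ...] = CSC_MARKERS

    def __post_init__(self) -> None:
        if self.ssgsea_alpha <= 0:
            raise ConfigError(f"ssgsea_alpha must be > 0; got {self.ssgsea_alpha}")
        if not self.csc_markers:
            raise ConfigError("csc_markers must be non-empty")


def _running_sum_score(in_set: np.ndarray, alpha: float) -> float:
    """Enrichment statistic for a boolean in-set mask over ranked positions.

    Position 0 is the highest-expressed gene; the in-set ECDF weights each hit
    by its rank-from-bottom raised to ``alpha``, the out-set ECDF is uniform.
    """
    n = in_set.size
    m = int(in_set.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper, non-empty subset of the genes")
    rank_from_bottom = np.arange(n, 0, -1, dtype=float)
    w = np.where(in_set, rank_from_bottom ** alpha, 0.0)
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~in_set) / (n - m)
    return float(np.sum(cdf_in - cdf_out))


def _score_bounds(n: int, m: int, alpha: float) -> tuple[float, float]:
    """Max/min of the statistic: all set genes at the top / at the bottom."""
    top = np.zeros(n, dtype=bool)
    top[:m] = True
    bottom = np.zeros(n, dtype=bool)
    bottom[n - m:] = True
    return _running_sum_score(top, alpha), _running_sum_score(bottom, alpha)


def ssgsea(expr_vector: pd.Series, gene_set: list[str],
           cfg: ScoringConfig = ScoringConfig()) -> float:
    """Single-sample enrichment score of one gene set for one entity.

    Genes are ranked by expression, descending, ties broken by input gene
    order; the score sums the difference between the weighted in-set ECDF and
    the uniform out-set ECDF along the ranking. With ``normalize_ssgsea`` the
    score is divided by the spread between the maximal and minimal value
    achievable for this set size, placing it in [-1, 1] territory regardless
    of gene count.
    """
    genes = expr_vector.index
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has no members in the expression vector")
    order = np.argsort(-expr_vector.to_numpy(dtype=float), kind="stable")
    in_set = genes[order].isin(members)
    score = _running_sum_score(np.asarray(in_set), cfg.ssgsea_alpha)
    if cfg.normalize_ssgsea:
        hi, lo = _score_bounds(len(genes), len(members), cfg.ssgsea_alpha)
        score /= hi - lo
    return score


def mean_z_score(expr: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Average per-gene z-score over the set genes, per entity.

    Genes absent from the matrix are dropped with a warning; genes constant
    across entities contribute 0 by convention.
    """
    present = [g for g in gene_set if g in expr.columns]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if len(present) < len(gene_set):
        warnings.warn(f"{len(gene_set) - len(present)} set genes absent; dropped",
                      stacklevel=2)
    sub = expr[present].to_numpy(dtype=float)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = np.where(sd > 0, (sub - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=1), index=expr.index, name="score")


class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """Transform an entity x gene expression frame into entity x signature scores."""

    def __init__(self, gene_sets: dict[str, list[str]],
                 alpha: float = 0.25, normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cfg = ScoringConfig(ssgsea_alpha=self.alpha, normalize_ssgsea=self.normalize)
        scores = {
            name: [ssgsea(X.loc[e], members, cfg) for e in X.index]
            for name, members in self.gene_sets.items()
        }
        return pd.DataFrame(scores, index=X.index)


class MeanZScorer(TransformerMixin, BaseEstimator):
    """Transform expression into per-signature mean z-scores."""

    def __init__(self, gene_sets: dict[str, list[str]]):
        self.gene_sets = gene_sets

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({name: mean_z_score(X, members)
                             for name, members in self.gene_sets.items()},
                            index=X.index)


def score_subtypes(expr: pd.DataFrame, marker_lists: dict[str, list[str]],
                   method: str = "ssgsea",
                   cfg: ScoringConfig = ScoringConfig()) -> pd.DataFrame:
    """Score every entity against the three subtype marker signatures."""
    if len(marker_lists) != 3:
        raise ValueError("expected exactly three subtype marker lists")
    if method == "ssgsea":
        scorer = SSGSEAScorer(marker_lists, alpha=cfg.ssgsea_alpha,
                              normalize=cfg.normalize_ssgsea)
    elif method == "meanz":
        scorer = MeanZScorer(marker_lists)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return scorer.transform(expr)


def assign_subtype_by_score(scores: pd.DataFrame) -> pd.Series:
    """Argmax-score subtype per entity; exact ties become ``"unassigned"``."""
    values = scores.to_numpy(dtype=float)
    labels = scores.columns[values.argmax(axis=1)].to_numpy(dtype=object)
    sorted_scores = np.sort(values, axis=1)
    ties = sorted_scores[:, -1] == sorted_scores[:, -2]
    labels[ties] = "unassigned"
    return pd.Series(labels, index=scores.index, name="subtype")


def classify_bulk(expr: pd.DataFrame, metab_markers: list[str],
                  emt_markers: list[str]) -> pd.Series:
    """Split bulk samples into Metab-HCC / EMT-HCC / Mixed-HCC.

    Average-linkage hierarchical clustering with correlation distance over
    the combined marker space, cut at three groups; the group with the
    highest mean metabolism signature is Metab-HCC, the highest EMT signature
    is EMT-HCC, and the remainder Mixed-HCC.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 samples to form three groups")
    genes = [g for g in [*metab_markers, *emt_markers] if g in expr.columns]
    if not genes:
        raise ValueError("no marker gene present in the bulk matrix")
    sub = expr[genes].to_numpy(dtype=float)
    if np.allclose(sub, sub[0], atol=1e-12):
        raise ValueError("no separation: all samples identical on the marker space")
    dist = ssd.pdist(sub, metric="correlation")
    groups = sch.fcluster(sch.linkage(dist, method="average"), t=3,
                          criterion="maxclust")
    groups = pd.Series(groups, index=expr.index)

    metab_score = mean_z_score(expr, metab_markers).groupby(groups).mean()
    emt_score = mean_z_score(expr, emt_markers).groupby(groups).mean()
    metab_group = metab_score.idxmax()
    emt_group = emt_score.idxmax()
    if metab_group == emt_group:
        raise ValueError("naming collision: one group tops both signatures")
    names = {metab_group: "Metab-HCC", emt_group: "EMT-HCC"}
    return groups.map(lambda g: names.get(g, "Mixed-HCC")).rename("bulk_subtype")
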