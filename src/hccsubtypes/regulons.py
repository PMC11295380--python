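"""Regulon activity on pseudo-cells: recovery-curve AUC and specificity scores.

Regulons (a transcription factor's target-gene set) are supplied as inputs.
To damp single-cell noise, same-subtype cells are averaged in random disjoint
groups of fixed size ("pseudo-cells"). Activity is the normalized area under
the recovery curve of regulon genes within the top fraction of each
pseudo-cell's expression ranking; specificity per subtype is one minus the
square root of the Jensen–Shannon divergence between the regulon's activity
distribution and the subtype's indicator distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ConfigError, check_count, check_fraction, substream

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulonConfig:
    pseudocell_size: int = 20
    auc_top_fraction: float = 0.05
    jsd_log_base: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        check_count(self.pseudocell_size, "pseudocell_size")
        check_fraction(self.auc_top_fraction, "auc_top_fraction", lo_open=True)
        if self.jsd_log_base <= 1:
            raise ConfigError(f"jsd_log_base must be > 1; got {self.jsd_log_base}")


class PseudocellAggregator(TransformerMixin, BaseEstimator):
    """Average same-label cells in random disjoint chunks of fixed size.

    Cells of each label are randomly permuted (seeded) and split into
    consecutive groups of exactly ``size``; an incomplete trailing group is
    dropped, so every retained cell contributes to exactly one pseudo-cell.

    Attributes
    ----------
    labels_ : pd.Series
        Subtype label of each pseudo-cell, set by :meth:`fit_transform`.
    members_ : dict
        Pseudo-cell id -> contributing cell ids.
    """

    def __init__(self, size: int = 20, random_state: int = 0):
        self.size = size
        self.random_state = random_state

    def fit_transform(self, X: pd.DataFrame, y: pd.Series | None = None
                      ) -> pd.DataFrame:
        if y is None:
            raise ValueError("pseudo-cell aggregation needs per-cell labels y")
        y = y.reindex(X.index)
        rng = substream(self.random_state, "pseudocells")
        rows, labels, members = [], [], {}
        for label in sorted(map(str, y.dropna().unique())):
            ids = X.index[(y == label).to_numpy()].to_numpy()
            if len(ids) < self.size:
                warnings.warn(f"label {label!r} has {len(ids)} cells "
                              f"< pseudocell_size {self.size}; contributes none",
                              stacklevel=2)
                continue
            perm = rng.permutation(ids)
            for c in range(len(ids) // self.size):
                chunk = perm[c * self.size:(c + 1) * self.size]
                pc_id = f"{label}_pc{c + 1:03d}"
                rows.append(X.loc[chunk].mean(axis=0).rename(pc_id))
                labels.append(label)
                members[pc_id] = chunk.tolist()
        if not rows:
            raise ValueError("no label reaches pseudocell_size; nothing to aggregate")
        out = pd.DataFrame(rows)
        self.labels_ = pd.Series(labels, index=out.index, name="subtype")
        self.members_ = members
        return out

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self


def make_pseudocells(expr: pd.DataFrame, labels: pd.Series,
                     cfg: RegulonConfig = RegulonConfig()
                     ) -> tuple[pd.DataFrame, pd.Series]:
    agg = PseudocellAggregator(size=cfg.pseudocell_size, random_state=cfg.seed)
    matrix = agg.fit_transform(expr, labels)
    return matrix, agg.labels_


def auc_recovery(expr_vector: pd.Series, regulon_genes: list[str],
                 cfg: RegulonConfig = RegulonConfig()) -> float:
    """Normalized area under the regulon-gene recovery curve.

    Genes are ranked by expression descending (ties by input order); along
    the top ``ceil(auc_top_fraction * n_genes)`` positions the step curve of
    cumulative regulon hits is integrated and divided by the area an ideal
    ranking (all regulon genes first) would achieve, giving a value in [0, 1].
    """
    genes = expr_vector.index
    members = set(regulon_genes) & set(genes)
    if not members:
        raise ValueError("regulon has no genes in the expression vector")
    n = len(genes)
    window = int(np.ceil(cfg.auc_top_fraction * n))
    order = np.argsort(-expr_vector.to_numpy(dtype=float), kind="stable")[:window]
    hits = np.asarray(genes[order].isin(members), dtype=float)
    area = float(np.cumsum(hits).sum())
    ideal = np.minimum(np.arange(1, window + 1), len(members))
    return area / float(ideal.sum())


class RegulonAUCScorer(TransformerMixin, BaseEstimator):
    """Transform entity x gene expression into entity x regulon AUC activity."""

    def __init__(self, regulons: dict[str, list[str]], top_fraction: float = 0.05):
        self.regulons = regulons
        self.top_fraction = top_fraction

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cfg = RegulonConfig(auc_top_fraction=self.top_fraction)
        return pd.DataFrame(
            {name: [auc_recovery(X.loc[e], members, cfg) for e in X.index]
             for name, members in self.regulons.items()},
            index=X.index)


def rss(activity: pd.DataFrame, labels: pd.Series,
        cfg: RegulonConfig = RegulonConfig()) -> pd.DataFrame:
    """Regulon x subtype specificity scores in [0, 1].

    For each regulon, its AUC column is normalized into a distribution P over
    pseudo-cells; for each subtype, Q is uniform over that subtype's
    pseudo-cells and zero elsewhere. RSS = 1 - sqrt(JSD(P, Q)) with the
    configured logarithm base, so identical distributions score 1 and
    disjoint supports score 0.
    """
    labels = labels.reindex(activity.index)
    if labels.isna().any():
        raise ValueError("every pseudo-cell must carry a subtype label")
    subtype_names = sorted(map(str, labels.unique()))
    out = pd.DataFrame(index=activity.columns, columns=subtype_names, dtype=float)
    for regulon in activity.columns:
        col = activity[regulon].to_numpy(dtype=float)
        total = col.sum()
        if total == 0:
            warnings.warn(f"regulon {regulon!r} has all-zero activity; RSS set to 0",
                          stacklevel=2)
            out.loc[regulon] = 0.0
            continue
        P = col / total
        for subtype in subtype_names:
            mask = (labels == subtype).to_numpy()
            Q = mask / mask.sum()
            js_distance = jensenshannon(P, Q, base=cfg.jsd_log_base)
            out.loc[regulon, subtype] = 1.0 - float(min(js_distance, 1.0))
    return out
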