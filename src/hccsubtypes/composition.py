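"""Sample-level subtype composition and intra-/inter-patient heterogeneity.

Each sample is summarized by its (metab, prol, emt) tumor-cell fractions, a
point on the 2-simplex. Samples are grouped into metabolism-dominated and
EMT-dominated cohorts by hierarchical clustering of those fractions, and
heterogeneity is quantified by Euclidean distances between composition
vectors, compared within versus between patients with a two-sided Wilcoxon
rank-sum test (exact enumeration for small inputs).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import mannwhitneyu, rankdata

logger = logging.getLogger(__name__)

SUBTYPES = ("metab", "prol", "emt")
EXACT_ENUMERATION_LIMIT = 20


@dataclass
class DistanceSummary:
    within: np.ndarray
    between: np.ndarray
    within_median: float
    within_range: tuple[float, float]
    between_median: float
    between_range: tuple[float, float]
    p_value: float
    method: str


@dataclass
class CohortGrouping:
    sample_group: pd.Series          # sample -> {Metab-HCC, EMT-HCC}
    group_sizes: dict[str, int]
    emt_proportion: float


def composition_table(cell_subtypes: pd.Series, meta: pd.DataFrame
                      ) -> pd.DataFrame:
    """Per-sample subtype fractions among tumor cells (rows sum to 1).

    Returns a sample x (metab, prol, emt) frame carrying the sample→patient
    map in a ``patient_id`` column; samples without labeled tumor cells are
    excluded with a warning.
    """
    is_tumor = meta.get("cell_class", pd.Series("tumor", index=meta.index)) == "tumor"
    tumor = meta[is_tumor.to_numpy()]
    labels = cell_subtypes.reindex(tumor.index)
    if labels.isna().any():
        raise ValueError("every tumor cell must carry a subtype label")
    counts = pd.crosstab(tumor["sample_id"], labels).reindex(
        columns=list(SUBTYPES), fill_value=0)
    empty = set(meta["sample_id"].unique()) - set(counts.index)
    if empty:
        warnings.warn(f"samples without tumor cells excluded: {sorted(empty)}",
                      stacklevel=2)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    patients = tumor.groupby("sample_id")["patient_id"].first()
    fractions["patient_id"] = patients.reindex(fractions.index)
    return fractions


def group_cohort(comp: pd.DataFrame) -> CohortGrouping:
    """Split samples into Metab-HCC vs EMT-HCC by their composition vectors."""
    if comp.shape[0] < 2:
        raise ValueError("need at least 2 samples to group a cohort")
    vectors = comp[list(SUBTYPES)].to_numpy(dtype=float)
    if np.allclose(vectors, vectors[0], atol=1e-12):
        raise ValueError("no separation: all sample compositions identical")
    Z = sch.linkage(ssd.pdist(vectors, metric="euclidean"), method="average")
    groups = pd.Series(sch.fcluster(Z, t=2, criterion="maxclust"), index=comp.index)
    emt_means = comp["emt"].groupby(groups).mean()
    if emt_means.nunique() == 1:
        raise ValueError("naming error: both groups have equal mean EMT fraction")
    emt_group = emt_means.idxmax()
    named = groups.map(lambda g: "EMT-HCC" if g == emt_group else "Metab-HCC")
    sizes = named.value_counts().to_dict()
    return CohortGrouping(
        sample_group=named.rename("group"),
        group_sizes={k: int(v) for k, v in sizes.items()},
        emt_proportion=sizes.get("EMT-HCC", 0) / len(named),
    )


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Uses average ranks (so ties are handled) and the symmetric tail
    probability P(U <= u_lo) + P(U >= u_hi) of the Mann-Whitney U statistic
    under uniform reassignment of the pooled values.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    observed = ranks[:n1].sum()
    stats = np.fromiter(
        (sum(ranks[list(c)]) for c in itertools.combinations(range(n), n1)),
        dtype=float)
    u_obs = observed - n1 * (n1 + 1) / 2
    u_all = stats - n1 * (n1 + 1) / 2
    mean_u = n1 * (n - n1) / 2
    lo, hi = min(u_obs, 2 * mean_u - u_obs), max(u_obs, 2 * mean_u - u_obs)
    p = np.mean((u_all <= lo + 1e-12) | (u_all >= hi - 1e-12))
    return float(min(p, 1.0))


def ranksum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration when the pooled size is at most 20; otherwise the
    normal approximation with continuity and tie correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= EXACT_ENUMERATION_LIMIT:
        return _exact_ranksum_p(x, y), "exact"
    stat = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                        use_continuity=True)
    return float(stat.pvalue), "normal"


def distance_summary(comp: pd.DataFrame) -> DistanceSummary:
    """Pairwise composition distances split within/between patients, with test."""
    if "patient_id" not in comp.columns:
        raise ValueError("composition table must carry a patient_id column")
    vectors = comp[list(SUBTYPES)].to_numpy(dtype=float)
    patients = comp["patient_id"].to_numpy()
    if len(set(patients)) < 2:
        raise ValueError("need samples from at least 2 patients")
    dists = ssd.squareform(ssd.pdist(vectors, metric="euclidean"))
    within, between = [], []
    n = len(patients)
    for i in range(n):
        for j in range(i + 1, n):
            (within if patients[i] == patients[j] else between).append(dists[i, j])
    if not within:
        raise ValueError("no patient contributes more than one sample")
    within, between = np.asarray(within), np.asarray(between)
    p, method = ranksum_test(within, between)
    return DistanceSummary(
        within=within, between=between,
        within_median=float(np.median(within)),
        within_range=(float(within.min()), float(within.max())),
        between_median=float(np.median(between)),
        between_range=(float(between.min()), float(between.max())),
        p_value=p, method=method,
    )


def _round_half_up(value: float, digits: int = 1) -> float:
    return float(Decimal(repr(float(value))).quantize(Decimal(f"1e-{digits}"),
                                                      rounding=ROUND_HALF_UP))


def mutation_rate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subtype per-gene mutation percentages with raw counts retained.

    Rates are 100 x mutant / total, rounded half-up to one decimal to match
    conventional reporting; returns one row per (subtype, gene).
    """
    gene_cols = [c for c in table.columns if c != "subtype"]
    if not gene_cols:
        raise ValueError("mutation table has no gene flag columns")
    records = []
    for subtype, block in table.groupby("subtype"):
        if block.empty:
            raise ValueError(f"subtype {subtype!r} has no cell lines")
        for gene in gene_cols:
            flags = block[gene].astype(bool)
            records.append({
                "subtype": subtype, "gene": gene,
                "n_mutant": int(flags.sum()), "n_total": int(len(flags)),
                "rate_pct": _round_half_up(100.0 * flags.sum() / len(flags)),
            })
    return pd.DataFrame.from_records(records)
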