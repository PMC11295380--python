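"""QC filtering, normalization, feature selection and tumor-cell subclustering.

The defaults mirror common scRNA-seq practice for tumor atlases: cells with
fewer than 500 detected features or more than 15% mitochondrial counts are
dropped, samples left with fewer than 20 tumor cells are excluded entirely,
expression is depth-normalized to 10k counts and log-transformed, the 2000
most variable genes feed an exact PCA, and subclusters come from Leiden
community detection on a shared-nearest-neighbor graph in PC space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._utils import ConfigError, check_count, check_fraction

logger = logging.getLogger(__name__)

MITO_PREFIXES = ("MT-", "mt-")


@dataclass(frozen=True)
class PreprocessConfig:
    min_features: int = 500
    max_mito_fraction: float = 0.15
    min_tumor_cells_per_sample: int = 20
    n_hvgs: int = 2000
    n_pcs: int = 20
    cluster_resolution: float = 1.0
    snn_neighbors: int = 20
    snn_prune: float = 1 / 15
    zscore_clip: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        check_count(self.min_features, "min_features")
        check_count(self.min_tumor_cells_per_sample, "min_tumor_cells_per_sample")
        check_count(self.n_hvgs, "n_hvgs")
        check_count(self.n_pcs, "n_pcs")
        check_count(self.snn_neighbors, "snn_neighbors", minimum=2)
        check_fraction(self.max_mito_fraction, "max_mito_fraction",
                       lo_open=True, hi_open=True)
        if self.cluster_resolution <= 0:
            raise ConfigError("cluster_resolution must be > 0; "
                              f"got {self.cluster_resolution}")


def _qc_covariates(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    X = sp.csr_matrix(adata.X)
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    is_mito = adata.var_names.str.startswith(MITO_PREFIXES)
    mito = np.asarray(X[:, is_mito].sum(axis=1)).ravel() if is_mito.any() \
        else np.zeros_like(totals)
    frac = np.divide(mito, totals, out=np.zeros_like(totals), where=totals > 0)
    return n_features, frac


def qc_filter(adata: ad.AnnData, cfg: PreprocessConfig = PreprocessConfig()
              ) -> tuple[ad.AnnData, dict]:
    """Drop low-quality cells, then samples with too few surviving tumor cells.

    A cell is removed when it detects fewer than ``min_features`` genes or its
    mitochondrial fraction exceeds ``max_mito_fraction`` (both strict on the
    removal side, so cells sitting exactly on a threshold survive). Samples
    whose surviving tumor-cell count falls below ``min_tumor_cells_per_sample``
    are then excluded wholesale. Returns the filtered view (copied) and a
    report of removals per rule.
    """
    n_features, mito_frac = _qc_covariates(adata)
    low_features = n_features < cfg.min_features
    high_mito = mito_frac > cfg.max_mito_fraction
    keep = ~(low_features | high_mito)

    obs = adata.obs
    is_tumor = (obs.get("cell_class", pd.Series("tumor", index=obs.index)) == "tumor")
    surviving = obs.loc[keep & is_tumor.to_numpy(), "sample_id"].value_counts()
    small = set(surviving[surviving < cfg.min_tumor_cells_per_sample].index)
    small |= set(obs["sample_id"].unique()) - set(surviving.index)
    sample_drop = obs["sample_id"].isin(small).to_numpy()
    keep_final = keep & ~sample_drop

    if not keep_final.any():
        raise ValueError("no cells survive QC")
    out = adata[keep_final].copy()
    out.obs["n_features"] = n_features[keep_final]
    out.obs["mito_fraction"] = mito_frac[keep_final]
    report = {
        "n_input_cells": int(adata.n_obs),
        "n_kept_cells": int(out.n_obs),
        "removed_low_features": int(low_features.sum()),
        "removed_high_mito": int((high_mito & ~low_features).sum()),
        "excluded_samples": sorted(small),
        "removed_in_excluded_samples": int((keep & sample_drop).sum()),
    }
    return out, report


def normalize_log1p_cp10k(adata: ad.AnnData) -> ad.AnnData:
    """Depth-normalize to 10k counts per cell and apply ln(1 + x)."""
    X = sp.csr_matrix(adata.X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    X = sp.diags(1e4 / totals) @ X
    X.data = np.log1p(X.data)
    out = adata.copy()
    out.X = sp.csr_matrix(X)
    return out


def select_hvgs(adata: ad.AnnData, n_hvgs: int) -> list[str]:
    """Rank genes by variance of log-normalized expression; return the top n."""
    if n_hvgs > adata.n_vars:
        raise ValueError(f"n_hvgs ({n_hvgs}) exceeds gene count ({adata.n_vars})")
    X = sp.csr_matrix(adata.X)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean ** 2, 0.0)
    order = np.argsort(-var, kind="stable")
    return adata.var_names[order[:n_hvgs]].tolist()


def pca(adata: ad.AnnData, hvgs: list[str], n_pcs: int,
        zscore_clip: float = 10.0) -> pd.DataFrame:
    """Exact PCA of the centered, unit-scaled (clipped) HVG submatrix."""
    if adata.n_obs < n_pcs:
        raise ValueError(f"n_pcs ({n_pcs}) exceeds cell count ({adata.n_obs})")
    sub = np.asarray(adata[:, hvgs].X.todense(), dtype=np.float64)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = (sub - mean) / np.where(sd > 0, sd, 1.0)
    np.clip(z, -zscore_clip, zscore_clip, out=z)
    model = PCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(z)
    return pd.DataFrame(scores, index=adata.obs_names,
                        columns=[f"PC{i + 1}" for i in range(n_pcs)])


class SNNLeiden(ClusterMixin, BaseEstimator):
    """Leiden community detection on a shared-nearest-neighbor graph.

    The graph uses ``n_neighbors`` Euclidean neighbors (the cell itself
    included), Jaccard overlap of neighbor sets as edge weights, and drops
    edges below ``prune``. Modularity is optimized at the given resolution
    with a seeded Leiden run, so results are deterministic.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster label per observation after :meth:`fit`.
    """

    def __init__(self, n_neighbors: int = 20, resolution: float = 1.0,
                 prune: float = 1 / 15, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.prune = prune
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        k_excl = min(self.n_neighbors - 1, n - 1)  # neighbors besides the cell itself
        nn = NearestNeighbors(n_neighbors=k_excl).fit(X)
        indices = nn.kneighbors(return_distance=False)
        # adjacency of neighbor sets incl. self; SNN = shared-neighbor counts
        rows = np.repeat(np.arange(n), k_excl)
        A = sp.csr_matrix(
            (np.ones(n * k_excl, dtype=np.int32), (rows, indices.ravel())),
            shape=(n, n))
        A = A + sp.eye(n, format="csr", dtype=np.int32)
        shared = (A @ A.T).tocoo()
        union = np.full(n, k_excl + 1)  # every cell has k_excl + 1 neighbors incl. self
        jaccard = shared.data / (union[shared.row] + union[shared.col] - shared.data)
        mask = (jaccard >= self.prune) & (shared.row < shared.col)
        graph = igraph.Graph(
            n=n,
            edges=list(zip(shared.row[mask].tolist(), shared.col[mask].tolist())),
            edge_attrs={"weight": jaccard[mask].tolist()},
        )
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=self.resolution,
            seed=int(self.random_state), n_iterations=2)
        self.labels_ = np.asarray(part.membership)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_graph(pc_scores: pd.DataFrame, resolution: float = 1.0,
                  seed: int = 0, n_neighbors: int = 20,
                  prune: float = 1 / 15) -> pd.Series:
    """Subcluster cells in PC space; returns integer labels indexed by cell."""
    model = SNNLeiden(n_neighbors=n_neighbors, resolution=resolution,
                      prune=prune, random_state=seed)
    labels = model.fit_predict(pc_scores.to_numpy())
    return pd.Series(labels, index=pc_scores.index, name="subcluster")
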