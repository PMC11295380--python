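"""NMF consensus validation of the three-subtype classification.

Tumor cells are downsampled per sample, factorized with k = 3 by
multiplicative-update NMF (squared Frobenius loss), assigned to their
dominant factor, and compared with the similarity-based subtype labels
through a best-matching concordance rate; resampling repeats the whole
procedure to gauge stability.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import ConfigError, check_count, substream

logger = logging.getLogger(__name__)

_EPS = np.finfo(np.float64).eps


@dataclass(frozen=True)
class NMFConfig:
    k: int = 3
    cells_per_sample: int = 50
    n_repeats: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        check_count(self.k, "k", minimum=2)
        check_count(self.cells_per_sample, "cells_per_sample", minimum=self.k)
        check_count(self.n_repeats, "n_repeats")
        check_count(self.max_iter, "max_iter")
        if self.tol <= 0:
            raise ConfigError(f"tol must be > 0; got {self.tol}")


@dataclass
class NMFResult:
    W: pd.DataFrame                # cells x k loadings
    H: pd.DataFrame                # k x genes basis
    loss_trajectory: np.ndarray    # squared Frobenius error per iteration
    metagenes: dict[int, list[str]]


@dataclass
class ConcordanceReport:
    rates: list[float]
    median: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        self.median = float(np.median(self.rates))
        self.min = float(np.min(self.rates))
        self.max = float(np.max(self.rates))


class MultiplicativeNMF(TransformerMixin, BaseEstimator):
    """Non-negative matrix factorization by multiplicative updates.

    Minimizes ``||X - WH||_F^2`` with Lee–Seung updates, recording the loss
    every iteration and stopping once the relative improvement drops below
    ``tol`` or ``max_iter`` is reached. The loss trajectory is checked to be
    non-increasing (tiny relative slack for floating point).

    Attributes
    ----------
    components_ : ndarray (k, n_genes)
        The basis H.
    reconstruction_err_trajectory_ : ndarray
        Squared Frobenius loss after each update sweep.
    """

    def __init__(self, n_components: int = 3, max_iter: int = 500,
                 tol: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if (X < 0).any():
            raise ValueError("NMF input must be elementwise non-negative")
        n, m = X.shape
        k = self.n_components
        if not X.any():
            # all-zero matrix factorizes exactly into zero factors
            self.components_ = np.zeros((k, m))
            self.reconstruction_err_trajectory_ = np.array([0.0])
            self.n_iter_ = 0
            return np.zeros((n, k))

        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(X.mean() / k)
        W = scale * rng.random((n, k)) + _EPS
        H = scale * rng.random((k, m)) + _EPS

        losses = []
        prev = None
        x_norm2 = float(np.linalg.norm(X) ** 2)
        for it in range(self.max_iter):
            H *= (W.T @ X) / (W.T @ W @ H + _EPS)
            W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
            loss = float(np.linalg.norm(X - W @ H) ** 2)
            losses.append(loss)
            if prev is not None:
                # relative slack plus an absolute floor: once the loss reaches
                # the float64 noise floor of ||X||^2, wiggle is round-off
                if loss > prev * (1 + 1e-10) + 1e-12 * x_norm2:
                    raise RuntimeError(
                        f"NMF loss increased at iteration {it}: {prev} -> {loss}")
                if prev > 0 and (prev - loss) / prev < self.tol:
                    break
            prev = loss
        self.components_ = H
        self.reconstruction_err_trajectory_ = np.asarray(losses)
        self.n_iter_ = len(losses)
        return W

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        # least-squares loadings against the frozen basis, projected to >= 0
        W, *_ = np.linalg.lstsq(self.components_.T, np.asarray(X, float).T, rcond=None)
        return np.maximum(W.T, 0.0)


def nmf_factorize(X: pd.DataFrame, cfg: NMFConfig = NMFConfig(),
                  n_metagenes: int = 30) -> NMFResult:
    """Factorize a non-negative expression matrix; report factor metagenes."""
    model = MultiplicativeNMF(n_components=cfg.k, max_iter=cfg.max_iter,
                              tol=cfg.tol, random_state=cfg.seed)
    W = model.fit_transform(X.to_numpy())
    H = model.components_
    metagenes = {
        f: X.columns[np.argsort(-H[f], kind="stable")[:n_metagenes]].tolist()
        for f in range(cfg.k)
    }
    return NMFResult(
        W=pd.DataFrame(W, index=X.index, columns=range(cfg.k)),
        H=pd.DataFrame(H, index=range(cfg.k), columns=X.columns),
        loss_trajectory=model.reconstruction_err_trajectory_,
        metagenes=metagenes,
    )


def downsample_cells(meta: pd.DataFrame, n_per_sample: int, seed: int) -> list[str]:
    """Uniformly draw up to ``n_per_sample`` cells per sample, without replacement."""
    if meta.empty:
        raise ValueError("empty cell metadata")
    rng = substream(seed, "downsample")
    chosen: list[str] = []
    for sample in sorted(meta["sample_id"].unique()):
        ids = meta.index[meta["sample_id"] == sample].to_numpy()
        take = min(n_per_sample, len(ids))
        chosen.extend(rng.choice(ids, size=take, replace=False))
    return chosen


def assign_by_factor(result: NMFResult) -> pd.Series:
    """Label each cell with its argmax factor; ties go to the lowest index."""
    W = result.W.to_numpy()
    labels = W.argmax(axis=1).astype(object)
    sorted_W = np.sort(W, axis=1)
    ties = (W.shape[1] > 1) & (sorted_W[:, -1] == sorted_W[:, -2]) & (sorted_W[:, -1] > 0)
    if np.asarray(ties).any():
        logger.warning("%d cells tie on their top factor; lowest index kept",
                       int(np.sum(ties)))
    labels[~W.any(axis=1)] = "unassigned"
    return pd.Series(labels, index=result.W.index, name="factor")


def concordance(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Best-matching agreement rate between two categorical labelings.

    Classes of one labeling are injectively matched to classes of the other
    by exhaustive search (both sides must have <= 6 classes); the rate is the
    matched agreement count over the shared cells. Cells labeled
    ``"unassigned"`` on either side are excluded from the denominator.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("labelings share no cells")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    keep = (a != "unassigned") & (b != "unassigned")
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no assigned cells in common")
    classes_a = sorted(map(str, a.unique()))
    classes_b = sorted(map(str, b.unique()))
    if len(classes_a) > 6 or len(classes_b) > 6:
        raise ValueError("concordance matching supports at most 6 classes per side")
    table = pd.crosstab(a.astype(str), b.astype(str)).reindex(
        index=classes_a, columns=classes_b, fill_value=0).to_numpy()
    if table.shape[0] > table.shape[1]:
        table = table.T
    best = max(
        sum(table[i, j] for i, j in enumerate(perm))
        for perm in itertools.permutations(range(table.shape[1]), table.shape[0]))
    return best / len(a)


def resample_concordance(expr: pd.DataFrame, meta: pd.DataFrame,
                         subtype_labels: pd.Series,
                         cfg: NMFConfig = NMFConfig(),
                         feature_genes: list[str] | None = None
                         ) -> tuple[ConcordanceReport, list[pd.Series]]:
    """Repeat downsample → factorize → assign → concordance ``n_repeats`` times.

    Repeat ``r`` uses seed ``cfg.seed + r`` for both the resampling and the
    factorization, so individual repeats are reproducible in isolation.
    Returns the concordance summary and the per-repeat factor labels.
    """
    if feature_genes is not None:
        missing = set(feature_genes) - set(expr.columns)
        if missing:
            raise ValueError(f"{len(missing)} feature genes absent from expression")
        expr = expr[list(feature_genes)]
    rates, per_repeat = [], []
    for r in range(cfg.n_repeats):
        cells = downsample_cells(meta, cfg.cells_per_sample, seed=cfg.seed + r)
        sub = expr.loc[cells]
        result = nmf_factorize(
            sub, NMFConfig(k=cfg.k, cells_per_sample=cfg.cells_per_sample,
                           n_repeats=cfg.n_repeats, max_iter=cfg.max_iter,
                           tol=cfg.tol, seed=cfg.seed + r))
        factors = assign_by_factor(result)
        rates.append(concordance(factors, subtype_labels.loc[cells]))
        per_repeat.append(factors)
    return ConcordanceReport(rates=rates), per_repeat
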