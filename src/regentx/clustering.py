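"""Consensus k-means classification of temporal expression profiles.

Significant genes' per-timepoint log2 fold changes are z-scored row-wise and
clustered with Euclidean k-means many times from different random
initializations. Gene pairs co-clustered in at least a support fraction of
runs (default 80 of 100) are linked; the connected components of that link
graph are the consensus temporal classes, and genes whose component is
smaller than a minimum size are reported "unstable". This formalizes
consensus ("k-means support") clustering as pairwise co-clustering evidence.

The estimator follows scikit-learn conventions (fit / labels_ / get_params);
scikit-learn's own KMeans is deliberately not used for the runs — Lloyd's
algorithm with random-point initialization is implemented here so the run
semantics are fully specified — but serves as an independent cross-check in
the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

UNSTABLE = "unstable"


def zscore_rows(lfc: pd.DataFrame, eps: float = 1e-12) -> pd.DataFrame:
    """Row-wise z-scores ((x - mean) / sample sd, ddof=1).

    Rows with (numerically) zero variance carry no temporal shape and are
    excluded, with the dropped ids logged. Requires >= 2 columns.
    """
    if lfc.shape[1] < 2:
        raise ValueError("need at least two time windows")
    mat = lfc.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    constant = sd <= eps
    if constant.any():
        dropped = list(lfc.index[constant])
        logger.info("excluding %d constant rows: %s", len(dropped), dropped[:10])
    keep = ~constant
    z = (mat[keep] - mat[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=lfc.index[keep], columns=lfc.columns)


def kmeans_run(
    Z: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """One k-means run: Lloyd's algorithm, Euclidean distance, centers
    initialized at k distinct data points drawn from ``seed``, iterated to
    convergence (center movement below ``tol``). Within-run inertia never
    increases. Emptied clusters are re-seeded at the point farthest from its
    assigned center."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    rng = np.random.default_rng(seed)
    centers = Z[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centers[j] = Z[members].mean(axis=0)
            else:
                worst = d2[np.arange(n), labels].argmax()
                new_centers[j] = Z[worst]
                labels[worst] = j
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        if shift < tol:
            break
    return labels


def inertia(Z: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to cluster means."""
    total = 0.0
    for j in np.unique(labels):
        pts = Z[labels == j]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


@dataclass
class TemporalClassAssignment:
    """Consensus cluster label (1..n_classes) or "unstable" per gene, with
    the pairwise co-clustering support matrix behind the call."""

    labels: pd.Series  # gene id -> int class or UNSTABLE
    support: pd.DataFrame  # symmetric gene x gene co-clustering frequency
    class_sizes: dict = field(default_factory=dict)

    def stable_genes(self) -> list[str]:
        return [g for g, lab in self.labels.items() if lab != UNSTABLE]


class ConsensusKMeans(BaseEstimator, ClusterMixin):
    """Consensus k-means over repeated random-initialization runs.

    Parameters
    ----------
    n_clusters : number of clusters per k-means run (default 5).
    n_runs : number of runs (default 100); run r uses seed ``random_state + r``.
    n_init : random-point starts per run, keeping the lowest-inertia
        labelling (default 20). A single random-point start of Lloyd's
        algorithm frequently fails to place a center in every well-separated
        cluster, which corrupts the co-clustering evidence; best-of-n
        restarts are the standard remedy.
    support : minimum co-clustering fraction linking two genes (default 0.8).
    min_component_size : components smaller than this are "unstable".
    random_state : master seed.

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of consensus class labels (0-based ints; -1 unstable).
    support_matrix_ : (n, n) co-clustering frequencies in [0, 1].
    n_classes_ : number of consensus components of sufficient size.
    """

    def __init__(
        self,
        n_clusters: int = 5,
        n_runs: int = 100,
        n_init: int = 20,
        support: float = 0.8,
        min_component_size: int = 2,
        random_state: int = 0,
        max_iter: int = 300,
        tol: float = 1e-6,
    ):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.n_init = n_init
        self.support = support
        self.min_component_size = min_component_size
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        co = np.zeros((n, n))
        for r in range(self.n_runs):
            labels, best_inertia = None, np.inf
            for i in range(self.n_init):
                cand = kmeans_run(
                    X, self.n_clusters,
                    seed=self.random_state + r + i * 1_000_003,
                    max_iter=self.max_iter, tol=self.tol,
                )
                w = inertia(X, cand)
                if w < best_inertia:
                    labels, best_inertia = cand, w
            for j in range(self.n_clusters):
                members = np.flatnonzero(labels == j)
                co[np.ix_(members, members)] += 1.0
        co /= self.n_runs
        adjacency = csr_matrix(co >= self.support)
        n_comp, comp = connected_components(adjacency, directed=False)
        sizes = np.bincount(comp, minlength=n_comp)
        labels = np.full(n, -1, dtype=int)
        next_label = 0
        # components ordered by discovery; relabelled compactly, small ones unstable
        for c in range(n_comp):
            if sizes[c] >= self.min_component_size:
                labels[comp == c] = next_label
                next_label += 1
        self.labels_ = labels
        self.support_matrix_ = co
        self.n_classes_ = next_label
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster(
    Z: pd.DataFrame,
    k: int = 5,
    runs: int = 100,
    support: float = 0.80,
    seed: int = 0,
    min_component_size: int = 2,
) -> TemporalClassAssignment:
    """Consensus classification of a z-profile matrix.

    Consensus classes are numbered 1..n by the time of their peak mean
    z-score (earliest-peaking class first); unstable genes get "unstable".
    """
    model = ConsensusKMeans(
        n_clusters=k, n_runs=runs, support=support,
        min_component_size=min_component_size, random_state=seed,
    ).fit(Z.to_numpy())
    raw = model.labels_
    # order classes by peak time of the class-mean profile
    order = []
    for c in range(model.n_classes_):
        mean_profile = Z.to_numpy()[raw == c].mean(axis=0)
        order.append((int(mean_profile.argmax()), -float(mean_profile.max()), c))
    rank = {c: i + 1 for i, (_, _, c) in enumerate(sorted(order))}
    labels = pd.Series(
        [UNSTABLE if c < 0 else rank[c] for c in raw], index=Z.index, name="temporal_class"
    )
    support_df = pd.DataFrame(model.support_matrix_, index=Z.index, columns=Z.index)
    sizes = {rank[c]: int((raw == c).sum()) for c in range(model.n_classes_)}
    return TemporalClassAssignment(labels=labels, support=support_df, class_sizes=sizes)
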