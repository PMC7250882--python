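"""Fuzzy c-means soft clustering of standardized expression profiles.

Each gene receives a membership weight in every cluster rather than a hard
label; "core genes" are those whose top membership clears a threshold.
This is the classic Bezdek alternating-optimization scheme on Euclidean
distances, with a low fuzzifier (m = 1.25) suited to standardized
time-course profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .expression import ExpressionMatrix

__all__ = [
    "SoftClustering",
    "fuzzy_cmeans",
    "assign_clusters",
    "core_genes",
    "peak_condition",
    "cluster_report",
]


@dataclass
class SoftClustering:
    """Result of a fuzzy c-means run.

    ``membership`` is genes x clusters with rows summing to one;
    ``centers`` is clusters x conditions.  Cluster labels are the integers
    1..c.  ``objective`` records J = sum_ij u_ij^m ||x_i - c_j||^2 per
    iteration (non-increasing).
    """

    membership: pd.DataFrame
    centers: pd.DataFrame
    fuzzifier: float
    n_iterations: int
    objective: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        sums = self.membership.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; zero-distance rows get a
    one-hot membership at the first zero-distance cluster."""
    u = np.zeros_like(d2)
    zero = d2 <= 0.0
    has_zero = zero.any(axis=1)
    if has_zero.any():
        first = np.argmax(zero[has_zero], axis=1)
        u[np.flatnonzero(has_zero), first] = 1.0
    rest = ~has_zero
    if rest.any():
        w = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = w / w.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(X: ExpressionMatrix, c: int, m: float = 1.25,
                 tol: float = 1e-6, max_iter: int = 1000,
                 seed: int | None = None) -> SoftClustering:
    """Soft-cluster gene profiles into ``c`` fuzzy clusters.

    Parameters
    ----------
    X
        Standardized expression matrix (genes x conditions).
    c
        Number of clusters (2 <= c < number of genes).
    m
        Fuzzifier, > 1; memberships harden as m -> 1.
    tol
        Convergence threshold on the maximum membership change.
    seed
        Seeds the center initialization (c distinct gene profiles are
        sampled as starting centers).
    """
    data = X.values.to_numpy(dtype=float)
    n_genes = data.shape[0]
    if not np.isfinite(data).all():
        raise ValueError("expression profiles contain non-finite values")
    if c < 2:
        raise ValueError(f"need at least 2 clusters, got {c}")
    if c >= n_genes:
        raise ValueError(f"cluster count {c} must be below gene count {n_genes}")
    if m <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    unique = np.unique(data, axis=0)
    if len(unique) >= c:
        centers = unique[rng.choice(len(unique), size=c, replace=False)].copy()
    else:
        centers = data[rng.choice(n_genes, size=c, replace=False)].copy()

    u = _memberships(cdist(data, centers, "sqeuclidean"), m)
    objective: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u ** m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]
        d2 = cdist(data, centers, "sqeuclidean")
        u_new = _memberships(d2, m)
        objective.append(float((u_new ** m * d2).sum()))
        delta = np.abs(u_new - u).max()
        u = u_new
        if delta < tol:
            break

    labels = list(range(1, c + 1))
    return SoftClustering(
        membership=pd.DataFrame(u, index=X.values.index, columns=labels),
        centers=pd.DataFrame(centers, index=labels, columns=X.values.columns),
        fuzzifier=m,
        n_iterations=n_iter,
        objective=objective,
        seed=seed,
    )


def assign_clusters(sc: SoftClustering) -> pd.Series:
    """Hard assignment: argmax membership; ties go to the lowest label."""
    u = sc.membership.to_numpy()
    idx = np.argmax(u, axis=1)  # first maximum on ties
    labels = np.asarray(sc.membership.columns)[idx]
    return pd.Series(labels, index=sc.membership.index, name="cluster")


def core_genes(sc: SoftClustering, min_membership: float = 0.5) -> dict[int, set[str]]:
    """Per-cluster sets of genes whose top membership is >= the threshold."""
    if not 0 < min_membership <= 1:
        raise ValueError("min_membership must lie in (0, 1]")
    hard = assign_clusters(sc)
    top = sc.membership.max(axis=1)
    out: dict[int, set[str]] = {int(c): set() for c in sc.membership.columns}
    for gene in sc.membership.index[top >= min_membership]:
        out[int(hard[gene])].add(gene)
    return out


def peak_condition(sc: SoftClustering) -> dict[int, str]:
    """Condition at which each cluster center peaks (ties: earliest)."""
    peaks = {}
    cols = np.asarray(sc.centers.columns)
    for c in sc.centers.index:
        peaks[int(c)] = str(cols[int(np.argmax(sc.centers.loc[c].to_numpy()))])
    return peaks


def cluster_report(sc: SoftClustering, min_membership: float = 0.5) -> pd.DataFrame:
    """Per-cluster gene count, core-gene count and peak condition."""
    hard = assign_clusters(sc)
    cores = core_genes(sc, min_membership)
    peaks = peak_condition(sc)
    rows = []
    for c in sc.membership.columns:
        rows.append({
            "cluster": int(c),
            "n_genes": int((hard == c).sum()),
            "n_core": len(cores[int(c)]),
            "peak": peaks[int(c)],
        })
    return pd.DataFrame(rows).set_index("cluster")
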