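"""Weighted co-expression network modules (WGCNA-style), per species.

Pipeline: soft-threshold the gene-gene Pearson correlation into an
adjacency, form the topological overlap measure (TOM), average-linkage
cluster on 1 - TOM and cut the tree statically into labelled modules.
Modules smaller than a minimum size are left unassigned (label 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

__all__ = [
    "CoexprGraph",
    "ModulePartition",
    "adjacency",
    "scale_free_fit",
    "tom_similarity",
    "detect_modules",
]


@dataclass
class CoexprGraph:
    """Soft-thresholded co-expression network over one species' genes."""

    adjacency: np.ndarray  # genes x genes, symmetric, zero diagonal
    genes: list
    beta: float
    signed: bool
    tom: np.ndarray | None = None

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum of adjacencies to every other gene."""
        return self.adjacency.sum(axis=1)


@dataclass
class ModulePartition:
    """gene -> module label (positive integers; 0 = unassigned)."""

    labels: pd.Series
    species: str = ""
    params: dict = field(default_factory=dict)

    def module_genes(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])

    @property
    def module_labels(self) -> list[int]:
        return sorted(int(l) for l in set(self.labels) if l != 0)


def adjacency(em: ExpressionMatrix, beta: float = 6, signed: bool = False) -> CoexprGraph:
    """Soft-threshold adjacency from Pearson correlation across samples.

    Unsigned: ``|r|^beta``; signed: ``((1 + r)/2)^beta``.  The diagonal is
    zeroed (self-adjacency does not count toward connectivity).
    """
    if beta <= 0:
        raise ValueError(f"soft-threshold power must be positive, got {beta}")
    if em.values.shape[1] < 4:
        raise ValueError("adjacency needs at least 4 samples")
    X = em.values.to_numpy(dtype=float)
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = em.genes[int(np.argmax(sds == 0))]
        raise ValueError(f"gene {bad!r} has zero variance; filter before adjacency")
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    a = (a + a.T) / 2.0
    return CoexprGraph(adjacency=a, genes=em.genes, beta=beta, signed=signed)


def scale_free_fit(graph: CoexprGraph, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression (scale-free topology fit).

    Connectivities are binned, empty bins skipped, and the squared
    correlation of log frequency on log mean connectivity returned.
    """
    k = graph.connectivity
    if len(k) < 20:
        raise ValueError("scale-free fit needs at least 20 genes")
    if np.allclose(k, k[0]):
        raise ValueError("all connectivities equal; scale-free fit undefined")
    pos = k[k > 0]
    if len(pos) < 20:
        raise ValueError("too few genes with positive connectivity")
    # logarithmic bins: the unbiased way to estimate a power-law density
    edges = np.geomspace(pos.min(), pos.max(), n_bins + 1)
    which = np.clip(np.digitize(pos, edges[1:-1]), 0, n_bins - 1)
    widths = np.diff(edges)
    logp, logk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = pos[mask].mean()
        density = mask.mean() / widths[b]
        logp.append(np.log10(density))
        logk.append(np.log10(mean_k))
    if len(logk) < 3:
        raise ValueError("too few occupied bins for a regression")
    fit = _st.linregress(logk, logp)
    return float(fit.rvalue ** 2)


def tom_similarity(graph: CoexprGraph) -> CoexprGraph:
    """Fill the topological overlap measure.

    ``t_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_u a_iu a_uj`` over shared neighbours; ``t_ii = 1``.
    A zero denominator (isolated pair) yields ``t_ij = 0``.
    """
    a = graph.adjacency
    k = graph.connectivity
    L = a @ a  # zero diagonal of a excludes u = i and u = j automatically
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (L + a) / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return CoexprGraph(adjacency=a, genes=graph.genes, beta=graph.beta,
                       signed=graph.signed, tom=t)


def detect_modules(graph: CoexprGraph, cut_height_fraction: float = 0.9,
                   min_size: int = 10, species: str = "") -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a static cut.

    The dendrogram is cut at ``cut_height_fraction`` times the maximum merge
    height; clusters smaller than ``min_size`` become label 0.  Surviving
    modules are relabelled 1, 2, ... by decreasing size (ties by first
    gene appearance).
    """
    if graph.tom is None:
        raise ValueError("compute tom_similarity before module detection")
    genes = graph.genes
    params = {"beta": graph.beta, "signed": graph.signed,
              "cut_height_fraction": cut_height_fraction, "min_size": min_size}
    if len(genes) < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned", stacklevel=2)
        return ModulePartition(pd.Series(0, index=genes), species, params)
    d = 1.0 - graph.tom
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(np.clip(d, 0, None), checks=False),
                          method="average")
    cut = cut_height_fraction * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    # order surviving clusters by decreasing size, then first appearance
    first_pos = {c: int(np.argmax(raw == c)) for c in sizes.index}
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    keep.sort(key=lambda c: (-sizes[c], first_pos[c]))
    relabel = {c: i + 1 for i, c in enumerate(keep)}
    out = labels.map(lambda c: relabel.get(c, 0)).astype(int)
    return ModulePartition(out, species, params)


def choose_beta(em: ExpressionMatrix, candidates=(2, 4, 6, 8, 10, 12),
                target_r2: float = 0.8, signed: bool = False) -> float:
    """Smallest candidate power whose scale-free fit R^2 reaches the target;
    falls back to the best-fitting candidate if none does."""
    best, best_r2 = candidates[0], -1.0
    for b in candidates:
        try:
            r2 = scale_free_fit(adjacency(em, beta=b, signed=signed))
        except ValueError:
            continue
        if r2 >= target_r2:
            return float(b)
        if r2 > best_r2:
            best, best_r2 = b, r2
    return float(best)
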