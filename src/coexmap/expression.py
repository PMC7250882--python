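"""Expression-matrix data model, cRPKM normalization and sample clustering.

The central container is :class:`ExpressionMatrix`: a genes x samples table
with per-sample condition (tissue or stage) and replicate annotations and a
unit tag.  Raw counts are normalized to cRPKM -- reads per kilobase of
uniquely mappable positions per million mapped reads -- using per-gene
effective lengths; mapped-read totals are the per-sample column sums of the
count matrix, so normalization is self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "compute_crpkm",
    "average_replicates",
    "filter_by_cv",
    "standardize_genes",
    "cluster_samples",
]

#: unit tags for which negative values are forbidden
_NONNEG_UNITS = ("counts", "cRPKM")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    condition
        Series mapping each sample to its condition label (tissue or stage).
    replicate
        Series mapping each sample to a replicate index.  Defaults to 1.
    unit
        ``"counts"``, ``"cRPKM"`` or ``"zscore"`` (standardized profiles).
    """

    values: pd.DataFrame
    condition: pd.Series
    replicate: pd.Series | None = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.replicate is None:
            self.replicate = pd.Series(1, index=self.values.columns)
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        missing = [s for s in cols if s not in self.condition.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.condition = self.condition.reindex(cols)
        self.replicate = self.replicate.reindex(cols).fillna(1).astype(int)
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("expression matrix contains missing values")
        if self.unit in _NONNEG_UNITS and (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (metadata) order."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.condition[s], None)
        return list(seen)

    def copy_with(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        cond = self.condition.reindex(values.columns)
        rep = self.replicate.reindex(values.columns)
        return ExpressionMatrix(values, cond, rep, unit or self.unit)


def _parse_sample_name(name: str) -> tuple[str, int]:
    """``condition.replicate`` convention; no dot means single replicate."""
    if "." in name:
        cond, _, rep = name.rpartition(".")
        try:
            return cond, int(rep)
        except ValueError:
            pass
    return name, 1


def read_expression_tsv(path: str | Path, metadata: str | Path | None = None,
                        unit: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV (header of sample names, first column genes).

    Condition labels come from a sidecar metadata TSV with columns
    ``sample``, ``condition``, ``replicate`` or, failing that, from the
    ``condition.replicate`` sample-name convention.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: ragged or missing values at gene row {bad!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene row {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype={"sample": str})
        meta = meta.set_index("sample")
        cond = meta["condition"].astype(str)
        rep = meta["replicate"].astype(int) if "replicate" in meta else None
    else:
        parsed = [_parse_sample_name(s) for s in df.columns]
        cond = pd.Series([c for c, _ in parsed], index=df.columns)
        rep = pd.Series([r for _, r in parsed], index=df.columns)
    return ExpressionMatrix(df, cond, rep, unit)


def write_expression_tsv(em: ExpressionMatrix, path: str | Path,
                         metadata_path: str | Path | None = None) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene")
    if metadata_path is not None:
        meta = pd.DataFrame({
            "sample": em.samples,
            "condition": em.condition.values,
            "replicate": em.replicate.values,
        })
        meta.to_csv(metadata_path, sep="\t", index=False)


def compute_crpkm(em: ExpressionMatrix, lengths_kb: pd.Series) -> ExpressionMatrix:
    """Normalize raw counts to cRPKM.

    ``crpkm(g, s) = count(g, s) / (length_kb(g) * mapped(s) / 1e6)`` where
    ``mapped(s)`` is the column sum of the count matrix.
    """
    if em.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {em.unit!r}")
    missing = [g for g in em.genes if g not in lengths_kb.index]
    if missing:
        raise ValueError(f"genes missing from lengths: {missing[:5]}")
    lens = lengths_kb.reindex(em.values.index).astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise ValueError(f"non-positive effective length for gene {bad!r}")
    totals = em.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    vals = em.values.div(lens, axis=0).div(totals / 1e6, axis=1)
    return em.copy_with(vals, unit="cRPKM")


def average_replicates(em: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate columns to one column per condition (arithmetic mean).

    Output columns follow the condition order of the sample metadata.
    """
    conds = em.conditions
    cols = {}
    for c in conds:
        members = [s for s in em.samples if em.condition[s] == c]
        cols[c] = em.values[members].mean(axis=1)
    vals = pd.DataFrame(cols)[conds]
    cond = pd.Series(conds, index=conds)
    rep = pd.Series(1, index=conds)
    return ExpressionMatrix(vals, cond, rep, em.unit)


def filter_by_cv(em: ExpressionMatrix, min_cv: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose coefficient of variation (sd/mean, sd with n-1
    denominator) across samples is at least ``min_cv``; zero-mean genes drop."""
    if em.values.shape[1] < 2:
        raise ValueError("coefficient of variation needs at least 2 samples")
    mean = em.values.mean(axis=1)
    sd = em.values.std(axis=1, ddof=1)
    keep = (mean > 0) & (sd / mean.where(mean > 0) >= min_cv)
    return em.copy_with(em.values.loc[keep])


def standardize_genes(em: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, sd 1 (n-1 denominator).

    Rows with zero variance carry no profile information and are dropped
    with a warning.
    """
    if em.values.shape[1] < 2:
        raise ValueError("standardization needs at least 2 columns")
    mean = em.values.mean(axis=1)
    sd = em.values.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} constant gene rows before standardization",
            stacklevel=2,
        )
    vals = em.values.loc[~flat]
    vals = vals.sub(mean[~flat], axis=0).div(sd[~flat], axis=0)
    return em.copy_with(vals, unit="zscore")


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        la = node(int(a))
        lb = node(int(b))
        ba = h - height[int(a)]
        bb = h - height[int(b)]
        height[i] = h
        return f"({la}:{ba:.6g},{lb}:{bb:.6g})"

    for i in range(len(Z)):
        height[n + i] = Z[i, 2]
    return node(n + len(Z) - 1) + ";"


def cluster_samples(em: ExpressionMatrix, log_transform: bool = True,
                    method: str = "average") -> str:
    """Hierarchically cluster samples on 1 - Pearson correlation.

    By default expression is log10(x+1)-transformed first (variance
    stabilization for cRPKM).  Returns a Newick string over the sample
    labels with merge heights as branch lengths; ties break by input order
    (scipy linkage is deterministic for a fixed input ordering).
    """
    if em.values.shape[1] < 3:
        raise ValueError("sample clustering needs at least 3 samples")
    X = em.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log10(X + 1.0)
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = em.samples[int(np.argmax(sds == 0))]
        raise ValueError(f"sample {bad!r} has zero variance; correlation undefined")
    r = np.corrcoef(X.T)
    D = 1.0 - r
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    return _linkage_to_newick(Z, em.samples)
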