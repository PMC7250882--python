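"""Tau tissue specificity, the shared-tissue filter and flat enrichment.

The tau index summarizes how restricted a gene's expression is across
conditions: 0 for perfectly uniform expression, 1 when a single condition
carries all the signal.  The shared-tissue filter asks, for genes highly
expressed in a focal tissue (e.g. developing wing pads), which *second*
tissue co-expresses them: the focal and second tissue form a "test group"
that must clear a minimum expression and stand out from every other tissue
by a relative margin.  Enrichment of gene sets (GO-style terms, planted
module labels, phylostrata) uses two-sided Fisher's exact tests on flat
term-to-gene maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .orthology import PhylostratumAssignment
from .stats import benjamini_hochberg, fisher_two_sided

__all__ = [
    "tau",
    "tau_table",
    "specific_genes",
    "SharedTissueResult",
    "shared_tissue_genes",
    "enrich_terms",
    "enrich_phylostrata",
    "read_gmt",
    "write_gmt",
]


def tau(x) -> float:
    """Tissue-specificity index: sum(1 - x_i/max(x)) / (n - 1).

    ``x`` is a non-negative expression vector over n >= 2 conditions
    (replicates averaged upstream).  Returns NaN when max(x) = 0 (tau is
    undefined for an unexpressed gene).

    >>> tau([10, 5, 0, 0])
    0.8333333333333334
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a vector over at least 2 conditions")
    if (x < 0).any():
        raise ValueError("tau is defined for non-negative expression only")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def tau_table(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tau, peak condition and specificity over a condition-averaged
    matrix.  Columns: ``tau`` (NaN if unexpressed), ``peak``."""
    vals = em.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("tau needs at least 2 conditions")
    taus = [tau(row) for row in vals]
    peaks = [em.samples[int(np.argmax(row))] for row in vals]
    return pd.DataFrame({"tau": taus, "peak": peaks}, index=em.values.index)


def specific_genes(em: ExpressionMatrix, threshold: float = 0.8) -> pd.DataFrame:
    """Genes with tau strictly above ``threshold``, annotated with their
    argmax condition."""
    tt = tau_table(em)
    return tt[tt["tau"] > threshold]


@dataclass
class SharedTissueResult:
    """Outcome of the shared-tissue filter for one focal condition."""

    focal: str
    table: pd.DataFrame  # gene, second, test_min, passes
    counts: pd.Series    # second condition -> number of passing genes

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]


def shared_tissue_genes(em: ExpressionMatrix, focal: str = "wing_pad",
                        min_expr: float = 20.0, margin: float = 0.30) -> SharedTissueResult:
    """Genes preferentially expressed in the focal tissue plus one other.

    For each gene the *second* condition is its highest-expressed non-focal
    condition; the test group is {focal, second}.  A gene passes iff the
    test-group minimum is >= ``min_expr`` and every remaining condition is
    at most ``(1 - margin)`` times that minimum.  The result tabulates
    passing genes per second condition.
    """
    if focal not in em.samples:
        raise KeyError(f"focal condition {focal!r} not in matrix")
    others = [c for c in em.samples if c != focal]
    if len(others) < 2:
        raise ValueError("need at least two non-focal conditions")
    rows = []
    for g in em.genes:
        x = em.values.loc[g]
        second = max(others, key=lambda c: (x[c], -others.index(c)))
        test_min = min(x[focal], x[second])
        rest = [c for c in others if c != second]
        ok = test_min >= min_expr and all(x[c] <= (1.0 - margin) * test_min
                                          for c in rest)
        rows.append({"gene": g, "second": second,
                     "test_min": float(test_min), "passes": bool(ok)})
    table = pd.DataFrame(rows).set_index("gene")
    counts = (table.loc[table["passes"], "second"]
              .value_counts().rename_axis("second").rename("n_genes"))
    return SharedTissueResult(focal=focal, table=table, counts=counts)


def enrich_terms(subset, background, term_sets: dict[str, set]) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of each term in a gene subset.

    Per term T with subset S and background B: a = |S n T|, b = |S| - a,
    c = |T| - a, d = |B| - |T| - b (terms restricted to the background).
    Raw p-values are reported alongside Benjamini-Hochberg adjusted ones.
    """
    S = set(subset)
    B = set(background)
    if not S <= B:
        raise ValueError("subset must be contained in the background")
    rows = []
    for term, genes in term_sets.items():
        T = set(genes) & B
        a = len(S & T)
        b = len(S) - a
        c = len(T) - a
        d = len(B) - len(T) - b
        rows.append({"term": term, "subset_in": a, "subset_out": b,
                     "rest_in": c, "rest_out": d,
                     "p_raw": fisher_two_sided(a, b, c, d)})
    df = pd.DataFrame(rows).set_index("term")
    if len(df):
        df["p_bh"] = benjamini_hochberg(df["p_raw"].to_numpy())
    return df


def enrich_phylostrata(subset, background,
                       assignment: PhylostratumAssignment) -> pd.DataFrame:
    """Per-stratum two-sided Fisher's exact test of the subset's age profile
    against the background's, strata encoded as flat terms."""
    strata = assignment.strata
    missing = [g for g in set(subset) | set(background) if g not in strata.index]
    if missing:
        raise ValueError(f"genes without a phylostratum: {missing[:5]}")
    terms = {s: set(strata.index[strata == s])
             for s in range(1, assignment.n_strata + 1)}
    df = enrich_terms(subset, background, terms)
    df.index.name = "stratum"
    return df


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file: one term per line, tab-separated name, description,
    then gene IDs."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 fields")
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def write_gmt(term_sets: dict[str, set], path, description: str = "coexmap") -> None:
    with open(path, "w") as fh:
        for term, genes in term_sets.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")
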