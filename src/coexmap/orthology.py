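"""Orthogroup tables, species trees, phylostratigraphy and gene gains.

Orthogroups (gene families descending from a single ancestral gene) mediate
every cross-species comparison in the pipeline.  Tables follow the
OrthoFinder ``Orthogroups.tsv`` dialect: first column orthogroup ID, one
column per species, cells holding ", "-joined gene lists.  A rooted species
tree assigns each focal-species gene a phylostratum -- the node on the
root-to-focal path at which its family first appears -- and per-node counts
of family gains and "core" gains (families retained in every sampled
descendant leaf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "OrthogroupTable",
    "SpeciesTree",
    "PhylostratumAssignment",
    "read_orthogroups",
    "write_orthogroups",
    "filter_min_species",
    "assign_phylostrata",
    "count_gains",
]


@dataclass
class OrthogroupTable:
    """orthogroup ID -> {species -> tuple of gene IDs}."""

    groups: dict[str, dict[str, tuple[str, ...]]]
    species: list[str]

    #: gene -> orthogroup ID, built on construction
    gene_index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        for og, cells in self.groups.items():
            if not any(cells.get(s) for s in self.species):
                raise ValueError(f"orthogroup {og!r} is empty in every species")
            for sp, genes in cells.items():
                for g in genes:
                    if g in index:
                        raise ValueError(
                            f"gene {g!r} occurs in both {index[g]!r} and {og!r}"
                        )
                    index[g] = og
        self.gene_index = index

    def genes(self, species: str) -> list[str]:
        if species not in self.species:
            raise KeyError(f"species {species!r} not in orthogroup table")
        out = []
        for cells in self.groups.values():
            out.extend(cells.get(species, ()))
        return out

    def orthogroup_of(self, gene: str) -> str | None:
        return self.gene_index.get(gene)

    def species_present(self, og: str) -> set[str]:
        return {s for s, genes in self.groups[og].items() if genes}

    def __len__(self) -> int:
        return len(self.groups)


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Parse an OrthoFinder-dialect ``Orthogroups.tsv`` file."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    species = list(df.columns[1:])
    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    for _, row in df.iterrows():
        og = row[og_col]
        cells = {}
        for sp in species:
            cell = row[sp].strip()
            cells[sp] = tuple(g.strip() for g in cell.split(",") if g.strip()) if cell else ()
        groups[og] = cells
    return OrthogroupTable(groups, species)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    rows = []
    for og, cells in table.groups.items():
        row = {"Orthogroup": og}
        for sp in table.species:
            row[sp] = ", ".join(cells.get(sp, ()))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path, sep="\t", index=False)


def filter_min_species(table: OrthogroupTable, k: int = 2) -> OrthogroupTable:
    """Keep orthogroups with members in at least ``k`` species."""
    if k < 1:
        raise ValueError("k must be at least 1")
    kept = {og: cells for og, cells in table.groups.items()
            if len(table.species_present(og)) >= k}
    return OrthogroupTable(kept, list(table.species))


class SpeciesTree:
    """Rooted species tree with labelled internal nodes.

    Unlabelled internal nodes are auto-labelled ``N1``, ``N2``, ... in
    preorder so that phylostrata and gain counts can refer to them stably.
    """

    def __init__(self, newick: str):
        self._tree = dendropy.Tree.get(data=newick, schema="newick",
                                       preserve_underscores=True)
        self._tree.is_rooted = True
        n = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                node._cx_label = node.taxon.label
            elif node.label:
                node._cx_label = node.label
            else:
                n += 1
                node._cx_label = f"N{n}"
        self._by_label = {nd._cx_label: nd for nd in self._tree.preorder_node_iter()}
        self._leafset = {
            nd._cx_label: frozenset(l.taxon.label for l in nd.leaf_iter())
            for nd in self._tree.preorder_node_iter()
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls(Path(path).read_text())

    @property
    def leaves(self) -> set[str]:
        return set(self._leafset[self.root])

    @property
    def root(self) -> str:
        return self._tree.seed_node._cx_label

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_set(self, label: str) -> frozenset[str]:
        return self._leafset[label]

    def lineage(self, focal: str) -> list[str]:
        """Node labels on the root -> focal path, root first, leaf last."""
        if focal not in self.leaves:
            raise KeyError(f"{focal!r} is not a leaf of the tree")
        node = self._by_label[focal]
        path = []
        while node is not None:
            path.append(node._cx_label)
            node = node.parent_node
        return path[::-1]

    def mrca(self, species: set[str]) -> str:
        """Label of the most recent common ancestor of the given leaves."""
        unknown = set(species) - self.leaves
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(species) == 1:
            return next(iter(species))
        node = self._tree.mrca(taxon_labels=sorted(species))
        return node._cx_label


@dataclass
class PhylostratumAssignment:
    """Per-gene phylostratum of the focal species.

    Stratum 1 is the root (oldest); stratum S the focal leaf
    (species-specific).  ``node_of_stratum`` maps stratum index to the tree
    node label.
    """

    strata: pd.Series  # gene -> stratum index
    node_of_stratum: dict[int, str]
    focal: str

    @property
    def n_strata(self) -> int:
        return len(self.node_of_stratum)


def assign_phylostrata(table: OrthogroupTable, tree: SpeciesTree, focal: str,
                       genes: list[str] | None = None) -> PhylostratumAssignment:
    """Assign each focal-species gene the stratum of its family's origin.

    The origin node of a gene's orthogroup is the MRCA of the focal species
    and every species with a member; genes without an orthogroup (or in
    focal-only orthogroups) are species-specific (youngest stratum).
    ``genes`` may extend the focal gene list with singletons absent from the
    table.
    """
    path = tree.lineage(focal)
    index_of = {label: i + 1 for i, label in enumerate(path)}
    S = len(path)
    unknown = set(table.species) - tree.leaves
    if unknown:
        raise KeyError(f"orthogroup species missing from tree: {sorted(unknown)}")
    focal_genes = table.genes(focal)
    if genes is not None:
        extra = [g for g in genes if g not in table.gene_index]
        focal_genes = list(focal_genes) + extra
    strata = {}
    og_stratum: dict[str, int] = {}
    for g in focal_genes:
        og = table.orthogroup_of(g)
        if og is None:
            strata[g] = S
            continue
        if og not in og_stratum:
            present = table.species_present(og) | {focal}
            og_stratum[og] = index_of[tree.mrca(present)]
        strata[g] = og_stratum[og]
    node_of = {i + 1: label for i, label in enumerate(path)}
    return PhylostratumAssignment(pd.Series(strata, name="stratum"), node_of, focal)


def count_gains(table: OrthogroupTable, tree: SpeciesTree) -> pd.DataFrame:
    """Per-node orthogroup gains and core gains.

    A family is gained at the MRCA of its member species; it is a *core*
    gain if every sampled leaf descending from that node retains a member.
    Returns a DataFrame indexed by node label with columns ``gains`` and
    ``core_gains``; every orthogroup contributes to exactly one node.
    """
    gains: dict[str, int] = {}
    core: dict[str, int] = {}
    for og in table.groups:
        present = table.species_present(og)
        node = tree.mrca(present)
        gains[node] = gains.get(node, 0) + 1
        if tree.leaf_set(node) <= present:
            core[node] = core.get(node, 0) + 1
    rows = [{"node": n, "gains": gains.get(n, 0), "core_gains": core.get(n, 0)}
            for n in sorted(gains)]
    return pd.DataFrame(rows).set_index("node") if rows else pd.DataFrame(
        columns=["gains", "core_gains"])
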