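"""Cross-species module conservation via orthogroup overlap.

Each species' co-expression modules are mapped into orthogroup space (one
vote per family, collapsing lineage-specific duplicates) and every module
pair across two species is scored by an upper-tail hypergeometric test on
the shared families.  The universe is the set of orthogroups represented in
both species' analysed gene sets, so the test conditions on what could have
been drawn.  Shared "core" gene sets expand the overlapping families back
to per-species gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .modules import ModulePartition
from .orthology import OrthogroupTable
from .stats import benjamini_hochberg, hypergeom_upper_tail

__all__ = ["OverlapResult", "module_to_orthogroups", "overlap_matrix", "conserved_core"]

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """All module-pair overlap statistics for one species pair.

    ``p`` and ``x`` are modules_A x modules_B DataFrames of raw upper-tail
    hypergeometric p-values and overlap counts; ``shared`` maps each module
    pair to the sorted list of shared orthogroup IDs.  ``module_sizes_*``
    give each module's orthogroup count within the universe.
    """

    species_a: str
    species_b: str
    universe: int
    p: pd.DataFrame
    x: pd.DataFrame
    module_sizes_a: dict[int, int]
    module_sizes_b: dict[int, int]
    shared: dict[tuple[int, int], list[str]] = field(default_factory=dict)

    def transpose(self) -> "OverlapResult":
        return OverlapResult(
            species_a=self.species_b, species_b=self.species_a,
            universe=self.universe, p=self.p.T.copy(), x=self.x.T.copy(),
            module_sizes_a=dict(self.module_sizes_b),
            module_sizes_b=dict(self.module_sizes_a),
            shared={(b, a): ogs for (a, b), ogs in self.shared.items()},
        )

    def to_long(self, adjusted: bool = False) -> pd.DataFrame:
        """Long-format table: module_A, module_B, K, n, x, N, p_raw[, p_bh]."""
        rows = []
        for ma in self.p.index:
            for mb in self.p.columns:
                rows.append({
                    "module_a": ma, "module_b": mb,
                    "K": self.module_sizes_a[ma], "n": self.module_sizes_b[mb],
                    "x": int(self.x.loc[ma, mb]), "N": self.universe,
                    "p_raw": float(self.p.loc[ma, mb]),
                })
        df = pd.DataFrame(rows)
        if adjusted and len(df):
            df["p_bh"] = benjamini_hochberg(df["p_raw"].to_numpy())
        return df


def module_to_orthogroups(partition: ModulePartition, table: OrthogroupTable,
                          species: str) -> dict[int, set[str]]:
    """Map each module (label > 0) to the set of orthogroups of its genes.

    Multi-gene families collapse to a single orthogroup.  Genes absent from
    the table are dropped (count logged).
    """
    if species not in table.species:
        raise KeyError(f"species {species!r} not in orthogroup table")
    out: dict[int, set[str]] = {}
    dropped = 0
    for label in partition.module_labels:
        ogs = set()
        for g in partition.module_genes(label):
            og = table.orthogroup_of(g)
            if og is None:
                dropped += 1
            else:
                ogs.add(og)
        out[label] = ogs
    if dropped:
        logger.info("%d module genes of %s absent from the orthogroup table",
                    dropped, species)
    return out


def _analysed_orthogroups(partition: ModulePartition, table: OrthogroupTable) -> set[str]:
    """Orthogroups touched by any analysed gene (unassigned label 0 included)."""
    ogs = set()
    for g in partition.labels.index:
        og = table.orthogroup_of(g)
        if og is not None:
            ogs.add(og)
    return ogs


def overlap_matrix(part_a: ModulePartition, part_b: ModulePartition,
                   table: OrthogroupTable, species_a: str | None = None,
                   species_b: str | None = None) -> OverlapResult:
    """Score every cross-species module pair by hypergeometric overlap.

    The universe N is the set of orthogroups with at least one analysed gene
    in each species; module orthogroup sets are restricted to it.  Label 0
    (unassigned) contributes to the universe but is not tested.
    """
    sp_a = species_a or part_a.species
    sp_b = species_b or part_b.species
    ogs_a = _analysed_orthogroups(part_a, table)
    ogs_b = _analysed_orthogroups(part_b, table)
    universe = ogs_a & ogs_b
    if not universe:
        raise ValueError(
            f"no orthogroups shared between analysed gene sets of {sp_a!r} and {sp_b!r}")
    N = len(universe)
    mods_a = {m: s & universe for m, s in
              module_to_orthogroups(part_a, table, sp_a).items()}
    mods_b = {m: s & universe for m, s in
              module_to_orthogroups(part_b, table, sp_b).items()}
    la, lb = sorted(mods_a), sorted(mods_b)
    p = pd.DataFrame(index=la, columns=lb, dtype=float)
    x = pd.DataFrame(index=la, columns=lb, dtype=int)
    shared: dict[tuple[int, int], list[str]] = {}
    for ma in la:
        for mb in lb:
            inter = mods_a[ma] & mods_b[mb]
            shared[(ma, mb)] = sorted(inter)
            x.loc[ma, mb] = len(inter)
            p.loc[ma, mb] = hypergeom_upper_tail(
                len(inter), N, len(mods_a[ma]), len(mods_b[mb]))
    return OverlapResult(
        species_a=sp_a, species_b=sp_b, universe=N, p=p, x=x,
        module_sizes_a={m: len(s) for m, s in mods_a.items()},
        module_sizes_b={m: len(s) for m, s in mods_b.items()},
        shared=shared,
    )


def conserved_core(ogs_a: set[str], ogs_b: set[str], table: OrthogroupTable,
                   species_a: str, species_b: str) -> tuple[list[str], dict[str, list[str]]]:
    """Shared orthogroups of two mapped modules, expanded to per-species genes.

    One family may expand to unequal gene counts per species (paralogs), so
    the per-species gene lists can be longer than the family list.
    """
    shared = sorted(ogs_a & ogs_b)
    genes = {species_a: [], species_b: []}
    for og in shared:
        genes[species_a].extend(table.groups[og].get(species_a, ()))
        genes[species_b].extend(table.groups[og].get(species_b, ()))
    return shared, genes
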