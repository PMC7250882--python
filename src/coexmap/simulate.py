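"""Synthetic multi-species expression datasets with planted structure.

The generator emulates the statistical shape of a multi-stage/multi-tissue
bulk RNA-seq study across related species: co-regulated gene modules whose
orthogroups are partially shared across species, tissue-restricted genes
for tau testing, an orthogroup table with a tree-node origin for every
family (so phylostrata have a ground truth), log-normal baselines,
log-scale Gaussian replicate noise, and Poisson count sampling at a fixed
library size.  Every planted feature is recorded in a ground-truth table so
downstream recovery can be scored without external data.

Counts are drawn by Poisson thinning of expected expression to the library
size, which makes cRPKM normalization meaningful; with ``noise_sd = 0`` the
generator degenerates to deterministic rounded counts so that zero-noise
datasets make downstream recoveries exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_expression_tsv
from .orthology import OrthogroupTable, SpeciesTree, write_orthogroups
from .specificity import write_gmt

__all__ = [
    "PlantedModule",
    "PlantedSpecific",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_timecourse",
    "write_fixture",
    "default_tree",
]


@dataclass(frozen=True)
class PlantedModule:
    """A co-expression module planted in every species.

    ``peak`` lists the condition(s) in which member genes are up-regulated;
    ``ortho_fraction`` (phi) is the fraction of member genes whose
    orthogroup is shared by all species' partner modules; ``effect`` is the
    log-scale up-regulation at the peak condition(s).
    """

    size: int = 40
    peak: tuple[str, ...] = ("gill",)
    ortho_fraction: float = 0.8
    effect: float = 3.0


@dataclass(frozen=True)
class PlantedSpecific:
    """Tissue-restricted genes planted per species for tau testing."""

    n_genes: int = 10
    tissue: str = "gill"


def default_tree(species: tuple[str, ...]) -> str:
    """Ladder topology over the species list, e.g. ``((A,B),C);``."""
    if len(species) == 1:
        return f"{species[0]};"
    nwk = f"({species[0]},{species[1]})"
    for s in species[2:]:
        nwk = f"({nwk},{s})"
    return nwk + ";"


@dataclass
class SimulationConfig:
    """Conditions of the synthetic study.

    Defaults describe a two-species design with eight tissues/stages, two
    replicates, four planted module pairs of 40 genes sharing 80% of their
    orthogroups, thirty planted tissue-specific genes per species and
    log-scale replicate noise of 0.3.  One module peaks jointly in wing pads
    and gills so that those two samples share a co-expression programme.
    """

    seed: int = 0
    species: tuple[str, ...] = ("spA", "spB")
    tree_newick: str | None = None
    n_orthogroups: int = 400
    p_single_copy: float = 0.5
    retention_prob: float = 0.8
    paralog_prob: float = 0.1
    tissues: tuple[str, ...] = ("wing_pad", "gill", "gut", "brain",
                                "muscle", "malpighian", "ovary", "head")
    n_replicates: int = 2
    planted_modules: tuple[PlantedModule, ...] = (
        PlantedModule(40, ("wing_pad", "gill"), 0.8, 3.0),
        PlantedModule(40, ("gut",), 0.8, 3.0),
        PlantedModule(40, ("brain",), 0.8, 3.0),
        PlantedModule(40, ("muscle",), 0.8, 3.0),
    )
    planted_specific: tuple[PlantedSpecific, ...] = (
        PlantedSpecific(10, "gill"),
        PlantedSpecific(10, "brain"),
        PlantedSpecific(10, "ovary"),
    )
    noise_sd: float = 0.3
    baseline_loc: float = 2.0
    baseline_scale: float = 1.0
    library_size: int = 2_000_000
    length_kb_range: tuple[float, float] = (0.5, 3.0)
    off_target_fraction: float = 0.02

    def validate(self) -> None:
        if self.n_orthogroups <= 0 or self.n_replicates <= 0 or self.library_size <= 0:
            raise ValueError("counts in the configuration must be positive")
        for p, name in ((self.p_single_copy, "p_single_copy"),
                        (self.retention_prob, "retention_prob"),
                        (self.paralog_prob, "paralog_prob")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 conditions")
        for m in self.planted_modules:
            if m.size <= 0:
                raise ValueError("planted module sizes must be positive")
            if not 0 <= m.ortho_fraction <= 1:
                raise ValueError("ortho_fraction must lie in [0, 1]")
            unknown = set(m.peak) - set(self.tissues)
            if unknown:
                raise ValueError(f"module peak conditions not in tissues: {unknown}")
        for s in self.planted_specific:
            if s.tissue not in self.tissues:
                raise ValueError(f"specific tissue {s.tissue!r} not in tissues")
        if self._planted_og_demand() > self.n_orthogroups:
            raise ValueError(
                f"planted modules and specific genes require "
                f"{self._planted_og_demand()} orthogroups but only "
                f"{self.n_orthogroups} were configured")

    def _planted_og_demand(self) -> int:
        k = len(self.species)
        demand = 0
        for m in self.planted_modules:
            n_shared = round(m.ortho_fraction * m.size)
            demand += n_shared + k * (m.size - n_shared)
        demand += k * sum(s.n_genes for s in self.planted_specific)
        return demand


@dataclass
class GroundTruth:
    """Planted-feature tables emitted alongside each simulated dataset."""

    modules: dict[str, pd.Series]        # species -> gene -> label ('' = none)
    specific: dict[str, pd.Series]       # species -> gene -> tissue ('' = none)
    og_origin: pd.Series                 # orthogroup -> origin node label
    module_pairs: list[tuple[str, str, str, str]]  # (sp_a, label, sp_b, label)


@dataclass
class SimulatedDataset:
    expression: dict[str, ExpressionMatrix]   # per-species raw counts
    lengths: dict[str, pd.Series]             # per-species effective kb
    orthogroups: OrthogroupTable
    tree: SpeciesTree
    truth: GroundTruth
    config: SimulationConfig


def _counts_from_rates(log_mu: np.ndarray, lengths_kb: np.ndarray,
                       library_size: int, rng: np.random.Generator,
                       poisson: bool) -> np.ndarray:
    rate = np.exp(log_mu) * lengths_kb[:, None]
    lam = rate / rate.sum(axis=0, keepdims=True) * library_size
    if poisson:
        return rng.poisson(lam).astype(float)
    return np.rint(lam)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full multi-species dataset described by ``config``.

    Returns per-species count matrices, gene lengths, the orthogroup table,
    the species tree and the ground truth.  Identical configs and seeds
    yield identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree(config.tree_newick or default_tree(config.species))
    if set(config.species) != tree.leaves:
        raise ValueError("tree leaves must match the configured species")
    species = list(config.species)
    root = tree.root
    all_nodes = [root]
    # deterministic node list: lineage of each leaf, de-duplicated in order
    for sp in species:
        for node in tree.lineage(sp):
            if node not in all_nodes:
                all_nodes.append(node)

    counters = {sp: 0 for sp in species}

    def new_gene(sp: str) -> str:
        counters[sp] += 1
        return f"{sp}_g{counters[sp]:04d}"

    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    og_origin: dict[str, str] = {}
    og_counter = 0

    def new_og(cells: dict[str, tuple[str, ...]], origin: str) -> str:
        nonlocal og_counter
        og_counter += 1
        og = f"OG{og_counter:07d}"
        groups[og] = {sp: cells.get(sp, ()) for sp in species}
        og_origin[og] = origin
        return og

    module_truth = {sp: {} for sp in species}
    specific_truth = {sp: {} for sp in species}
    gene_role: dict[str, tuple[str, object]] = {}  # gene -> ("module", PlantedModule) etc.

    # ---- planted modules -------------------------------------------------
    labels = [f"M{i + 1}" for i in range(len(config.planted_modules))]
    for label, mod in zip(labels, config.planted_modules):
        n_shared = round(mod.ortho_fraction * mod.size)
        for _ in range(n_shared):
            cells = {}
            for sp in species:
                g = new_gene(sp)
                cells[sp] = (g,)
                module_truth[sp][g] = label
                gene_role[g] = ("module", mod)
            new_og(cells, tree.mrca(set(species)) if len(species) > 1 else root)
        for sp in species:
            for _ in range(mod.size - n_shared):
                g = new_gene(sp)
                module_truth[sp][g] = label
                gene_role[g] = ("module", mod)
                new_og({sp: (g,)}, sp)

    # ---- planted tissue-specific genes ----------------------------------
    for spec in config.planted_specific:
        for sp in species:
            for _ in range(spec.n_genes):
                g = new_gene(sp)
                specific_truth[sp][g] = spec.tissue
                gene_role[g] = ("specific", spec)
                new_og({sp: (g,)}, sp)

    # ---- background orthogroups -----------------------------------------
    n_background = config.n_orthogroups - og_counter
    for _ in range(n_background):
        if rng.random() < config.p_single_copy:
            origin = tree.mrca(set(species)) if len(species) > 1 else root
            members = list(species)
        else:
            origin = all_nodes[rng.integers(len(all_nodes))]
            descendants = sorted(tree.leaf_set(origin))
            members = [sp for sp in descendants
                       if rng.random() < config.retention_prob]
            if not members:
                members = [descendants[rng.integers(len(descendants))]]
        cells = {}
        for sp in members:
            n_copies = 1 + (1 if rng.random() < config.paralog_prob else 0)
            gs = []
            for _ in range(n_copies):
                g = new_gene(sp)
                gene_role[g] = ("background", None)
                gs.append(g)
            cells[sp] = tuple(gs)
        new_og(cells, origin)

    table = OrthogroupTable(groups, species)

    # ---- expression ------------------------------------------------------
    samples = [f"{t}.{r + 1}" for t in config.tissues
               for r in range(config.n_replicates)]
    sample_tissue = [s.rpartition(".")[0] for s in samples]
    lo, hi = config.length_kb_range
    poisson = config.noise_sd > 0

    expression: dict[str, ExpressionMatrix] = {}
    lengths: dict[str, pd.Series] = {}
    for sp in species:
        genes = table.genes(sp)
        n = len(genes)
        lens = rng.uniform(lo, hi, size=n)
        baseline = rng.normal(config.baseline_loc, config.baseline_scale, size=n)
        log_mu = np.tile(baseline[:, None], (1, len(samples)))
        for i, g in enumerate(genes):
            kind, obj = gene_role[g]
            if kind == "module":
                for j, t in enumerate(sample_tissue):
                    if t in obj.peak:
                        log_mu[i, j] += obj.effect
            elif kind == "specific":
                off = np.log(config.off_target_fraction)
                for j, t in enumerate(sample_tissue):
                    if t != obj.tissue:
                        log_mu[i, j] += off
        if config.noise_sd > 0:
            log_mu = log_mu + rng.normal(0.0, config.noise_sd,
                                         size=log_mu.shape)
        counts = _counts_from_rates(log_mu, lens, config.library_size, rng, poisson)
        order = rng.permutation(n)
        values = pd.DataFrame(counts, index=genes, columns=samples).iloc[order]
        cond = pd.Series(sample_tissue, index=samples)
        rep = pd.Series([int(s.rpartition(".")[2]) for s in samples], index=samples)
        expression[sp] = ExpressionMatrix(values, cond, rep, unit="counts")
        lengths[sp] = pd.Series(lens, index=genes, name="length_kb").iloc[order]

    truth = GroundTruth(
        modules={sp: pd.Series(module_truth[sp]).reindex(
            expression[sp].genes, fill_value="") for sp in species},
        specific={sp: pd.Series(specific_truth[sp]).reindex(
            expression[sp].genes, fill_value="") for sp in species},
        og_origin=pd.Series(og_origin, name="origin"),
        module_pairs=[(a, lab, b, lab)
                      for i, a in enumerate(species) for b in species[i + 1:]
                      for lab in labels],
    )
    return SimulatedDataset(expression, lengths, table, tree, truth, config)


def simulate_timecourse(stages, n_clusters: int, genes_per_cluster: int = 50,
                        noise_sd: float = 0.2, seed: int | None = 0,
                        amplitude: float = 3.0):
    """Single-species developmental time course with planted temporal clusters.

    Each true cluster's genes follow a log-scale Gaussian bump peaking at
    one stage, peaks spread evenly across the stage axis, plus per-value
    Gaussian noise.  Returns an :class:`ExpressionMatrix` (one sample per
    stage) and a Series mapping genes to their true cluster (1-based).
    """
    stages = list(stages)
    S = len(stages)
    if S < 3:
        raise ValueError("need at least 3 stages")
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if n_clusters > S:
        raise ValueError(
            f"{n_clusters} clusters cannot have distinct peaks over {S} stages")
    rng = np.random.default_rng(seed)
    peaks = np.round(np.linspace(0, S - 1, n_clusters)).astype(int)
    if len(set(peaks.tolist())) != n_clusters:
        raise ValueError("could not place distinct peak stages")
    idx = np.arange(S)
    rows, names, truth = [], [], []
    for c, p in enumerate(peaks, start=1):
        bump = amplitude * np.exp(-0.5 * (idx - p) ** 2)
        for g in range(genes_per_cluster):
            noise = rng.normal(0.0, noise_sd, size=S) if noise_sd > 0 else 0.0
            rows.append(np.exp(bump + noise))
            names.append(f"g{c:02d}_{g + 1:04d}")
            truth.append(c)
    values = pd.DataFrame(np.asarray(rows), index=names, columns=stages)
    cond = pd.Series(stages, index=stages)
    em = ExpressionMatrix(values, cond, unit="cRPKM")
    return em, pd.Series(truth, index=names, name="true_cluster")


def write_fixture(ds: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as plain-text files.

    Emits per-species count/metadata/length TSVs, the orthogroup table
    (OrthoFinder dialect), the Newick tree, a GMT file of planted module
    labels and the ground-truth TSVs.  Everything round-trips through the
    package's readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp, em in ds.expression.items():
        paths[f"{sp}_counts"] = directory / f"{sp}_counts.tsv"
        paths[f"{sp}_samples"] = directory / f"{sp}_samples.tsv"
        write_expression_tsv(em, paths[f"{sp}_counts"], paths[f"{sp}_samples"])
        paths[f"{sp}_lengths"] = directory / f"{sp}_lengths.tsv"
        ds.lengths[sp].rename_axis("gene").to_csv(paths[f"{sp}_lengths"], sep="\t")
    paths["orthogroups"] = directory / "Orthogroups.tsv"
    write_orthogroups(ds.orthogroups, paths["orthogroups"])
    paths["tree"] = directory / "tree.nwk"
    paths["tree"].write_text(ds.tree.as_newick() + "\n")
    terms = {}
    for sp, series in ds.truth.modules.items():
        for label in sorted(set(series) - {""}):
            terms[f"{sp}:{label}"] = set(series.index[series == label])
    paths["gmt"] = directory / "modules.gmt"
    write_gmt(terms, paths["gmt"], description="planted module")
    mod_rows = [{"species": sp, "gene": g, "module": lab}
                for sp, series in ds.truth.modules.items()
                for g, lab in series.items() if lab]
    spec_rows = [{"species": sp, "gene": g, "tissue": t}
                 for sp, series in ds.truth.specific.items()
                 for g, t in series.items() if t]
    paths["truth_modules"] = directory / "truth_modules.tsv"
    pd.DataFrame(mod_rows).to_csv(paths["truth_modules"], sep="\t", index=False)
    paths["truth_specific"] = directory / "truth_specific.tsv"
    pd.DataFrame(spec_rows).to_csv(paths["truth_specific"], sep="\t", index=False)
    paths["truth_og_origin"] = directory / "truth_og_origin.tsv"
    ds.truth.og_origin.rename_axis("orthogroup").to_csv(
        paths["truth_og_origin"], sep="\t")
    paths["truth_module_pairs"] = directory / "truth_module_pairs.tsv"
    pd.DataFrame(ds.truth.module_pairs,
                 columns=["species_a", "module_a", "species_b", "module_b"]
                 ).to_csv(paths["truth_module_pairs"], sep="\t", index=False)
    return paths
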