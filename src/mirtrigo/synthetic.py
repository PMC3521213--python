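"""Seeded synthetic tri-partite scenarios for testing and calibration.

A scenario bundles the four inputs of the pipeline — an ontology DAG, raw
gene annotations, a miRNA-target network, and one miRNA cluster — generated
from a single integer seed.  The generator emulates the salient features of
real miRNA target data: a heavy-tailed miRNA out-degree distribution (a
single miRNA can regulate hundreds of targets), genes annotated to a few
terms of a multi-level DAG, and, optionally, a *planted* enriched term: the
cluster members' links are biased toward the genes of one designated term
with a configurable probability, so the miRNA-centric test has a known
ground-truth signal.  With the bias at zero the scenario is an exact null
and serves for type-I error calibration.

:func:`make_discriminability_fixtures` builds the four hand-wired topologies
(A, B, C, D) demonstrating that the gene-centric measure cannot distinguish
wiring patterns that the link-centric and miRNA-centric measures can.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ontology import (
    AnnotationTable,
    OntologyGraph,
    Term,
    write_gaf,
    write_obo,
)
from .target_network import (
    MiRNACluster,
    TargetNetwork,
    write_clusters,
    write_target_pairs,
)

logger = logging.getLogger(__name__)

#: Minimum miRNA out-degree of the truncated power-law sampler.
MIN_OUT_DEGREE = 5

#: Planted-term size band, as fractions of the gene count.
PLANTED_MIN_FRACTION = 0.005
PLANTED_MAX_FRACTION = 0.05
PLANTED_TARGET_FRACTION = 0.02


class InfeasibleScenarioError(ValueError):
    """Raised before generation when a configuration cannot produce a valid
    scenario (e.g. no candidate planted term with annotated genes)."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the scenario generator.

    * ``n_mirnas`` / ``n_genes`` / ``n_terms`` — sizes of the three layers.
    * ``dag_branching`` — mean number of children per expanded term.
    * ``annotation_density`` — mean number of (raw) term annotations per gene.
    * ``degree_skew`` — exponent of the truncated power-law miRNA out-degree
      distribution; smaller = heavier tail.
    * ``planted_term_fraction`` — probability that a cluster member's link is
      steered to a gene of the planted term (0 = exact null).
    * ``cluster_size`` — number of miRNAs in the investigated cluster.
    * ``seed`` — single integer governing all randomness.
    """

    n_mirnas: int = 200
    n_genes: int = 1000
    n_terms: int = 150
    dag_branching: float = 3.0
    annotation_density: float = 2.0
    degree_skew: float = 2.0
    planted_term_fraction: float = 0.9
    cluster_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_genes) < 1 or self.n_terms < 2:
            raise ValueError("scenario sizes below the minimum viable")
        if not 1 <= self.cluster_size <= self.n_mirnas:
            raise ValueError("cluster_size must lie in [1, n_mirnas]")
        if not 0.0 <= self.planted_term_fraction <= 1.0:
            raise ValueError("planted_term_fraction must lie in [0, 1]")
        if self.dag_branching <= 0 or self.annotation_density < 1:
            raise ValueError("dag_branching > 0 and annotation_density >= 1 required")
        if self.degree_skew <= 0:
            raise ValueError("degree_skew must be positive")


@dataclass
class Scenario:
    """One generated tri-partite scenario."""

    config: ScenarioConfig
    graph: OntologyGraph
    annotations: AnnotationTable  # raw, unpropagated
    network: TargetNetwork
    cluster: MiRNACluster
    planted_term: str | None


def _term_id(index: int) -> str:
    return f"GO:{index:07d}"


def _generate_dag(rng: np.random.Generator, n_terms: int, branching: float) -> OntologyGraph:
    """Top-down DAG: the root spawns Poisson(branching) children per frontier
    term; ~15% of non-root terms acquire a second parent among earlier terms,
    which keeps the graph acyclic by construction."""
    terms = [Term(_term_id(1), "synthetic root", "BP")]
    edges: list[tuple[str, str]] = []
    frontier = [_term_id(1)]
    next_index = 2
    while next_index <= n_terms:
        new_frontier: list[str] = []
        for parent in frontier:
            if next_index > n_terms:
                break
            for _ in range(int(rng.poisson(branching))):
                if next_index > n_terms:
                    break
                child = _term_id(next_index)
                terms.append(Term(child, f"synthetic term {next_index}", "BP"))
                edges.append((child, parent))
                if next_index > 2 and rng.random() < 0.15:
                    extra = _term_id(int(rng.integers(1, next_index)))
                    if extra != parent:
                        edges.append((child, extra))
                new_frontier.append(child)
                next_index += 1
        if not new_frontier and next_index <= n_terms:
            # frontier died out; attach remaining terms to random existing ones
            child = _term_id(next_index)
            parent = _term_id(int(rng.integers(1, next_index)))
            terms.append(Term(child, f"synthetic term {next_index}", "BP"))
            edges.append((child, parent))
            new_frontier.append(child)
            next_index += 1
        frontier = new_frontier
    return OntologyGraph(terms, edges)


def sample_out_degrees(
    rng: np.random.Generator,
    n: int,
    skew: float,
    d_min: int = MIN_OUT_DEGREE,
    d_max: int | None = None,
) -> np.ndarray:
    """Heavy-tailed out-degrees: a discrete Pareto with tail exponent *skew*,
    truncated to [d_min, d_max].  Smaller exponents give heavier tails and a
    larger max/median ratio."""
    u = rng.random(n)
    degrees = np.floor(d_min * (1.0 - u) ** (-1.0 / skew)).astype(int)
    if d_max is not None:
        degrees = np.minimum(degrees, d_max)
    return np.maximum(degrees, d_min)


def _propagated_gene_sets(
    graph: OntologyGraph, annotations: AnnotationTable
) -> dict[str, set[str]]:
    acc: dict[str, set[str]] = {}
    for term, genes in annotations.genes_by_term().items():
        for anc in graph.ancestors(term, include_self=True):
            acc.setdefault(anc, set()).update(genes)
    return acc


def _pick_planted_term(
    graph: OntologyGraph, gene_sets: dict[str, set[str]], n_genes: int
) -> str | None:
    lo = max(3, int(PLANTED_MIN_FRACTION * n_genes))
    hi = max(lo, int(PLANTED_MAX_FRACTION * n_genes))
    target = PLANTED_TARGET_FRACTION * n_genes
    root = graph.roots["BP"]
    candidates = [
        (abs(len(genes) - target), term)
        for term, genes in gene_sets.items()
        if term != root and lo <= len(genes) <= hi
    ]
    if not candidates:
        return None
    return min(candidates)[1]


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a fully seeded scenario; identical configs give identical
    outputs."""
    rng = np.random.default_rng(config.seed)
    graph = _generate_dag(rng, config.n_terms, config.dag_branching)
    genes = [f"g{idx:05d}" for idx in range(1, config.n_genes + 1)]
    mirnas = [f"mir-{idx:04d}" for idx in range(1, config.n_mirnas + 1)]

    non_root = [t for t in graph.terms_in("BP") if t != graph.roots["BP"]]
    rows = []
    for gene in genes:
        k = 1 + int(rng.poisson(config.annotation_density - 1.0))
        k = min(k, len(non_root))
        for term_idx in rng.choice(len(non_root), size=k, replace=False):
            rows.append((gene, non_root[int(term_idx)], "IEA"))
    annotations = AnnotationTable.from_pairs(rows)

    gene_sets = _propagated_gene_sets(graph, annotations)
    planted = _pick_planted_term(graph, gene_sets, config.n_genes)
    if planted is None and config.planted_term_fraction > 0:
        raise InfeasibleScenarioError(
            "no candidate planted term with enough annotated genes; "
            "increase n_genes or annotation_density"
        )
    planted_genes = sorted(gene_sets[planted]) if planted else []

    members = sorted(
        mirnas[int(m)] for m in rng.choice(config.n_mirnas, config.cluster_size, replace=False)
    )
    member_set = set(members)
    degrees = sample_out_degrees(rng, config.n_mirnas, config.degree_skew,
                                 d_max=config.n_genes)
    links: list[tuple[str, str]] = []
    for mirna, degree in zip(mirnas, degrees):
        if mirna in member_set and planted_genes and config.planted_term_fraction > 0:
            steered = rng.random(degree) < config.planted_term_fraction
            chosen: set[str] = set()
            for s in steered:
                pool = planted_genes if s else genes
                chosen.add(pool[int(rng.integers(len(pool)))])
            targets = sorted(chosen)
        else:
            picks = rng.choice(config.n_genes, size=int(degree), replace=False)
            targets = [genes[int(p)] for p in picks]
        links.extend((mirna, g) for g in targets)
    network = TargetNetwork(links)
    cluster = MiRNACluster("cluster-1", frozenset(members))
    return Scenario(config, graph, annotations, network, cluster, planted)


def write_scenario(scenario: Scenario, outdir, force: bool = False) -> dict:
    """Write the four standard input files plus a manifest.

    Files: ``scenario.obo``, ``scenario.gaf``, ``pairs.tsv``,
    ``clusters.tsv`` and ``manifest.json`` (parameters, planted term, and
    SHA-256 checksums of each file).  Refuses to overwrite an existing
    non-empty directory unless *force* is given.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty (use force to overwrite)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "obo": outdir / "scenario.obo",
        "gaf": outdir / "scenario.gaf",
        "pairs": outdir / "pairs.tsv",
        "clusters": outdir / "clusters.tsv",
    }
    write_obo(scenario.graph, files["obo"])
    write_gaf(scenario.annotations, scenario.graph, files["gaf"])
    write_target_pairs(scenario.network, files["pairs"])
    write_clusters([scenario.cluster], files["clusters"])
    manifest = {
        "config": asdict(scenario.config),
        "planted_term": scenario.planted_term,
        "files": {
            key: {
                "path": path.name,
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for key, path in files.items()
        },
    }
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# -- hand-wired discriminability fixtures --------------------------------


@dataclass(frozen=True)
class DiscriminabilityFixture:
    """One wired topology plus the gene set annotated to the probed term."""

    label: str
    network: TargetNetwork
    cluster: MiRNACluster
    annotated_genes: frozenset[str]


def _background_links() -> list[tuple[str, str]]:
    links: list[tuple[str, str]] = []
    # 24 background miRNAs, 3 non-annotated targets each ...
    for idx in range(7, 31):
        for off in range(3):
            gene_idx = 12 + ((idx * 3 + off) % 49)
            links.append((f"mir-{idx:02d}", f"g{gene_idx:02d}"))
    # ... and six of them each hit one annotated gene, so the non-cluster
    # margins of the tau and mu tables are nonzero
    for idx, gene_idx in [(7, 7), (8, 8), (9, 9), (10, 10), (11, 11), (12, 7)]:
        links.append((f"mir-{idx:02d}", f"g{gene_idx:02d}"))
    return links


def make_discriminability_fixtures() -> dict[str, DiscriminabilityFixture]:
    """Four fixed topologies on a 30-miRNA, 60-gene background.

    All four share the cluster {mir-01..mir-06}, the annotated gene set
    {g01..g11}, and identical gene-centric quartets within each pair:

    * A vs B — the same 5 cluster miRNAs reach the same 6 annotated genes
      through 8 (sparse) vs 22 (dense) links: only the link-centric quartet
      differs.
    * C vs D — the cluster sends the same 6 links to the same 6 annotated
      genes, but through 6 vs 3 distinct members: only the miRNA-centric
      quartet differs.
    """
    cluster = MiRNACluster(
        "fixture-cluster", frozenset(f"mir-{i:02d}" for i in range(1, 7))
    )
    annotated = frozenset(f"g{i:02d}" for i in range(1, 12))
    background = _background_links()

    sparse = [
        ("mir-01", "g01"), ("mir-01", "g02"), ("mir-01", "g03"),
        ("mir-02", "g04"), ("mir-03", "g05"), ("mir-04", "g06"),
        ("mir-05", "g01"), ("mir-05", "g02"),
    ]
    excluded = {
        ("mir-01", "g06"), ("mir-02", "g05"), ("mir-03", "g04"),
        ("mir-04", "g03"), ("mir-05", "g02"), ("mir-05", "g01"),
        ("mir-04", "g02"), ("mir-03", "g01"),
    }
    dense = [
        (f"mir-{m:02d}", f"g{g:02d}")
        for m in range(1, 6)
        for g in range(1, 7)
        if (f"mir-{m:02d}", f"g{g:02d}") not in excluded
    ]
    ab_filler = [("mir-06", f"g{i:02d}") for i in range(12, 21)]

    six_wide = [(f"mir-{i:02d}", f"g{i:02d}") for i in range(1, 7)]
    six_wide += [(f"mir-{i:02d}", f"g{11 + i:02d}") for i in range(1, 7)]
    three_wide = [
        ("mir-01", "g01"), ("mir-01", "g02"), ("mir-02", "g03"),
        ("mir-02", "g04"), ("mir-03", "g05"), ("mir-03", "g06"),
        ("mir-04", "g12"), ("mir-04", "g13"), ("mir-05", "g14"),
        ("mir-05", "g15"), ("mir-06", "g16"), ("mir-06", "g17"),
    ]

    wirings = {
        "A": sparse + ab_filler,
        "B": dense + ab_filler,
        "C": six_wide,
        "D": three_wide,
    }
    return {
        label: DiscriminabilityFixture(
            label, TargetNetwork(background + wiring), cluster, annotated
        )
        for label, wiring in wirings.items()
    }
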