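"""2x2 contingency quartets for the three enrichment viewpoints.

For a miRNA cluster C and the gene set A annotated to one GO term, the
tri-partite network yields three contingency tables over three universes:

* rho (gene-centric): target genes of C that are / are not annotated,
  against the remaining genes of the network's gene universe;
* tau (link-centric): links from C to annotated / unannotated genes,
  against links from non-member miRNAs, over the link universe;
* mu (miRNA-centric): cluster members targeting at least one annotated
  gene, against non-members doing so, over the miRNA universe.

Each quartet (i, j, k, l) sums to its universe size.  rho is blind to the
wiring between the cluster and its target genes: any rewiring that preserves
the target gene cluster leaves it unchanged, while tau and mu are not — this
is exactly what makes the two new viewpoints discriminative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .target_network import EmptyClusterError, MiRNACluster, TargetNetwork

logger = logging.getLogger(__name__)

MEASURES = ("rho", "tau", "mu")


@dataclass(frozen=True)
class ContingencyQuartet:
    """The four cells of one 2x2 enrichment table.

    i: in-set and annotated, j: in-set not annotated, k: out-of-set
    annotated, l: out-of-set not annotated — where "set" means the target
    gene cluster (rho), the cluster's links (tau), or the cluster itself (mu).
    """

    measure: str
    i: int
    j: int
    k: int
    l: int
    cluster_id: str = ""
    term_id: str = ""

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if min(self.i, self.j, self.k, self.l) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def universe_size(self) -> int:
        return self.i + self.j + self.k + self.l

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.i, self.j, self.k, self.l)


class QuartetCalculator:
    """Per-cluster precomputation shared by the three quartet derivations.

    Built once per (network, cluster); each call then only depends on the
    term's annotated gene set, so enrichment over thousands of terms stays
    linear in the annotation size.
    """

    def __init__(self, network: TargetNetwork, cluster: MiRNACluster) -> None:
        self.network = network
        members = cluster.members & network.mirna_universe
        dropped = cluster.members - members
        if dropped:
            logger.warning(
                "cluster %s: dropping %d members absent from the miRNA universe: %s",
                cluster.cluster_id, len(dropped), sorted(dropped)[:5],
            )
        if not members:
            raise EmptyClusterError(
                f"cluster {cluster.cluster_id!r} has no member in the miRNA universe"
            )
        self.cluster_id = cluster.cluster_id
        self.members = members
        target_genes: set[str] = set()
        for m in members:
            target_genes.update(network.targets_of(m))
        self.target_genes = frozenset(target_genes)
        # links are deduplicated pairs, so the number of cluster links to a
        # gene equals the number of members regulating it
        self._cluster_links_by_gene = {
            g: len(network.regulators_of(g) & members) for g in target_genes
        }
        self.n_cluster_links = sum(self._cluster_links_by_gene.values())
        self.n_mirnas = len(network.mirna_universe)
        self.n_genes = len(network.gene_universe)
        self.n_links = network.link_universe_size

    def _restrict(self, annotated_genes: frozenset[str]) -> frozenset[str]:
        return frozenset(annotated_genes) & self.network.gene_universe

    def rho(self, annotated_genes: frozenset[str], term_id: str = "") -> ContingencyQuartet:
        a = self._restrict(annotated_genes)
        i = len(a & self.target_genes)
        j = len(self.target_genes) - i
        k = len(a) - i
        l = self.n_genes - len(self.target_genes) - len(a) + i
        return ContingencyQuartet("rho", i, j, k, l, self.cluster_id, term_id)

    def tau(self, annotated_genes: frozenset[str], term_id: str = "") -> ContingencyQuartet:
        a = self._restrict(annotated_genes)
        i = sum(self._cluster_links_by_gene.get(g, 0) for g in a)
        links_to_a = sum(len(self.network.regulators_of(g)) for g in a)
        k = links_to_a - i
        j = self.n_cluster_links - i
        l = self.n_links - i - j - k
        return ContingencyQuartet("tau", i, j, k, l, self.cluster_id, term_id)

    def mu(self, annotated_genes: frozenset[str], term_id: str = "") -> ContingencyQuartet:
        a = self._restrict(annotated_genes)
        hitting: set[str] = set()
        for g in a:
            hitting.update(self.network.regulators_of(g))
        i = len(hitting & self.members)
        j = len(self.members) - i
        k = len(hitting) - i
        l = self.n_mirnas - len(self.members) - k
        return ContingencyQuartet("mu", i, j, k, l, self.cluster_id, term_id)

    def quartet(self, measure: str, annotated_genes: frozenset[str], term_id: str = "") -> ContingencyQuartet:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        return getattr(self, measure)(annotated_genes, term_id)


def rho_quartet(
    network: TargetNetwork,
    cluster: MiRNACluster,
    annotated_genes: frozenset[str],
    term_id: str = "",
) -> ContingencyQuartet:
    """Gene-centric quartet: target genes of the cluster vs the gene universe,
    split by annotation to the term."""
    return QuartetCalculator(network, cluster).rho(annotated_genes, term_id)


def tau_quartet(
    network: TargetNetwork,
    cluster: MiRNACluster,
    annotated_genes: frozenset[str],
    term_id: str = "",
) -> ContingencyQuartet:
    """Link-centric quartet: links from cluster members vs all links, split by
    whether the link's gene is annotated to the term."""
    return QuartetCalculator(network, cluster).tau(annotated_genes, term_id)


def mu_quartet(
    network: TargetNetwork,
    cluster: MiRNACluster,
    annotated_genes: frozenset[str],
    term_id: str = "",
) -> ContingencyQuartet:
    """miRNA-centric quartet: miRNAs targeting at least one annotated gene,
    inside vs outside the cluster, over the miRNA universe."""
    return QuartetCalculator(network, cluster).mu(annotated_genes, term_id)
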