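"""Gene Ontology DAG, gene annotations, and information-theoretic term measures.

This module models the annotation layer of the tri-partite network:

* :class:`OntologyGraph` — the GO DAG (``is_a`` edges only by default), with
  one designated root per category (BP, MF, CC) and cached ancestor /
  descendant queries.
* :class:`AnnotationTable` — gene-to-term associations read from a GAF file,
  before or after true-path propagation (a gene annotated to a term is
  implicitly annotated to every ancestor of that term).
* Term specificity and relatedness: annotation frequency, Information
  Content ``IC(t) = -log(freq(t) / freq(root))`` and Resnik semantic
  similarity ``sim(a, b) = IC`` of the most informative common ancestor.

Two frequency conventions are supported.  ``multiplicity_sum`` adds the direct
annotation count of a term to the direct counts of *all* its descendants, so
a gene annotated to two descendants contributes twice; ``unique_genes``
counts the union of genes instead.  ``multiplicity_sum`` is the default and must be
fed raw (unpropagated) annotations, otherwise descendant counts would be
inflated a second time.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: GO namespace (as spelled in OBO files) -> two-letter category code.
NAMESPACE_TO_CATEGORY = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
CATEGORY_TO_NAMESPACE = {v: k for k, v in NAMESPACE_TO_CATEGORY.items()}
CATEGORIES = ("BP", "MF", "CC")

#: GAF aspect column letter -> category code.
ASPECT_TO_CATEGORY = {"P": "BP", "F": "MF", "C": "CC"}
CATEGORY_TO_ASPECT = {v: k for k, v in ASPECT_TO_CATEGORY.items()}

#: Evidence codes recognised by the GAF 2.x standard; unknown codes are kept
#: with a warning.
KNOWN_EVIDENCE_CODES = frozenset(
    "EXP IDA IPI IMP IGI IEP HTP HDA HMP HGI HEP IBA IBD IKR IRD "
    "ISS ISO ISA ISM IGC RCA TAS NAS IC ND IEA NR".split()
)

#: Evidence codes excluded by default: ND (No biological Data) and
#: NR (Not Recorded) carry no usable information.
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"ND", "NR"})

GAF_COLUMNS = 17


class OboParseError(ValueError):
    """Raised when an OBO stream cannot be parsed."""


class GafParseError(ValueError):
    """Raised when a GAF stream cannot be parsed."""


class StructuralError(ValueError):
    """Raised when the ontology graph violates a structural requirement
    (cyclic ``is_a`` relations, missing root, no common ancestor, ...)."""


class UndefinedInformationContent(ValueError):
    """Raised for terms with zero annotation frequency, whose IC is undefined."""


@dataclass(frozen=True)
class Term:
    """A single GO term."""

    term_id: str
    name: str
    category: str
    is_obsolete: bool = False

    def __post_init__(self) -> None:
        if not (
            self.term_id.startswith("GO:")
            and len(self.term_id) == 10
            and self.term_id[3:].isdigit()
        ):
            raise ValueError(f"malformed GO accession: {self.term_id!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown GO category: {self.category!r}")


class OntologyGraph:
    """The GO DAG: terms plus directed child-to-parent ``is_a`` relations.

    Edges always point from child to parent, so graph-theoretic
    reachability corresponds to ontological ancestry.  Obsolete terms are
    retained (flagged) but carry no edges and never participate in
    enrichment or similarity queries.
    """

    def __init__(
        self,
        terms: Iterable[Term],
        parent_edges: Iterable[tuple[str, str]],
    ) -> None:
        self.terms: dict[str, Term] = {t.term_id: t for t in terms}
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in parent_edges:
            for end in (child, parent):
                if end not in self.terms:
                    raise StructuralError(f"edge references unknown term {end!r}")
            if self.terms[child].is_obsolete or self.terms[parent].is_obsolete:
                raise StructuralError(
                    f"obsolete term in edge {child!r} -> {parent!r}"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructuralError(f"cyclic is_a relations: {cycle}")
        self._graph = g
        self.roots = self._find_roots()
        self._ancestors: dict[str, frozenset[str]] = {}
        self._descendants: dict[str, frozenset[str]] = {}

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for cat in CATEGORIES:
            candidates = [
                t.term_id
                for t in self.terms.values()
                if t.category == cat
                and not t.is_obsolete
                and self._graph.out_degree(t.term_id) == 0
            ]
            if len(candidates) > 1:
                raise StructuralError(
                    f"category {cat} has {len(candidates)} parentless terms; "
                    f"expected a single root: {sorted(candidates)[:5]}"
                )
            if candidates:
                roots[cat] = candidates[0]
        return roots

    # -- basic queries ---------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def category(self, term_id: str) -> str:
        return self.terms[term_id].category

    def parents(self, term_id: str) -> frozenset[str]:
        return frozenset(self._graph.successors(term_id))

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self._graph.predecessors(term_id))

    def ancestors(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable from ``term_id`` along is_a edges."""
        if term_id not in self._ancestors:
            self._ancestors[term_id] = frozenset(nx.descendants(self._graph, term_id))
        anc = self._ancestors[term_id]
        return anc | {term_id} if include_self else anc

    def descendants(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        if term_id not in self._descendants:
            self._descendants[term_id] = frozenset(nx.ancestors(self._graph, term_id))
        desc = self._descendants[term_id]
        return desc | {term_id} if include_self else desc

    def terms_in(self, category: str, include_obsolete: bool = False) -> list[str]:
        """Term ids of one category, sorted, obsolete terms excluded by default."""
        return sorted(
            t.term_id
            for t in self.terms.values()
            if t.category == category and (include_obsolete or not t.is_obsolete)
        )

    def edges(self) -> Iterable[tuple[str, str]]:
        """(child, parent) pairs."""
        return self._graph.edges()


def _validate_obo_lines(lines: list[str]) -> None:
    in_term = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"line {lineno}: malformed stanza header {raw!r}")
            in_term = line == "[Term]"
            continue
        if in_term and ":" not in line:
            raise OboParseError(
                f"line {lineno}: malformed tag-value line in [Term] stanza: {raw!r}"
            )


def parse_obo(source, include_part_of: bool = False) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 stream or path into an :class:`OntologyGraph`.

    Only ``is_a`` relations define ancestry unless *include_part_of* is set.
    Obsolete terms are retained with their flag and no edges.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    _validate_obo_lines(text.splitlines())
    try:
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare ValueError
        raise OboParseError(f"unparseable OBO stream: {exc}") from exc

    default_ns = (multigraph.graph.get("default-namespace") or [None])[0]
    terms = []
    for node, data in multigraph.nodes(data=True):
        ns = data.get("namespace", default_ns)
        if ns not in NAMESPACE_TO_CATEGORY:
            raise OboParseError(f"term {node}: unknown or missing namespace {ns!r}")
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms.append(
            Term(node, data.get("name", node), NAMESPACE_TO_CATEGORY[ns], obsolete)
        )
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    obsolete_ids = {t.term_id for t in terms if t.is_obsolete}
    edges = [
        (child, parent)
        for child, parent, key in multigraph.edges(keys=True)
        if key in keep and child not in obsolete_ids and parent not in obsolete_ids
    ]
    return OntologyGraph(terms, edges)


def write_obo(graph: OntologyGraph, path_or_handle) -> None:
    """Serialise the graph to a minimal OBO 1.2 document (inverse of
    :func:`parse_obo` for the fields this package uses)."""
    own = isinstance(path_or_handle, (str, os.PathLike))
    fh = open(path_or_handle, "wt", encoding="utf-8") if own else path_or_handle
    try:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        parents: dict[str, list[str]] = {}
        for child, parent in graph.edges():
            parents.setdefault(child, []).append(parent)
        for term_id in sorted(graph.terms):
            term = graph.terms[term_id]
            fh.write(f"\n[Term]\nid: {term.term_id}\nname: {term.name}\n")
            fh.write(f"namespace: {CATEGORY_TO_NAMESPACE[term.category]}\n")
            for parent in sorted(parents.get(term_id, ())):
                fh.write(f"is_a: {parent} ! {graph.terms[parent].name}\n")
            if term.is_obsolete:
                fh.write("is_obsolete: true\n")
    finally:
        if own:
            fh.close()


class AnnotationTable:
    """Gene-to-GO-term associations.

    Stores one record per ``(gene, term)`` pair (first evidence code kept on
    duplicates).  ``propagated`` records whether the true-path closure has
    been applied.
    """

    def __init__(self, records: pd.DataFrame, propagated: bool = False) -> None:
        df = records.loc[:, ["gene", "term", "evidence"]].drop_duplicates(
            subset=["gene", "term"], keep="first"
        )
        self.records = df.reset_index(drop=True)
        self.propagated = propagated
        self._genes_by_term: dict[str, frozenset[str]] | None = None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str] | tuple[str, str, str]],
        propagated: bool = False,
    ) -> "AnnotationTable":
        rows = [(p[0], p[1], p[2] if len(p) > 2 else "IEA") for p in pairs]
        return cls(
            pd.DataFrame(rows, columns=["gene", "term", "evidence"]), propagated
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.records["gene"])

    @property
    def annotated_terms(self) -> frozenset[str]:
        return frozenset(self.records["term"])

    def genes_by_term(self) -> dict[str, frozenset[str]]:
        """Mapping term -> genes carrying that annotation (cached)."""
        if self._genes_by_term is None:
            self._genes_by_term = {
                term: frozenset(group)
                for term, group in self.records.groupby("term")["gene"]
            }
        return self._genes_by_term

    def direct_counts(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.genes_by_term().items()}

    def restrict_genes(self, genes: frozenset[str]) -> "AnnotationTable":
        """Keep only annotations of the given genes."""
        mask = self.records["gene"].isin(genes)
        return AnnotationTable(self.records[mask], self.propagated)


def parse_gaf(
    source,
    excluded_evidence: frozenset[str] = DEFAULT_EXCLUDED_EVIDENCE,
    gene_id: str = "symbol",
) -> AnnotationTable:
    """Parse a GAF 2.x stream or path into a raw :class:`AnnotationTable`.

    Rows with a NOT qualifier are dropped, as are rows whose evidence code is
    in *excluded_evidence* (default ``{ND, NR}``).  *gene_id* selects the gene
    identifier: ``"symbol"`` (column 3, default, matching target-pair tables)
    or ``"object_id"`` (column 2).
    """
    if gene_id not in ("symbol", "object_id"):
        raise ValueError(f"gene_id must be 'symbol' or 'object_id', got {gene_id!r}")
    gene_col = 2 if gene_id == "symbol" else 1
    own = not hasattr(source, "read")
    fh = open(source, "rt", encoding="utf-8") if own else source
    rows = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) != GAF_COLUMNS:
                raise GafParseError(
                    f"line {lineno}: expected {GAF_COLUMNS} columns, got {len(fields)}"
                )
            qualifier, term, evidence = fields[3], fields[4], fields[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in excluded_evidence:
                continue
            if evidence not in KNOWN_EVIDENCE_CODES:
                logger.warning(
                    "line %d: unknown evidence code %r; row kept", lineno, evidence
                )
            rows.append((fields[gene_col], term, evidence))
    finally:
        if own:
            fh.close()
    return AnnotationTable(
        pd.DataFrame(rows, columns=["gene", "term", "evidence"]), propagated=False
    )


def write_gaf(table: AnnotationTable, graph: OntologyGraph, path_or_handle) -> None:
    """Serialise annotations as a GAF 2.2 document (inverse of :func:`parse_gaf`)."""
    own = isinstance(path_or_handle, (str, os.PathLike))
    fh = open(path_or_handle, "wt", encoding="utf-8") if own else path_or_handle
    try:
        fh.write("!gaf-version: 2.2\n")
        df = table.records.sort_values(["gene", "term"])
        for gene, term, evidence in df.itertuples(index=False):
            aspect = CATEGORY_TO_ASPECT[graph.category(term)]
            fields = [
                "SYN", gene, gene, "involved_in", term, "SYN_REF:0000001",
                evidence, "", aspect, "", "", "protein", "taxon:9606",
                "20120101", "SYN", "", "",
            ]
            fh.write("\t".join(fields) + "\n")
    finally:
        if own:
            fh.close()


def propagate_true_path(
    annotations: AnnotationTable, graph: OntologyGraph
) -> AnnotationTable:
    """Apply the true-path rule: annotate each gene to every ancestor of each
    of its annotated terms.  Annotations to terms absent from *graph* are
    dropped with a warning."""
    if annotations.propagated:
        raise ValueError("annotations are already true-path propagated")
    unknown = annotations.annotated_terms - set(graph.terms)
    if unknown:
        logger.warning(
            "dropping annotations to %d terms absent from the ontology: %s",
            len(unknown), sorted(unknown)[:5],
        )
    rows = []
    for gene, term, evidence in annotations.records.itertuples(index=False):
        if term in unknown:
            continue
        for target in sorted(graph.ancestors(term, include_self=True)):
            rows.append((gene, target, evidence))
    return AnnotationTable(
        pd.DataFrame(rows, columns=["gene", "term", "evidence"]), propagated=True
    )


def term_frequency(
    term_id: str,
    graph: OntologyGraph,
    annotations: AnnotationTable,
    counting_mode: str = "multiplicity_sum",
) -> int:
    """Annotation frequency of a term including its whole descendant subtree.

    ``multiplicity_sum`` sums the direct annotation counts of the term and of every
    descendant (a gene annotated to two descendants counts twice) and requires
    raw annotations; ``unique_genes`` counts the union of genes.
    """
    if term_id not in graph:
        raise KeyError(f"unknown term {term_id!r}")
    if counting_mode not in ("multiplicity_sum", "unique_genes"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")
    subtree = graph.descendants(term_id, include_self=True)
    gbt = annotations.genes_by_term()
    if counting_mode == "multiplicity_sum":
        if annotations.propagated:
            raise ValueError(
                "multiplicity_sum counting requires raw (unpropagated) annotations"
            )
        return sum(len(gbt.get(t, ())) for t in subtree)
    genes: set[str] = set()
    for t in subtree:
        genes.update(gbt.get(t, ()))
    return len(genes)


def information_content(
    term_id: str,
    graph: OntologyGraph,
    annotations: AnnotationTable,
    counting_mode: str = "multiplicity_sum",
    log_base: float = math.e,
) -> float:
    """``IC(t) = -log(freq(t) / freq(root))`` for the term's category root.

    The root has IC 0; IC never decreases from ancestor to descendant.
    Terms with zero frequency raise :class:`UndefinedInformationContent`.
    """
    root = graph.roots[graph.category(term_id)]
    f_root = term_frequency(root, graph, annotations, counting_mode)
    if f_root == 0:
        raise UndefinedInformationContent(
            f"category root {root} has zero annotation frequency"
        )
    f_t = term_frequency(term_id, graph, annotations, counting_mode)
    if f_t == 0:
        raise UndefinedInformationContent(f"term {term_id} has zero frequency")
    return -math.log(f_t / f_root) / math.log(log_base)


def resnik_similarity(
    term_a: str,
    term_b: str,
    graph: OntologyGraph,
    annotations: AnnotationTable,
    counting_mode: str = "multiplicity_sum",
    log_base: float = math.e,
) -> float:
    """Resnik semantic similarity: IC of the most informative common ancestor.

    In a DAG the "lowest" common ancestor is ambiguous; the standard Resnik
    convention of the common ancestor with maximum IC is used.  Symmetric,
    equals IC(t) for identical terms, and is bounded by the smaller endpoint IC.
    """
    if graph.category(term_a) != graph.category(term_b):
        raise ValueError(
            f"{term_a} and {term_b} belong to different GO categories"
        )
    common = graph.ancestors(term_a, include_self=True) & graph.ancestors(
        term_b, include_self=True
    )
    if not common:
        raise StructuralError(f"{term_a} and {term_b} share no common ancestor")
    return max(
        information_content(t, graph, annotations, counting_mode, log_base)
        for t in common
    )


class InformationContentIndex:
    """Batch IC / Resnik computations over a fixed corpus.

    Precomputes every term's frequency in one pass (each annotated term's
    direct count is added to all of its ancestors), then answers IC and
    pairwise similarity queries from dictionaries.  Produces exactly the same
    values as :func:`information_content` / :func:`resnik_similarity`.
    """

    def __init__(
        self,
        graph: OntologyGraph,
        annotations: AnnotationTable,
        counting_mode: str = "multiplicity_sum",
        log_base: float = math.e,
    ) -> None:
        self.graph = graph
        self.log_base = log_base
        if counting_mode == "multiplicity_sum" and annotations.propagated:
            raise ValueError(
                "multiplicity_sum counting requires raw (unpropagated) annotations"
            )
        freq: dict[str, float] = {}
        if counting_mode == "multiplicity_sum":
            for term, count in annotations.direct_counts().items():
                if term not in graph:
                    continue
                for anc in graph.ancestors(term, include_self=True):
                    freq[anc] = freq.get(anc, 0) + count
        elif counting_mode == "unique_genes":
            acc: dict[str, set[str]] = {}
            for term, genes in annotations.genes_by_term().items():
                if term not in graph:
                    continue
                for anc in graph.ancestors(term, include_self=True):
                    acc.setdefault(anc, set()).update(genes)
            freq = {t: len(g) for t, g in acc.items()}
        else:
            raise ValueError(f"unknown counting_mode {counting_mode!r}")
        self.frequencies = freq
        self._ic: dict[str, float] = {}

    def ic(self, term_id: str) -> float:
        if term_id in self._ic:
            return self._ic[term_id]
        root = self.graph.roots[self.graph.category(term_id)]
        f_root = self.frequencies.get(root, 0)
        f_t = self.frequencies.get(term_id, 0)
        if f_root == 0 or f_t == 0:
            raise UndefinedInformationContent(
                f"term {term_id} has zero annotation frequency"
            )
        value = -math.log(f_t / f_root) / math.log(self.log_base)
        self._ic[term_id] = value
        return value

    def resnik(self, term_a: str, term_b: str) -> float:
        if self.graph.category(term_a) != self.graph.category(term_b):
            raise ValueError(
                f"{term_a} and {term_b} belong to different GO categories"
            )
        common = self.graph.ancestors(term_a, include_self=True) & self.graph.ancestors(
            term_b, include_self=True
        )
        if not common:
            raise StructuralError(
                f"{term_a} and {term_b} share no common ancestor"
            )
        return max(self.ic(t) for t in common if self.frequencies.get(t, 0) > 0)
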