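"""Hypergeometric p-values, Fisher combination, ranks, and top-n term sets.

Each contingency quartet (i, j, k, l) is tested one-sidedly for
over-representation: with X hypergeometric over a population of i+j+k+l
containing i+k successes and a sample of i+j draws, the p-value is
P(X >= i).  The three per-term p-values (rho, tau, mu) are combined with
Fisher's method (-2 * sum(ln p) ~ chi-squared with 2k degrees of freedom),
rank-normalized per measure within a GO category, and turned into top-n term
sets S_theta(n) that can be intersected or united across measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import MEASURES, ContingencyQuartet, QuartetCalculator
from .ontology import AnnotationTable, OntologyGraph, propagate_true_path
from .target_network import MiRNACluster, TargetNetwork

logger = logging.getLogger(__name__)

_TINY = np.nextafter(0.0, 1.0)


def hypergeometric_upper_tail(quartet: ContingencyQuartet | tuple[int, int, int, int]) -> float:
    """Upper-tail hypergeometric p-value P(X >= i) of a contingency quartet.

    Computed through the survival function (never naive factorials), so it is
    overflow-safe for genome-scale universes.  Always in (0, 1]; i = 0 gives
    exactly 1.
    """
    i, j, k, l = quartet.counts if isinstance(quartet, ContingencyQuartet) else quartet
    if min(i, j, k, l) < 0:
        raise ValueError("contingency counts must be nonnegative")
    population = i + j + k + l
    if population == 0:
        raise ValueError("empty universe")
    if i == 0:
        return 1.0
    p = float(stats.hypergeom.sf(i - 1, population, i + k, i + j))
    return min(max(p, _TINY), 1.0)


def fisher_combine(pvalues: Sequence[float], method: str = "fisher") -> float:
    """Combine 2 or 3 p-values into one.

    ``method="fisher"`` (default) is the standard combined-probability test:
    S = -2 * sum(ln p) referred to chi-squared with 2*len(pvalues) degrees of
    freedom.  ``method="one_df"`` uses S = sum(-ln p) with len(pvalues) degrees
    of freedom, a non-standard variant retained for comparability with
    analyses that treated -ln(p) itself as chi-squared(1).  Zero p-values are
    clamped to the smallest positive float with a warning.
    """
    if len(pvalues) not in (2, 3):
        raise ValueError(f"expected 2 or 3 p-values, got {len(pvalues)}")
    clean = []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            logger.warning("p-value of 0 clamped to smallest positive float")
            p = _TINY
        clean.append(p)
    log_sum = -math.fsum(math.log(p) for p in clean)  # fsum: order-invariant
    if method == "fisher":
        stat, df = 2.0 * log_sum, 2 * len(clean)
    elif method == "one_df":
        stat, df = log_sum, len(clean)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    return min(max(float(stats.chi2.sf(stat, df)), _TINY), 1.0)


@dataclass
class EnrichmentRecord:
    """Per-(cluster, term) enrichment result.

    ``quartets`` / ``p`` are keyed by measure name; ``combined`` by the tuple
    of measures entering the Fisher combination; ``ranks`` holds the
    per-category competition rank of each measure's p-value (1 = smallest).
    """

    term_id: str
    name: str
    category: str
    cluster_id: str = ""
    quartets: dict[str, ContingencyQuartet] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    combined: dict[tuple[str, ...], float] = field(default_factory=dict)
    ranks: dict[str, int] = field(default_factory=dict)

    @property
    def p_rho(self) -> float | None:
        return self.p.get("rho")

    @property
    def p_tau(self) -> float | None:
        return self.p.get("tau")

    @property
    def p_mu(self) -> float | None:
        return self.p.get("mu")

    @property
    def p_rho_tau(self) -> float | None:
        return self.combined.get(("rho", "tau"))

    @property
    def p_rho_mu(self) -> float | None:
        return self.combined.get(("rho", "mu"))

    @property
    def p_tau_mu(self) -> float | None:
        return self.combined.get(("tau", "mu"))

    @property
    def p_rho_tau_mu(self) -> float | None:
        return self.combined.get(("rho", "tau", "mu"))


@dataclass(frozen=True)
class TermSet:
    """S_theta(n): the terms whose p-value ranks are <= n for the source
    measure(s), boundary ties included; multi-measure sets are built by
    intersection or union of the single-measure sets."""

    source_measures: tuple[str, ...]
    n: int
    terms: frozenset[str]
    category: str = ""


def _canonical_measures(measures: Iterable[str]) -> tuple[str, ...]:
    measures = set(measures)
    unknown = measures - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures {sorted(unknown)}")
    return tuple(m for m in MEASURES if m in measures)


def enrich_cluster(
    network: TargetNetwork,
    cluster: MiRNACluster,
    graph: OntologyGraph,
    annotations: AnnotationTable,
    category: str = "BP",
    measures: Iterable[str] = MEASURES,
    combine: bool = True,
    combine_method: str = "fisher",
    propagate: bool = True,
) -> list[EnrichmentRecord]:
    """Full per-term enrichment of one miRNA cluster in one GO category.

    Produces one record per non-obsolete term of *category* that has at
    least one annotated gene inside the network's gene universe (the
    enrichment universe is the set of genes with >= 1 predicted link, not
    the whole annotation corpus).  When *propagate* is set and the
    annotations are raw, the true-path closure is applied first, so a gene
    annotated to a term counts for all of the term's ancestors.

    Raises :class:`~mirtrigo.target_network.EmptyClusterError` when the
    cluster has no target gene; callers skip such clusters.
    """
    measures = _canonical_measures(measures)
    if not measures:
        raise ValueError("at least one measure must be requested")
    if propagate and not annotations.propagated:
        annotations = propagate_true_path(annotations, graph)
    calc = QuartetCalculator(network, cluster)
    gene_universe = network.gene_universe
    genes_by_term = annotations.genes_by_term()
    records: list[EnrichmentRecord] = []
    for term_id in graph.terms_in(category):
        annotated = genes_by_term.get(term_id, frozenset()) & gene_universe
        if not annotated:
            continue
        rec = EnrichmentRecord(
            term_id, graph.terms[term_id].name, category, calc.cluster_id
        )
        for m in measures:
            q = calc.quartet(m, annotated, term_id)
            rec.quartets[m] = q
            rec.p[m] = hypergeometric_upper_tail(q)
        if combine and len(measures) >= 2:
            for size in (2, 3):
                for combo in combinations(measures, size):
                    rec.combined[combo] = fisher_combine(
                        [rec.p[m] for m in combo], method=combine_method
                    )
        records.append(rec)
    for m in measures:
        rank_normalize(records, m)
    return records


def rank_normalize(records: list[EnrichmentRecord], measure: str) -> list[EnrichmentRecord]:
    """Assign ascending competition ranks of the measure's p-values in place.

    Rank 1 is the smallest p-value; tied p-values all receive the smallest
    rank of their tied block, so top-n sets include boundary ties.
    """
    if not records:
        return records
    pvals = [r.p[measure] for r in records]
    if any(p is None for p in pvals):
        raise ValueError(f"p-values for measure {measure!r} are not populated")
    ranks = stats.rankdata(pvals, method="min")
    for rec, rank in zip(records, ranks):
        rec.ranks[measure] = int(rank)
    return records


def top_n_set(
    records: list[EnrichmentRecord],
    measures: Iterable[str],
    n: int,
    combine_op: str = "intersection",
) -> TermSet:
    """Build S_theta(n) for one measure or a set-operation combination.

    For a single measure this is the set of terms ranked <= n (ties at the
    boundary included).  For several measures the single-measure sets are
    combined by *combine_op* (``intersection``, the consensus reading, or
    ``union``).
    """
    if n < 1:
        raise ValueError(f"rank threshold n must be >= 1, got {n}")
    measures = _canonical_measures(measures)
    if combine_op not in ("intersection", "union"):
        raise ValueError(f"unknown combine_op {combine_op!r}")
    per_measure = []
    for m in measures:
        if any(m not in r.ranks for r in records):
            raise ValueError(f"ranks for measure {m!r} are not populated")
        per_measure.append({r.term_id for r in records if r.ranks[m] <= n})
    if not per_measure:
        raise ValueError("at least one measure must be requested")
    op = frozenset.intersection if combine_op == "intersection" else frozenset.union
    terms = op(*(frozenset(s) for s in per_measure))
    category = records[0].category if records else ""
    return TermSet(measures, n, frozenset(terms), category)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional diagnostic column)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


# -- tabular output ------------------------------------------------------

_QUARTET_CELLS = ("i", "j", "k", "l")


def records_to_frame(records: list[EnrichmentRecord], bh: bool = False) -> pd.DataFrame:
    """Flatten enrichment records into the results table layout.

    Columns: category, term_id, term_name, then per-measure quartet cells
    (rho_i..rho_l, ...), per-measure p-values, Fisher-combined p-values, and
    per-measure ranks — only for the measures actually computed.  With *bh*
    a q_<measure> Benjamini-Hochberg column is appended per measure.
    """
    if not records:
        return pd.DataFrame(columns=["category", "term_id", "term_name"])
    present = [m for m in MEASURES if all(m in r.p for r in records)]
    combos = [c for c in (("rho", "tau"), ("rho", "mu"), ("tau", "mu"), ("rho", "tau", "mu"))
              if all(c in r.combined for r in records)]
    data: dict[str, list] = {
        "category": [r.category for r in records],
        "term_id": [r.term_id for r in records],
        "term_name": [r.name for r in records],
    }
    for m in present:
        for cell in _QUARTET_CELLS:
            data[f"{m}_{cell}"] = [getattr(r.quartets[m], cell) for r in records]
    for m in present:
        data[f"p_{m}"] = [r.p[m] for r in records]
    for combo in combos:
        data[f"p_{'_'.join(combo)}"] = [r.combined[combo] for r in records]
    for m in present:
        data[f"rank_{m}"] = [r.ranks.get(m) for r in records]
    frame = pd.DataFrame(data)
    if bh:
        for m in present:
            frame[f"q_{m}"] = benjamini_hochberg(frame[f"p_{m}"].to_numpy())
    return frame


def write_results(records: list[EnrichmentRecord], path, bh: bool = False) -> None:
    """Write the results TSV (probabilities with 6 significant digits)."""
    frame = records_to_frame(records, bh=bh)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_results(source) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    return pd.read_csv(source, sep="\t")
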