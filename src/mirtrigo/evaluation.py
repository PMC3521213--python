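"""Scoring of enriched term sets: specificity and functional homogeneity.

Two complementary quality metrics for a set of GO terms: the *average
Information Content* (higher = more specific terms) and the *semantic
similarity density* — the mean Resnik similarity over all unordered distinct
term pairs (higher = more functionally homogeneous set; undefined for sets
of fewer than two terms).  :func:`compare_measures` evaluates both metrics
for the seven measure combinations {rho, tau, mu, rho&tau, rho&mu, tau&mu,
rho&tau&mu} across a grid of rank thresholds n, producing a tidy long-format
report.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contingency import MEASURES
from .enrichment import EnrichmentRecord, TermSet, records_to_frame
from .ontology import (
    AnnotationTable,
    InformationContentIndex,
    OntologyGraph,
    UndefinedInformationContent,
)

logger = logging.getLogger(__name__)

#: The seven measure combinations of the evaluation protocol.
MEASURE_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("rho",), ("tau",), ("mu",),
    ("rho", "tau"), ("rho", "mu"), ("tau", "mu"),
    ("rho", "tau", "mu"),
)


def _term_ids(s: TermSet | Iterable[str]) -> list[str]:
    terms = s.terms if isinstance(s, TermSet) else s
    return sorted(terms)


def average_information_content(
    s: TermSet | Iterable[str],
    graph: OntologyGraph,
    annotations: AnnotationTable,
    counting_mode: str = "multiplicity_sum",
    log_base: float = math.e,
    ic_index: InformationContentIndex | None = None,
) -> float:
    """Arithmetic mean IC of a term set (the set's average specificity).

    Terms with undefined IC (zero annotation frequency) are excluded with a
    warning; an empty set is an error.
    """
    terms = _term_ids(s)
    if not terms:
        raise ValueError("cannot average the IC of an empty term set")
    idx = ic_index or InformationContentIndex(graph, annotations, counting_mode, log_base)
    values = []
    for t in terms:
        try:
            values.append(idx.ic(t))
        except UndefinedInformationContent:
            logger.warning("term %s has undefined IC; excluded from the average", t)
    if not values:
        raise ValueError("no term in the set has a defined IC")
    return float(np.mean(values))


def semantic_similarity_density(
    s: TermSet | Iterable[str],
    graph: OntologyGraph,
    annotations: AnnotationTable,
    counting_mode: str = "multiplicity_sum",
    log_base: float = math.e,
    ic_index: InformationContentIndex | None = None,
) -> float | None:
    """Mean pairwise Resnik similarity over all unordered distinct pairs.

    Self-pairs are excluded, so a singleton (or empty) set has no defined
    density and ``None`` is returned.
    """
    terms = _term_ids(s)
    if len(terms) < 2:
        return None
    idx = ic_index or InformationContentIndex(graph, annotations, counting_mode, log_base)
    sims = [idx.resnik(a, b) for a, b in _combinations(terms, 2)]
    return float(np.mean(sims))


def _combination_label(measures: tuple[str, ...]) -> str:
    return ",".join(measures)


def compare_measures(
    results: list[EnrichmentRecord] | pd.DataFrame,
    graph: OntologyGraph,
    annotations: AnnotationTable,
    n_grid: Sequence[int],
    counting_mode: str = "multiplicity_sum",
    log_base: float = math.e,
    combine_op: str = "intersection",
) -> pd.DataFrame:
    """Evaluate all seven measure combinations across rank thresholds.

    *results* is either the record list from
    :func:`~mirtrigo.enrichment.enrich_cluster` or a results table with
    ``term_id`` and ``rank_rho`` / ``rank_tau`` / ``rank_mu`` columns.
    Returns a long-format frame with one row per (combination, n):
    ``combination, n, set_size, average_ic, semsim_density, truncated``.
    Combination sets are built by set operation on the single-measure top-n
    sets; an n beyond the table size evaluates the full set and flags the
    row as truncated.  Empty sets and singletons yield NaN metrics.
    """
    frame = results if isinstance(results, pd.DataFrame) else records_to_frame(results)
    for m in MEASURES:
        if f"rank_{m}" not in frame.columns:
            raise ValueError(f"results table lacks required column rank_{m}")
    if combine_op not in ("intersection", "union"):
        raise ValueError(f"unknown combine_op {combine_op!r}")
    setop = set.intersection if combine_op == "intersection" else set.union
    idx = InformationContentIndex(graph, annotations, counting_mode, log_base)
    n_terms = len(frame)
    rows = []
    for measures in MEASURE_COMBINATIONS:
        for n in n_grid:
            if n < 1:
                raise ValueError(f"rank threshold n must be >= 1, got {n}")
            per_measure = [
                set(frame.loc[frame[f"rank_{m}"] <= n, "term_id"]) for m in measures
            ]
            terms = setop(*per_measure)
            avg_ic = (
                average_information_content(terms, graph, annotations, ic_index=idx)
                if terms else float("nan")
            )
            density = semantic_similarity_density(
                terms, graph, annotations, ic_index=idx
            )
            rows.append(
                {
                    "combination": _combination_label(measures),
                    "n": int(n),
                    "set_size": len(terms),
                    "average_ic": avg_ic,
                    "semsim_density": float("nan") if density is None else density,
                    "truncated": bool(n > n_terms),
                }
            )
    return pd.DataFrame(rows)


def pvalue_histogram(
    pvalues: Sequence[float], n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Counts and edges of an equal-width p-value histogram on [0, 1]
    (diagnostic for the shape of a measure's p-value distribution)."""
    return np.histogram(np.asarray(pvalues, dtype=float), bins=n_bins, range=(0.0, 1.0))


def plot_comparison(report: pd.DataFrame, path, metric: str = "average_ic") -> None:
    """Line chart of one evaluation metric against n, one line per measure
    combination.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for combo, group in report.groupby("combination"):
        group = group.sort_values("n")
        ax.plot(group["n"], group[metric], marker="o", label=combo)
    ax.set_xlabel("rank threshold n")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
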