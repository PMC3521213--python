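"""The miRNA -> target gene link layer.

A :class:`TargetNetwork` is an unweighted, deduplicated set of
(miRNA, gene) links; it defines the three universes of the tri-partite
framework — the miRNAs, the links, and the target genes.  When the input
table carries one 0/1 column per target-prediction algorithm, a
:class:`PredictionVoteTable` is built instead, from which filtered networks
("variations") are derived by vote-count rules: pairs supported by exactly v
algorithms, by lo..hi algorithms, or by lo..hi algorithms including one named
algorithm.  Raising the required number of positive voters can only shrink
the network.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd

logger = logging.getLogger(__name__)


class EmptyClusterError(ValueError):
    """Raised when a miRNA cluster has no member in the network's miRNA
    universe (and hence no target gene); callers typically skip the cluster."""


def _normalize_mirna(m: str) -> str:
    # miRNA ids are compared case-insensitively after trimming.
    return str(m).strip().lower()


class TargetNetwork:
    """Deduplicated miRNA -> gene links with precomputed adjacency."""

    def __init__(self, links: Iterable[tuple[str, str]]) -> None:
        self.links: frozenset[tuple[str, str]] = frozenset(
            (_normalize_mirna(m), str(g).strip()) for m, g in links
        )
        targets: dict[str, set[str]] = {}
        regulators: dict[str, set[str]] = {}
        for m, g in self.links:
            targets.setdefault(m, set()).add(g)
            regulators.setdefault(g, set()).add(m)
        self._targets = {m: frozenset(gs) for m, gs in targets.items()}
        self._regulators = {g: frozenset(ms) for g, ms in regulators.items()}

    @property
    def mirna_universe(self) -> frozenset[str]:
        return frozenset(self._targets)

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(self._regulators)

    @property
    def link_universe_size(self) -> int:
        return len(self.links)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self._targets.get(_normalize_mirna(mirna), frozenset())

    def regulators_of(self, gene: str) -> frozenset[str]:
        return self._regulators.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self.links)

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetNetwork) and self.links == other.links

    def __hash__(self) -> int:
        return hash(self.links)


@dataclass(frozen=True)
class MiRNACluster:
    """A named set of miRNAs under investigation (e.g. a co-expression
    cluster).  Members absent from a network's miRNA universe are dropped
    with a warning at analysis time."""

    cluster_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "members", frozenset(_normalize_mirna(m) for m in self.members)
        )
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")


# -- vote tables and variations -----------------------------------------


@dataclass(frozen=True)
class ExactVotes:
    """Keep pairs supported by exactly *v* positively voting algorithms."""

    v: int


@dataclass(frozen=True)
class VoteRange:
    """Keep pairs whose positive-vote count lies in [lo, hi]; when
    *including* names an algorithm, that algorithm must itself have voted
    positive for the pair."""

    lo: int
    hi: int
    including: str | None = None


VariationRule = Union[ExactVotes, VoteRange]


class PredictionVoteTable:
    """Per-pair positive/negative votes of target-prediction algorithms.

    Stored as a wide frame: one row per (mirna, gene) pair, one 0/1 column
    per algorithm, in the input's column order.
    """

    def __init__(self, frame: pd.DataFrame, algorithms: list[str]) -> None:
        missing = [a for a in algorithms if a not in frame.columns]
        if missing:
            raise ValueError(f"algorithm columns missing from frame: {missing}")
        self.algorithms = list(algorithms)
        self.frame = frame.loc[:, ["mirna", "gene", *self.algorithms]].reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    def positive_votes(self) -> pd.Series:
        """Number of positively voting algorithms per pair."""
        return self.frame[self.algorithms].sum(axis=1)


def read_target_pairs(source) -> PredictionVoteTable | TargetNetwork:
    """Read a miRNA-target pair TSV.

    Mandatory columns ``mirna`` and ``gene``; any further columns are taken
    as per-algorithm 0/1 vote columns and yield a
    :class:`PredictionVoteTable`, otherwise a bare :class:`TargetNetwork`.
    Duplicate (mirna, gene) rows are deduplicated with a warning.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ("mirna", "gene"):
        if col not in df.columns:
            raise ValueError(f"target-pair table lacks mandatory column {col!r}")
    df["mirna"] = df["mirna"].map(_normalize_mirna)
    df["gene"] = df["gene"].str.strip()
    dups = df.duplicated(subset=["mirna", "gene"]).sum()
    if dups:
        logger.warning("dropping %d duplicate (mirna, gene) rows", dups)
        df = df.drop_duplicates(subset=["mirna", "gene"], keep="first")
    algorithms = [c for c in df.columns if c not in ("mirna", "gene")]
    if not algorithms:
        return TargetNetwork(zip(df["mirna"], df["gene"]))
    votes = df[algorithms].astype(int)
    if not votes.isin((0, 1)).all().all():
        raise ValueError("algorithm vote columns must contain only 0/1 values")
    df[algorithms] = votes
    return PredictionVoteTable(df, algorithms)


def build_variation(votes: PredictionVoteTable, rule: VariationRule) -> TargetNetwork:
    """Filter a vote table down to a :class:`TargetNetwork` by a vote rule."""
    n_alg = len(votes.algorithms)
    counts = votes.positive_votes()
    if isinstance(rule, ExactVotes):
        if not 0 <= rule.v <= n_alg:
            raise ValueError(f"exact_votes {rule.v} outside [0, {n_alg}]")
        keep = counts == rule.v
    elif isinstance(rule, VoteRange):
        if not (0 <= rule.lo <= rule.hi <= n_alg):
            raise ValueError(f"vote_range [{rule.lo}, {rule.hi}] outside [0, {n_alg}]")
        keep = (counts >= rule.lo) & (counts <= rule.hi)
        if rule.including is not None:
            if rule.including not in votes.algorithms:
                raise KeyError(f"unknown algorithm {rule.including!r}")
            keep &= votes.frame[rule.including] == 1
    else:
        raise TypeError(f"unknown variation rule {rule!r}")
    kept = votes.frame.loc[keep, ["mirna", "gene"]]
    return TargetNetwork(zip(kept["mirna"], kept["gene"]))


def target_gene_cluster(
    network: TargetNetwork, cluster: MiRNACluster
) -> frozenset[str]:
    """All genes targeted by at least one cluster member.

    Members absent from the miRNA universe are ignored; a cluster with no
    member in the universe raises :class:`EmptyClusterError`.
    """
    members = cluster.members & network.mirna_universe
    if not members:
        raise EmptyClusterError(
            f"cluster {cluster.cluster_id!r} has no member in the miRNA universe"
        )
    genes: set[str] = set()
    for m in members:
        genes.update(network.targets_of(m))
    return frozenset(genes)


def read_clusters(source) -> list[MiRNACluster]:
    """Read a long-format cluster TSV (columns ``cluster_id``, ``mirna``)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    for col in ("cluster_id", "mirna"):
        if col not in df.columns:
            raise ValueError(f"cluster table lacks mandatory column {col!r}")
    return [
        MiRNACluster(cid, frozenset(group))
        for cid, group in df.groupby("cluster_id", sort=True)["mirna"]
    ]


def write_target_pairs(network: TargetNetwork, path_or_handle) -> None:
    """Write a bare pair table (inverse of :func:`read_target_pairs`)."""
    own = isinstance(path_or_handle, (str, os.PathLike))
    fh = open(path_or_handle, "wt", encoding="utf-8") if own else path_or_handle
    try:
        fh.write("mirna\tgene\n")
        for m, g in sorted(network.links):
            fh.write(f"{m}\t{g}\n")
    finally:
        if own:
            fh.close()


def write_clusters(clusters: Iterable[MiRNACluster], path_or_handle) -> None:
    own = isinstance(path_or_handle, (str, os.PathLike))
    fh = open(path_or_handle, "wt", encoding="utf-8") if own else path_or_handle
    try:
        fh.write("cluster_id\tmirna\n")
        for cluster in clusters:
            for m in sorted(cluster.members):
                fh.write(f"{cluster.cluster_id}\t{m}\n")
    finally:
        if own:
            fh.close()
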