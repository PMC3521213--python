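"""Shared fixtures: a hand-built toy GO corpus, a seeded synthetic scenario,
and the replicate studies (null calibration / planted-term power) that
several test modules share."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirtrigo as mt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000002
name: alpha
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: beta
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000004
name: gamma
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000005
name: delta
namespace: biological_process
is_a: GO:0000003
is_a: GO:0000004

[Term]
id: GO:0000006
name: mf root
namespace: molecular_function

[Term]
id: GO:0000007
name: mf leaf
namespace: molecular_function
is_a: GO:0000006

[Term]
id: GO:0000008
name: retired
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def toy_graph() -> mt.OntologyGraph:
    return mt.parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture
def toy_annotations() -> mt.AnnotationTable:
    # raw (unpropagated) annotations over the toy DAG
    return mt.AnnotationTable.from_pairs(
        [
            ("gA", "GO:0000005"),
            ("gB", "GO:0000005"),
            ("gC", "GO:0000003"),
            ("gD", "GO:0000004"),
            ("gE", "GO:0000002"),
            ("gF", "GO:0000004"),
            ("gA", "GO:0000003"),
            ("gG", "GO:0000007"),
        ]
    )


@pytest.fixture(scope="session")
def scenario() -> mt.Scenario:
    """One planted-signal scenario at default scale."""
    return mt.generate_scenario(mt.ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def scenario_records(scenario) -> list[mt.EnrichmentRecord]:
    return mt.enrich_cluster(
        scenario.network, scenario.cluster, scenario.graph, scenario.annotations
    )


@dataclass(frozen=True)
class NullStudy:
    """200 null replicates (no planted signal) of the miRNA-centric test."""

    n_replicates: int
    n_terms_total: int
    n_significant: int  # terms with p_mu < 0.05, pooled over replicates
    all_pvalues: np.ndarray
    planted_pvalues: np.ndarray  # the designated term's p_mu per replicate


@pytest.fixture(scope="session")
def null_study() -> NullStudy:
    n_sig = 0
    n_tot = 0
    all_ps: list[float] = []
    planted_ps: list[float] = []
    for rep in range(200):
        sc = mt.generate_scenario(
            mt.ScenarioConfig(planted_term_fraction=0.0, seed=10_000 + rep)
        )
        records = mt.enrich_cluster(
            sc.network, sc.cluster, sc.graph, sc.annotations,
            measures=("mu",), combine=False,
        )
        ps = [r.p["mu"] for r in records]
        n_sig += sum(p < 0.05 for p in ps)
        n_tot += len(ps)
        all_ps.extend(ps)
        if sc.planted_term is not None:
            rec = next((r for r in records if r.term_id == sc.planted_term), None)
            if rec is not None:
                planted_ps.append(rec.p["mu"])
    return NullStudy(200, n_tot, n_sig, np.array(all_ps), np.array(planted_ps))


@dataclass(frozen=True)
class PowerStudy:
    """100 strong-alternative replicates (planting probability 0.9)."""

    n_replicates: int
    planted_pvalues: np.ndarray
    planted_ranks: np.ndarray


@pytest.fixture(scope="session")
def power_study() -> PowerStudy:
    ps: list[float] = []
    ranks: list[int] = []
    for rep in range(100):
        sc = mt.generate_scenario(
            mt.ScenarioConfig(planted_term_fraction=0.9, seed=20_000 + rep)
        )
        records = mt.enrich_cluster(
            sc.network, sc.cluster, sc.graph, sc.annotations,
            measures=("mu",), combine=False,
        )
        rec = next(r for r in records if r.term_id == sc.planted_term)
        ps.append(rec.p["mu"])
        ranks.append(rec.ranks["mu"])
    return PowerStudy(100, np.array(ps), np.array(ranks))
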