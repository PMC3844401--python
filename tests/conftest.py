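"""Shared fixtures: synthetic panels and independent query oracles."""

from __future__ import annotations

import numpy as np
import pytest

from obams import (
    BuildConfig,
    OntologyGraph,
    OntologyTerm,
    build_comparison_ontology,
    plant_markers,
    simulate_expression,
    simulate_ontology,
)
from obams.ontology import IS_A
from obams.synthio import PopulationPanel


def make_term(graph: OntologyGraph, tid: str, name: str, *parents: str) -> str:
    graph.add_term(
        OntologyTerm(id=tid, name=name, parents=[(IS_A, p) for p in parents])
    )
    return tid


def build_lymphocyte_panel(
    n_b: int = 8, n_nk: int = 16, n_t: int = 16
) -> tuple[PopulationPanel, dict[str, str]]:
    """The mature-lymphocyte panel shape: a shared parent with a B branch
    (n_b mapped subtypes) and NK/T branches (n_nk + n_t mapped subtypes).

    Returns the panel plus a name->id map for the named branch classes.
    """
    g = OntologyGraph()
    ids = {}
    ids["mature lymphocyte"] = make_term(g, "CLX:0000001", "mature lymphocyte")
    ids["mature B cell"] = make_term(g, "CLX:0000002", "mature B cell", ids["mature lymphocyte"])
    ids["mature NK cell"] = make_term(g, "CLX:0000003", "mature NK cell", ids["mature lymphocyte"])
    ids["mature T cell"] = make_term(g, "CLX:0000004", "mature T cell", ids["mature lymphocyte"])
    n = 5
    p2c = {}
    for prefix, branch, count in (("b", "mature B cell", n_b),
                                  ("nk", "mature NK cell", n_nk),
                                  ("t", "mature T cell", n_t)):
        for i in range(count):
            tid = make_term(g, f"CLX:{n:07d}", f"{prefix} subtype {i}", ids[branch])
            p2c[f"{prefix}{i}"] = tid
            n += 1
    g.validate()
    return PopulationPanel(g, p2c), ids


def reachable(graph: OntologyGraph, start: str) -> set[str]:
    """Independent is_a reachability oracle: exhaustive path search, no reuse
    of the closure implementation."""
    seen: set[str] = set()

    def walk(node: str) -> None:
        for rel, parent in graph.terms[node].parents:
            if rel == IS_A and parent not in seen:
                seen.add(parent)
                walk(parent)

    walk(start)
    return seen


def brute_force_query(co, focus: str, reference: str, direction: str):
    """Predicate-filter every comparison class using the path-search oracle."""
    desc_x = {t for t in co.graph.terms if focus in reachable(co.graph, t) or t == focus}
    desc_y = {t for t in co.graph.terms if reference in reachable(co.graph, t) or t == reference}
    out = []
    for gsid in sorted(co.comparisons):
        c = co.comparisons[gsid]
        a, b = (c.up_class, c.down_class) if direction == "up" else (c.down_class, c.up_class)
        if a in desc_x and b in desc_y and b not in desc_x:
            out.append(c)
    return out


def random_dag_panel(rng: np.random.Generator) -> PopulationPanel:
    """Random multi-parent is_a DAG with <= 12 mapped populations."""
    n_classes = int(rng.integers(5, 15))
    g = OntologyGraph()
    ids = [f"RND:{i:07d}" for i in range(n_classes)]
    for i, tid in enumerate(ids):
        # parents only among earlier nodes -> acyclic by construction
        n_par = 0 if i == 0 else int(rng.integers(1, min(i, 3) + 1))
        parents = list(rng.choice(i, size=n_par, replace=False)) if n_par else []
        make_term(g, tid, f"random class {i}", *[ids[int(p)] for p in parents])
    g.validate()
    n_pops = int(rng.integers(2, 13))
    classes = rng.choice(n_classes, size=n_pops, replace=True)
    p2c = {f"pop{i}": ids[int(c)] for i, c in enumerate(classes)}
    return PopulationPanel(g, p2c)


@pytest.fixture(scope="session")
def noiseless_build():
    """2-level, 3-branch panel, 4-fold planted markers, no noise."""
    panel = simulate_ontology(levels=2, branching=3, seed=11)
    truth = plant_markers(panel, markers_per_class=5, down_markers_per_class=2,
                          n_background=50, delta=2.0, replicates=3, sigma=0.0,
                          seed=11)
    matrix, sheet = simulate_expression(truth, panel)
    co = build_comparison_ontology(panel.graph, sheet, matrix, BuildConfig())
    return panel, truth, co


@pytest.fixture(scope="session")
def lymphocyte_build():
    """The 8 + 32 mature-lymphocyte panel with a built comparison ontology."""
    panel, ids = build_lymphocyte_panel()
    truth = plant_markers(panel, markers_per_class=2, n_background=20,
                          delta=2.0, replicates=2, sigma=0.0, seed=5)
    matrix, sheet = simulate_expression(truth, panel)
    co = build_comparison_ontology(panel.graph, sheet, matrix)
    return panel, ids, co
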