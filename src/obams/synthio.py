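"""Synthetic ontologies and expression panels with planted markers.

The generator emulates the statistical structure the signature method
assumes: a balanced is_a tree of cell-type classes whose leaves are sampled
populations, and genes planted as branch-specific markers.  A marker of
class ``a`` receives a fixed log2 offset (the effect size) in every
population descending from ``a``; effects add along the ancestor chain so
class-level and subclass-level markers coexist, mirroring the layered
signatures (pan-branch / branch / subtype) the method recovers on real
panels.  Replicate noise is Gaussian on the log2 scale, matching
RMA-normalized intensities.

Defaults reflect a small but realistic microarray panel: baseline log2
intensity 8 +/- 1 across genes, replicate noise sd 0.25, three replicates
per population, 4-fold (log2 effect 2) planted markers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix, SampleSheet
from .errors import ValidationError
from .ontology import IS_A, OntologyGraph, OntologyTerm, closure
from .signature import Signature

__all__ = [
    "PopulationPanel",
    "SyntheticTruth",
    "RecoveryScore",
    "simulate_ontology",
    "plant_markers",
    "simulate_expression",
    "score_recovery",
    "write_inputs",
]


@dataclass
class PopulationPanel:
    """A synthetic ontology with one mapped population per leaf class."""

    graph: OntologyGraph
    population_to_class: dict[str, str]

    @property
    def populations(self) -> list[str]:
        return sorted(self.population_to_class)

    def sample_sheet(self, replicates: int) -> SampleSheet:
        s2p = {
            f"{pop}_r{i + 1}": pop
            for pop in self.populations
            for i in range(replicates)
        }
        return SampleSheet(s2p, dict(self.population_to_class))


@dataclass
class SyntheticTruth:
    """Planted marker assignment plus the simulation parameters.

    ``up_effects``/``down_effects`` map class -> {gene: |log2 effect|}; an up
    marker of a class is shifted up by its effect in every population below
    that class, a down marker shifted down.
    """

    up_effects: dict[str, dict[str, float]]
    down_effects: dict[str, dict[str, float]]
    genes: list[str]
    replicates: int = 3
    sigma: float = 0.25
    mu0: float = 8.0
    tau: float = 1.0
    seed: int = 0

    def planted(self, cls: str, direction: str = "up") -> dict[str, float]:
        table = self.up_effects if direction == "up" else self.down_effects
        if cls not in table:
            raise ValidationError(f"class {cls!r} has no planted {direction} markers")
        return table[cls]

    def to_json(self) -> str:
        return json.dumps(
            {
                "up_effects": self.up_effects,
                "down_effects": self.down_effects,
                "genes": self.genes,
                "replicates": self.replicates,
                "sigma": self.sigma,
                "mu0": self.mu0,
                "tau": self.tau,
                "seed": self.seed,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


@dataclass
class RecoveryScore:
    """Precision/recall of a signature against the planted truth.

    An empty signature has undefined precision; by convention it is reported
    as 1 with ``precision_defined=False``.
    """

    precision: float
    recall: float
    precision_defined: bool = True


def simulate_ontology(
    levels: int, branching: int, seed: int = 0, prefix: str = "SYN"
) -> PopulationPanel:
    """Balanced is_a tree: ``branching**levels`` leaves, one population each.

    Ids are assigned breadth-first and deterministically; the seed is part of
    the panel identity but the topology depends only on (levels, branching).
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    if branching < 2:
        raise ValidationError("branching must be >= 2")
    graph = OntologyGraph()
    counter = 1

    def new_term(name: str, parent: str | None) -> str:
        nonlocal counter
        tid = f"{prefix}:{counter:07d}"
        counter += 1
        parents = [(IS_A, parent)] if parent else []
        graph.add_term(OntologyTerm(id=tid, name=name, parents=parents))
        return tid

    root = new_term("cell type root", None)
    frontier = [(root, "c")]
    for _ in range(levels):
        nxt = []
        for parent_id, label in frontier:
            for b in range(1, branching + 1):
                child_label = f"{label}{b}"
                nxt.append((new_term(f"cell type {child_label}", parent_id), child_label))
        frontier = nxt
    graph.validate()
    population_to_class = {f"pop_{label}": tid for tid, label in frontier}
    return PopulationPanel(graph=graph, population_to_class=population_to_class)


def plant_markers(
    panel: PopulationPanel,
    markers_per_class: int = 5,
    n_background: int = 200,
    delta: float = 2.0,
    down_markers_per_class: int = 0,
    replicates: int = 3,
    sigma: float = 0.25,
    mu0: float = 8.0,
    tau: float = 1.0,
    seed: int = 0,
    classes: list[str] | None = None,
) -> SyntheticTruth:
    """Assign disjoint marker genes to every non-root class (or ``classes``).

    Each chosen class gets ``markers_per_class`` up markers (and optionally
    down markers) of log2 effect ``delta``; ``n_background`` genes carry no
    effect anywhere.
    """
    graph = panel.graph
    if classes is None:
        roots = set(graph.roots())
        classes = sorted(t for t in graph.terms if t not in roots)
    up_effects: dict[str, dict[str, float]] = {}
    down_effects: dict[str, dict[str, float]] = {}
    genes: list[str] = []
    counter = 1

    def next_gene() -> str:
        nonlocal counter
        g = f"g{counter:06d}"
        counter += 1
        genes.append(g)
        return g

    for cls in classes:
        up_effects[cls] = {next_gene(): float(delta) for _ in range(markers_per_class)}
        down_effects[cls] = {
            next_gene(): float(delta) for _ in range(down_markers_per_class)
        }
    for _ in range(n_background):
        next_gene()
    return SyntheticTruth(
        up_effects=up_effects,
        down_effects=down_effects,
        genes=genes,
        replicates=replicates,
        sigma=sigma,
        mu0=mu0,
        tau=tau,
        seed=seed,
    )


def simulate_expression(
    truth: SyntheticTruth, panel: PopulationPanel
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Draw the log2 expression matrix implied by the planted truth.

    value(g, sample of population p) = baseline(g)
        + sum over reflexive ancestors a of p's class of effect(a, g)
        + N(0, sigma^2),
    with baseline(g) ~ N(mu0, tau^2) drawn once per gene.  Fully reproducible
    from ``truth.seed``.
    """
    unknown = sorted(
        (set(truth.up_effects) | set(truth.down_effects)) - set(panel.graph.terms)
    )
    if unknown:
        raise ValidationError("truth references classes absent from panel: " + ", ".join(unknown))

    sheet = panel.sample_sheet(truth.replicates)
    samples = sorted(sheet.sample_to_population)
    genes = truth.genes
    gene_idx = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(truth.seed)
    baseline = rng.normal(truth.mu0, truth.tau, size=len(genes))

    # per-class cumulative offsets for each population (signed effects)
    offsets: dict[str, np.ndarray] = {}
    for pop, cls in panel.population_to_class.items():
        off = np.zeros(len(genes))
        anc = closure(panel.graph, cls, direction="up", reflexive=True)
        for a in anc:
            for g, eff in truth.up_effects.get(a, {}).items():
                off[gene_idx[g]] += eff
            for g, eff in truth.down_effects.get(a, {}).items():
                off[gene_idx[g]] -= eff
        offsets[pop] = off

    values = np.empty((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        pop = sheet.sample_to_population[sample]
        noise = rng.normal(0.0, truth.sigma, size=len(genes)) if truth.sigma > 0 else 0.0
        values[:, j] = baseline + offsets[pop] + noise
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    return matrix, sheet


def score_recovery(sig: Signature, truth: SyntheticTruth, cls: str) -> RecoveryScore:
    """Precision and recall of a signature's genes against the planted set of
    ``cls`` in the signature's direction."""
    planted = set(truth.planted(cls, sig.query.direction))
    found = set(sig.genes)
    hits = len(found & planted)
    if not found:
        precision, defined = (1.0, bool(not planted))
    else:
        precision, defined = hits / len(found), True
    recall = 1.0 if not planted else hits / len(planted)
    return RecoveryScore(precision=precision, recall=recall, precision_defined=defined)


def write_inputs(
    truth: SyntheticTruth, panel: PopulationPanel, outdir: str
) -> dict[str, str]:
    """Write the standard pipeline inputs (OBO, matrix TSV, sheet TSV, truth
    JSON) to ``outdir``; returns the paths written."""
    import os

    from .ontology import write_obo

    os.makedirs(outdir, exist_ok=True)
    matrix, sheet = simulate_expression(truth, panel)
    paths = {
        "ontology": os.path.join(outdir, "ontology.obo"),
        "matrix": os.path.join(outdir, "matrix.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    with open(paths["ontology"], "w") as fh:
        fh.write(write_obo(panel.graph))
    matrix.write_tsv(paths["matrix"])
    sheet.write_tsv(paths["samples"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
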