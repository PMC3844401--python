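"""Materialize pairwise comparisons as ontology classes ("CL-pairwise").

Every ordered population pair (i, j), i != j, becomes one gene-set class in a
dedicated GS namespace holding the genes up in i vs j (and, mirrored, the
genes down).  Each class is a subclass of the "mature immune cell
comparisons" hub (GS:0000001, itself under a second root "Gene-sets") and
carries exactly one ``has_up_regulated_genes_for`` edge to the up
population's cell-type class and one ``has_down_regulated_genes_for`` edge to
the down population's class.  Those typed edges are what make molecular
signatures queryable by ontology subsumption.

Gene contents are not serialized in OBO (which has no payload tag for gene
lists); they live in a GMT sidecar keyed by GS id, so the ontology stays
readable by standard OBO tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .diffexpr import ExpressionMatrix, SampleSheet, moderated_de, threshold_gene_sets
from .errors import ValidationError
from .ontology import IS_A, OntologyGraph, OntologyTerm, closure, parse_obo, write_obo

__all__ = [
    "UP_RELATION",
    "DOWN_RELATION",
    "BuildConfig",
    "ComparisonGeneSet",
    "ComparisonOntology",
    "build_comparison_ontology",
    "export_comparison_obo",
    "export_gene_sets_gmt",
    "load_comparison_ontology",
    "map_populations",
]

UP_RELATION = "has_up_regulated_genes_for"
DOWN_RELATION = "has_down_regulated_genes_for"
# the short relation names are accepted as read-aliases of the canonical ones
RELATION_ALIASES = {
    "has_up_regulated_genes": UP_RELATION,
    "has_down_regulated_genes": DOWN_RELATION,
}

GS_ROOT = "GS:0000000"
GS_HUB = "GS:0000001"


@dataclass
class BuildConfig:
    """Thresholds and naming used when building the comparison ontology."""

    fold_threshold: float = 1.5
    alpha: float = 0.05
    min_replicates: int = 2
    gs_prefix: str = "GS"
    up_relation: str = UP_RELATION
    down_relation: str = DOWN_RELATION

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ComparisonGeneSet:
    """One comparison class s_(i,j): genes up in population i vs population j."""

    id: str
    up_population: str
    down_population: str
    up_class: str
    down_class: str
    up_genes: dict[str, float] = field(default_factory=dict)
    down_genes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up_population == self.down_population:
            raise ValidationError("a comparison needs two distinct populations")
        if any(fc <= 0 for fc in self.up_genes.values()):
            raise ValidationError(f"{self.id}: up_genes must have positive log2FC")
        if any(fc >= 0 for fc in self.down_genes.values()):
            raise ValidationError(f"{self.id}: down_genes must have negative log2FC")


class ComparisonOntology:
    """Base ontology augmented with one gene-set class per ordered pair."""

    def __init__(
        self,
        graph: OntologyGraph,
        comparisons: dict[str, ComparisonGeneSet],
        population_to_class: Mapping[str, str],
        config: BuildConfig,
    ):
        self.graph = graph
        self.comparisons = comparisons
        self.population_to_class = dict(population_to_class)
        self.config = config
        self.by_pair: dict[tuple[str, str], str] = {
            (c.up_population, c.down_population): gsid for gsid, c in comparisons.items()
        }

    @property
    def populations(self) -> list[str]:
        return sorted(self.population_to_class)

    def populations_under(self, term: str) -> list[str]:
        """Populations mapped to the reflexive is_a descendants of ``term``."""
        desc = closure(self.graph, term, direction="down", reflexive=True)
        return sorted(p for p, c in self.population_to_class.items() if c in desc)

    def comparison_for(self, up_population: str, down_population: str) -> ComparisonGeneSet:
        gsid = self.by_pair.get((up_population, down_population))
        if gsid is None:
            raise ValidationError(
                f"no comparison class for pair ({up_population!r}, {down_population!r})"
            )
        return self.comparisons[gsid]


def map_populations(
    names: Iterable[str],
    graph: OntologyGraph,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map population labels to ontology classes by exact (case-insensitive)
    name match; unmatched labels must be resolved through ``overrides`` (the
    manual-review hook).  Several labels may map to one class."""
    overrides = dict(overrides or {})
    by_name: dict[str, str] = {}
    ambiguous: set[str] = set()
    for t in graph.terms.values():
        if t.obsolete or not t.name:
            continue
        key = t.name.lower()
        if key in by_name and by_name[key] != t.id:
            ambiguous.add(key)
        by_name[key] = t.id

    out: dict[str, str] = {}
    unmatched: list[str] = []
    for label in names:
        if label in overrides:
            curie = overrides[label]
            if curie not in graph:
                raise ValidationError(f"override for {label!r} names unknown class {curie}")
            out[label] = curie
        elif label.lower() in ambiguous:
            raise ValidationError(
                f"label {label!r} matches more than one term name; add an override"
            )
        elif label.lower() in by_name:
            out[label] = by_name[label.lower()]
        else:
            unmatched.append(label)
    if unmatched:
        raise ValidationError(
            "unmatched population labels (add overrides): " + ", ".join(sorted(unmatched))
        )
    return out


def _gs_id(prefix: str, n: int) -> str:
    return f"{prefix}:{n:07d}"


def build_comparison_ontology(
    graph: OntologyGraph,
    sheet: SampleSheet,
    matrix: ExpressionMatrix,
    config: BuildConfig | None = None,
) -> ComparisonOntology:
    """Run the full pairwise analysis and attach every comparison to the
    ontology.

    For each ordered pair of populations a moderated-t contrast is computed
    and thresholded; the resulting gene-set class gets a deterministic GS id
    assigned by sorted (up_population, down_population) order starting at
    GS:0000002.  n populations yield exactly n*(n-1) comparison classes and
    2*n*(n-1) directional relations.
    """
    config = config or BuildConfig()
    pops = sheet.populations
    bad = sorted(p for p in pops if " vs " in p)
    if bad:
        raise ValidationError(
            "population labels may not contain ' vs ' (reserved): " + ", ".join(bad)
        )
    unknown = sorted(
        {c for c in (sheet.population_to_class[p] for p in pops) if c not in graph}
    )
    if unknown:
        raise ValidationError("populations mapped to unknown classes: " + ", ".join(unknown))

    # one DE fit per unordered pair; the reverse is its mirror
    gene_sets: dict[tuple[str, str], tuple[dict, dict]] = {}
    for a_idx in range(len(pops)):
        for b_idx in range(a_idx + 1, len(pops)):
            a, b = pops[a_idx], pops[b_idx]
            de = moderated_de(matrix, sheet, (a, b), min_replicates=config.min_replicates)
            up, down = threshold_gene_sets(de, config.fold_threshold, config.alpha)
            gene_sets[(a, b)] = (up, down)
            gene_sets[(b, a)] = (
                {g: -fc for g, fc in down.items()},
                {g: -fc for g, fc in up.items()},
            )

    aug = parse_obo(write_obo(graph))  # deep copy via round-trip
    aug.add_term(OntologyTerm(id=GS_ROOT.replace("GS", config.gs_prefix, 1), name="Gene-sets"))
    hub_id = GS_HUB.replace("GS", config.gs_prefix, 1)
    aug.add_term(
        OntologyTerm(
            id=hub_id,
            name="mature immune cell comparisons",
            parents=[(IS_A, GS_ROOT.replace("GS", config.gs_prefix, 1))],
        )
    )

    comparisons: dict[str, ComparisonGeneSet] = {}
    ordered_pairs = sorted((a, b) for a in pops for b in pops if a != b)
    for n, (a, b) in enumerate(ordered_pairs, start=2):
        gsid = _gs_id(config.gs_prefix, n)
        up, down = gene_sets[(a, b)]
        cgs = ComparisonGeneSet(
            id=gsid,
            up_population=a,
            down_population=b,
            up_class=sheet.population_to_class[a],
            down_class=sheet.population_to_class[b],
            up_genes=up,
            down_genes=down,
        )
        comparisons[gsid] = cgs
        aug.add_term(
            OntologyTerm(
                id=gsid,
                name=f"{a} vs {b}",
                parents=[
                    (IS_A, hub_id),
                    (config.up_relation, cgs.up_class),
                    (config.down_relation, cgs.down_class),
                ],
            )
        )
    aug.validate()
    return ComparisonOntology(aug, comparisons, sheet.population_to_class, config)


def export_comparison_obo(co: ComparisonOntology) -> str:
    """OBO text of the augmented ontology (gene contents live in the GMT
    sidecar; see :func:`export_gene_sets_gmt`)."""
    return write_obo(co.graph)


def export_gene_sets_gmt(co: ComparisonOntology) -> str:
    """GMT sidecar: two rows per comparison class (up and down sets).

    set-name = GS id, description = "up|down <up_class> vs <down_class>",
    members = "gene|log2FC" tokens.  Fold changes use repr so the round trip
    is exact.
    """
    lines = []
    for gsid in sorted(co.comparisons):
        c = co.comparisons[gsid]
        for direction, genes in (("up", c.up_genes), ("down", c.down_genes)):
            desc = f"{direction} {c.up_class} vs {c.down_class}"
            members = "\t".join(f"{g}|{fc!r}" for g, fc in sorted(genes.items()))
            lines.append(f"{gsid}\t{desc}" + ("\t" + members if members else ""))
    return "\n".join(lines) + "\n"


def load_comparison_ontology(
    obo: str | IO[str], gmt: str, config: BuildConfig | None = None
) -> ComparisonOntology:
    """Rebuild a :class:`ComparisonOntology` from its OBO + GMT artifacts.

    Comparison classes are recognized as children of the comparisons hub;
    populations are recovered from the "<up_pop> vs <down_pop>" term names.
    Read-aliases of the directional relation names are accepted.
    """
    config = config or BuildConfig()
    graph = parse_obo(obo)
    hub_id = GS_HUB.replace("GS", config.gs_prefix, 1)
    if hub_id not in graph:
        raise ValidationError(f"comparisons hub {hub_id} not found in ontology")

    sets: dict[tuple[str, str], dict[str, float]] = {}
    for line in gmt.splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"malformed GMT line: {line!r}")
        gsid, desc, *members = fields
        direction = desc.split(" ", 1)[0]
        if direction not in ("up", "down"):
            raise ValidationError(f"GMT description must start with up|down: {desc!r}")
        genes: dict[str, float] = {}
        for tok in members:
            gene, _, fc = tok.rpartition("|")
            genes[gene] = float(fc)
        sets[(gsid, direction)] = genes

    comparisons: dict[str, ComparisonGeneSet] = {}
    population_to_class: dict[str, str] = {}
    for t in graph.terms.values():
        rels = {}
        is_comparison = False
        for rel, tgt in t.parents:
            rel = RELATION_ALIASES.get(rel, rel)
            if rel == IS_A and tgt == hub_id:
                is_comparison = True
            elif rel in (config.up_relation, config.down_relation):
                rels[rel] = tgt
        if not is_comparison:
            continue
        if " vs " not in t.name:
            raise ValidationError(f"comparison term {t.id} name lacks '<up> vs <down>'")
        up_pop, down_pop = t.name.split(" vs ", 1)
        comparisons[t.id] = ComparisonGeneSet(
            id=t.id,
            up_population=up_pop,
            down_population=down_pop,
            up_class=rels[config.up_relation],
            down_class=rels[config.down_relation],
            up_genes=sets.get((t.id, "up"), {}),
            down_genes=sets.get((t.id, "down"), {}),
        )
        population_to_class[up_pop] = rels[config.up_relation]
        population_to_class[down_pop] = rels[config.down_relation]
    return ComparisonOntology(graph, comparisons, population_to_class, config)
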