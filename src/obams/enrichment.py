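"""Hypergeometric term enrichment with true-path annotation propagation.

Given an annotation ontology (e.g. the Gene Ontology) and direct
gene-to-term annotations, each gene is propagated to every ancestor of its
annotated terms over the chosen relations (default is_a plus part_of when
present).  Enrichment of a query gene set is the upper-tail hypergeometric
probability P(X >= k) of drawing k or more annotated genes in a sample of
size n from a universe of N genes of which K carry the annotation, corrected
for multiple testing across all tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .errors import ValidationError
from .ontology import IS_A, OntologyGraph, closure

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "propagate_annotations",
    "enrich",
    "read_annotations_tsv",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_PROPAGATION_RELATIONS = (IS_A, "part_of")


@dataclass
class AnnotationSet:
    """Term -> annotated genes after ancestor propagation."""

    term_to_genes: dict[str, set[str]]
    universe: set[str]
    relations: frozenset[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.term_to_genes.values(), set()) - self.universe
        if stray:
            raise ValidationError(
                "annotated genes outside the universe: " + ", ".join(sorted(stray)[:10])
            )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # query hits annotated to the term
    K: int  # universe genes annotated to the term
    n: int  # query size (after universe filtering)
    N: int  # universe size
    p_value: float
    adj_p_value: float


def propagate_annotations(
    onto: OntologyGraph,
    direct: Mapping[str, Iterable[str]],
    relations: Iterable[str] | None = None,
    universe: Iterable[str] | None = None,
) -> AnnotationSet:
    """Attach each gene to every ancestor of its directly annotated terms.

    ``relations`` defaults to is_a plus part_of (when the ontology declares
    it).  ``universe`` defaults to the annotated genes; passing the measured
    genes of an expression matrix restricts enrichment to what the signature
    could contain.
    """
    if relations is None:
        rels = {r for r in DEFAULT_PROPAGATION_RELATIONS if r in onto.relations}
    else:
        rels = set(relations)

    unknown_terms = sorted(
        {t for terms in direct.values() for t in terms if t not in onto}
    )
    if unknown_terms:
        raise ValidationError("annotations to unknown terms: " + ", ".join(unknown_terms))

    term_to_genes: dict[str, set[str]] = {}
    anc_cache: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        for term in terms:
            if term not in anc_cache:
                anc_cache[term] = closure(onto, term, rels, direction="up", reflexive=True)
            for t in anc_cache[term]:
                term_to_genes.setdefault(t, set()).add(gene)

    annotated = set(direct)
    if universe is None:
        uni = annotated
    else:
        uni = set(universe)
        dropped = annotated - uni
        if dropped:
            logger.info("dropping %d annotated genes outside the universe", len(dropped))
            term_to_genes = {
                t: gs & uni for t, gs in term_to_genes.items() if gs & uni
            }
    return AnnotationSet(term_to_genes=term_to_genes, universe=uni, relations=frozenset(rels))


def enrich(
    query_genes: Iterable[str], ann: AnnotationSet, correction: str = "bh"
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a gene set against every
    annotated term, sorted by raw p then term id."""
    if correction not in ("bh", "bonferroni"):
        raise ValidationError(f"correction must be 'bh' or 'bonferroni', got {correction!r}")
    query = set(query_genes)
    outside = query - ann.universe
    if outside:
        logger.info("dropping %d query genes outside the universe", len(outside))
        query -= outside
    if not query:
        raise ValidationError("query is empty after restricting to the universe")

    N, n = len(ann.universe), len(query)
    terms = sorted(t for t, gs in ann.term_to_genes.items() if gs)
    raw = []
    counts = []
    for term in terms:
        genes = ann.term_to_genes[term]
        K = len(genes)
        k = len(genes & query)
        raw.append(float(hypergeom.sf(k - 1, N, K, n)))
        counts.append((k, K))
    if correction == "bh":
        adj = bh_adjust(raw)
    else:
        adj = [min(1.0, p * len(raw)) for p in raw]

    results = [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N, p_value=p, adj_p_value=float(a))
        for t, (k, K), p, a in zip(terms, counts, raw, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def read_annotations_tsv(path_or_buf: str | IO[str]) -> dict[str, set[str]]:
    """Read gene->terms annotations from two-column TSV (gene, term); lines
    starting with '!' (GAF-style comments) are skipped."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="!", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("annotation TSV needs at least two columns (gene, term)")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, set()).add(term)
    return out


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
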