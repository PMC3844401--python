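"""Genus-differentia signature queries over the comparison ontology.

The molecular signature of a cell-type class x relative to a reference
ancestor y is the set of genes consistently up- (or down-) regulated in
*every* sampled subtype of x against *every* sampled subtype of y that is not
itself a kind of x.  The query therefore has three constraints: the
comparison's up-side class must be a reflexive descendant of x, its down-side
class a reflexive descendant of y, and its down-side class must NOT be a
reflexive descendant of x (otherwise within-x comparisons would poison the
intersection).  The returned gene sets are intersected and ranked by mean
log2 fold change.

Because ontology associations are transitive, stacking these signatures along
the is_a path from a class to a chosen root yields a layered expression
profile: a leaf type inherits the signature of every ancestor level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx
import pandas as pd

from .comparison import ComparisonGeneSet, ComparisonOntology
from .errors import QueryError
from .ontology import IS_A, closure

__all__ = [
    "SignatureQuery",
    "SignatureEntry",
    "Signature",
    "Profile",
    "query_gene_sets",
    "obams_signature",
    "full_profile",
    "subtraction_query",
]


@dataclass(frozen=True)
class SignatureQuery:
    """Focus class x vs reference class y (an is_a ancestor of x unless
    ``ad_hoc``), in one direction."""

    focus: str
    reference: str
    direction: str = "up"
    ad_hoc: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise QueryError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    mean_log2_fold_change: float
    sd_log2_fold_change: float

    @property
    def mean_linear_fold_change(self) -> float:
        return 2.0 ** self.mean_log2_fold_change


@dataclass
class Signature:
    """Ranked intersection of all gene sets returned by a query.

    ``status`` is ``"ok"`` for a normal result, ``"no_gene_sets"`` when the
    query matched no comparison classes at all (distinct from an empty
    intersection, which is still ``"ok"``).
    """

    query: SignatureQuery
    n_comparisons: int
    entries: list[SignatureEntry] = field(default_factory=list)
    status: str = "ok"

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [e.gene for e in self.entries],
                "mean_log2FC": [e.mean_log2_fold_change for e in self.entries],
                "mean_linear_FC": [e.mean_linear_fold_change for e in self.entries],
                "sd_log2FC": [e.sd_log2_fold_change for e in self.entries],
                "n_comparisons": self.n_comparisons,
            }
        )

    def write_tsv(self, path_or_buf: str | IO[str]) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)


@dataclass
class Profile:
    """Layered signatures of a class and its ancestors up to a root.

    ``levels`` holds (class, parent, Signature) triples in topological order,
    the focus class first; their union is the inferred expression character
    of the focus class.
    """

    focus: str
    root: str
    direction: str
    levels: list[tuple[str, str, Signature]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, (cls, parent, sig) in enumerate(self.levels):
            df = sig.to_frame()
            df.insert(0, "level", i)
            df.insert(1, "class", cls)
            df.insert(2, "parent", parent)
            frames.append(df)
        if not frames:
            return pd.DataFrame(
                columns=["level", "class", "parent", "gene", "mean_log2FC",
                         "mean_linear_FC", "sd_log2FC", "n_comparisons"]
            )
        return pd.concat(frames, ignore_index=True)

    def write_tsv(self, path_or_buf: str | IO[str]) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)


def query_gene_sets(co: ComparisonOntology, q: SignatureQuery) -> list[ComparisonGeneSet]:
    """Return the comparison classes satisfying the three-constraint query,
    sorted by GS id.

    direction='up': up_class in refl-desc(x), down_class in refl-desc(y),
    down_class not in refl-desc(x).  direction='down' swaps the roles of the
    two directional relations.
    """
    for cls in (q.focus, q.reference):
        if cls not in co.graph:
            raise QueryError(f"unknown class {cls!r}")
    if not q.ad_hoc:
        anc = closure(co.graph, q.focus, direction="up", reflexive=False)
        if q.reference not in anc:
            raise QueryError(
                f"{q.reference} is not an is_a ancestor of {q.focus}; "
                "set ad_hoc=True for arbitrary reference classes"
            )
    desc_x = closure(co.graph, q.focus, direction="down", reflexive=True)
    desc_y = closure(co.graph, q.reference, direction="down", reflexive=True)

    out = []
    for gsid in sorted(co.comparisons):
        c = co.comparisons[gsid]
        a, b = (c.up_class, c.down_class) if q.direction == "up" else (c.down_class, c.up_class)
        if a in desc_x and b in desc_y and b not in desc_x:
            out.append(c)
    return out


def _intersect(
    gene_maps: Sequence[dict[str, float]], query: SignatureQuery, status: str = "ok"
) -> Signature:
    """Intersect gene->log2FC maps; rank by |mean| descending, ties by gene."""
    if not gene_maps:
        return Signature(query=query, n_comparisons=0, entries=[], status="no_gene_sets")
    common = set(gene_maps[0])
    for m in gene_maps[1:]:
        common &= set(m)
    entries = []
    k = len(gene_maps)
    for gene in common:
        fcs = [m[gene] for m in gene_maps]
        mean = sum(fcs) / k
        sd = math.sqrt(sum((v - mean) ** 2 for v in fcs) / k)
        entries.append(SignatureEntry(gene, mean, sd))
    entries.sort(key=lambda e: (-abs(e.mean_log2_fold_change), e.gene))
    return Signature(query=query, n_comparisons=k, entries=entries, status=status)


def obams_signature(co: ComparisonOntology, q: SignatureQuery) -> Signature:
    """The molecular signature for a query: genes present in every returned
    comparison set, with mean and (population) sd of their log2 fold change,
    ranked by absolute mean.

    Fold changes are always reported from the focus class's perspective, so a
    down signature carries negative means.  For direction='down' the matched
    comparisons have their up-side in the reference branch (the predicates
    are swapped), hence their up-sets are negated.
    """
    sets = query_gene_sets(co, q)
    if q.direction == "up":
        maps = [s.up_genes for s in sets]
    else:
        maps = [{g: -fc for g, fc in s.up_genes.items()} for s in sets]
    return _intersect(maps, q)


def full_profile(
    co: ComparisonOntology, focus: str, root: str, direction: str = "up"
) -> Profile:
    """Per-parent signatures of ``focus`` and every class on its is_a paths
    up to ``root`` (root itself excluded — it has no reference parent).

    Classes appear in topological order starting from the focus; a class with
    several is_a parents on the path contributes one signature per parent
    (signatures are never merged across parents).
    """
    if focus not in co.graph:
        raise QueryError(f"unknown class {focus!r}")
    if root not in co.graph:
        raise QueryError(f"unknown class {root!r}")
    anc = closure(co.graph, focus, direction="up", reflexive=True)
    if root not in anc or root == focus:
        raise QueryError(f"{root} is not an is_a ancestor of {focus}")

    # classes on some focus->root path: reflexive ancestors of focus that are
    # also reflexive descendants of root
    desc_root = closure(co.graph, root, direction="down", reflexive=True)
    path_classes = anc & desc_root

    sub = nx.DiGraph()
    sub.add_nodes_from(path_classes)
    for cls in path_classes:
        for rel, parent in co.graph.terms[cls].parents:
            if rel == IS_A and parent in path_classes:
                sub.add_edge(cls, parent)  # child before parent in topo order

    profile = Profile(focus=focus, root=root, direction=direction)
    for cls in nx.lexicographical_topological_sort(sub):
        if cls == root:
            continue
        parents = sorted(
            parent
            for rel, parent in co.graph.terms[cls].parents
            if rel == IS_A and parent in path_classes
        )
        for parent in parents:
            q = SignatureQuery(focus=cls, reference=parent, direction=direction)
            profile.levels.append((cls, parent, obams_signature(co, q)))
    return profile


def subtraction_query(
    co: ComparisonOntology,
    focus: str,
    subtract_classes: Iterable[str],
    direction: str = "up",
    fold_threshold: float = 2.0,
) -> Signature:
    """In-silico subtraction: intersect the focus populations' gene sets
    against every population of each subtract class, at a (possibly stricter)
    fold threshold.

    Generalizes the recipe of comparing one cell type against hand-picked
    neighbours (e.g. a sibling plus activated out-groups) to remove shared
    programs.  ``fold_threshold`` must be at least the build threshold, since
    sets are re-filtered rather than recomputed.
    """
    if direction not in ("up", "down"):
        raise QueryError(f"direction must be 'up' or 'down', got {direction!r}")
    if fold_threshold < co.config.fold_threshold:
        raise QueryError(
            f"fold_threshold {fold_threshold} is below the build threshold "
            f"{co.config.fold_threshold}; rebuild with a lower threshold instead"
        )
    focus_pops = co.populations_under(focus)
    if not focus_pops:
        raise QueryError(f"focus class {focus} has no mapped populations")
    subtract_pops: list[str] = []
    for cls in subtract_classes:
        if cls not in co.graph:
            raise QueryError(f"unknown subtract class {cls!r}")
        pops = [p for p in co.populations_under(cls) if p not in focus_pops]
        if not pops:
            raise QueryError(f"subtract class {cls} has no mapped populations")
        subtract_pops.extend(p for p in pops if p not in subtract_pops)

    log_thr = math.log2(fold_threshold)
    maps = []
    for f in focus_pops:
        for s in subtract_pops:
            c = co.comparison_for(f, s)
            genes = c.up_genes if direction == "up" else c.down_genes
            if direction == "up":
                maps.append({g: fc for g, fc in genes.items() if fc > log_thr})
            else:
                maps.append({g: fc for g, fc in genes.items() if fc < -log_thr})
    q = SignatureQuery(focus=focus, reference="|".join(sorted(set(subtract_classes))),
                       direction=direction, ad_hoc=True)
    return _intersect(maps, q)
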