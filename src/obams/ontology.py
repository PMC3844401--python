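"""Ontology graphs: OBO parsing/writing and ancestor/descendant closure.

Cell-type ontologies such as the Cell Ontology are DAGs whose classes are
connected mainly by ``is_a`` (subtype) edges, with other typed relations
(``part_of``, ``develops_from``, ...) layered on top.  This module provides a
minimal, round-trippable OBO 1.2 reader/writer and the reflexive
ancestor/descendant closure operation that every downstream gene-set query is
built from.

Only the tag set needed for that purpose is interpreted (``id``, ``name``,
``is_a``, ``relationship``, ``is_obsolete``, ``xref``, ``def``); any other
tag line inside a ``[Term]`` stanza is preserved verbatim so that writing a
parsed file loses nothing.  Subsumption (``is_a``) must be acyclic; other
relations may form cycles since they carry no subsumption meaning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable

import networkx as nx

from .errors import OboParseError, OntologyError

__all__ = ["OntologyTerm", "OntologyGraph", "parse_obo", "write_obo", "closure"]

IS_A = "is_a"

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:\S+$")


def _check_curie(curie: str) -> str:
    if not _CURIE_RE.match(curie):
        raise OntologyError(f"identifier {curie!r} is not PREFIX:identifier shaped")
    return curie


@dataclass
class OntologyTerm:
    """One ontology class.

    ``parents`` holds outgoing typed edges as ``(relation, target-id)`` pairs;
    ``extra_lines`` preserves uninterpreted stanza lines for round-tripping.
    """

    id: str
    name: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False
    xrefs: list[str] = field(default_factory=list)
    definition: str | None = None
    extra_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_curie(self.id)


class OntologyGraph:
    """A DAG of typed ontology classes.

    Terms are stored by id; ``relations`` is the vocabulary of edge types seen
    (always containing ``is_a``).  The ``is_a`` subgraph is validated to be
    acyclic; every edge target must exist.
    """

    def __init__(self, header: Iterable[str] | None = None) -> None:
        self.terms: dict[str, OntologyTerm] = {}
        self.relations: set[str] = {IS_A}
        self.header: list[str] = list(header) if header is not None else ["format-version: 1.2"]
        # opaque non-[Term] stanzas ([Typedef], ...) kept verbatim
        self.other_stanzas: list[list[str]] = []
        self._children: dict[str, list[tuple[str, str]]] | None = None

    # -- construction -----------------------------------------------------

    def add_term(self, term: OntologyTerm) -> OntologyTerm:
        if term.id in self.terms:
            raise OntologyError(f"duplicate term id {term.id}")
        self.terms[term.id] = term
        for rel, _ in term.parents:
            self.relations.add(rel)
        self._children = None
        return term

    def add_edge(self, child: str, relation: str, parent: str) -> None:
        self.terms[child].parents.append((relation, parent))
        self.relations.add(relation)
        self._children = None

    def validate(self) -> None:
        """Check edge targets exist and the is_a subgraph is acyclic."""
        missing = sorted(
            {tgt for t in self.terms.values() for _, tgt in t.parents if tgt not in self.terms}
        )
        if missing:
            raise OntologyError("dangling edge target(s): " + ", ".join(missing))
        dag = nx.DiGraph()
        dag.add_nodes_from(self.terms)
        for t in self.terms.values():
            for rel, tgt in t.parents:
                if rel == IS_A:
                    dag.add_edge(t.id, tgt)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            path = " -> ".join(edge[0] for edge in cycle) + " -> " + cycle[-1][1]
            raise OntologyError(f"is_a cycle detected: {path}")

    # -- traversal ---------------------------------------------------------

    def _child_index(self) -> dict[str, list[tuple[str, str]]]:
        if self._children is None:
            idx: dict[str, list[tuple[str, str]]] = {tid: [] for tid in self.terms}
            for t in self.terms.values():
                if t.obsolete:
                    continue  # obsolete terms contribute no edges to closure
                for rel, tgt in t.parents:
                    if tgt in idx:
                        idx[tgt].append((rel, t.id))
            self._children = idx
        return self._children

    def roots(self, relation: str = IS_A) -> list[str]:
        """Terms with no outgoing edge of the given relation (sorted)."""
        return sorted(
            t.id
            for t in self.terms.values()
            if not t.obsolete and not any(rel == relation for rel, _ in t.parents)
        )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        if set(self.terms) != set(other.terms):
            return False
        for tid, t in self.terms.items():
            o = other.terms[tid]
            if (
                t.name != o.name
                or sorted(t.parents) != sorted(o.parents)
                or t.obsolete != o.obsolete
                or sorted(t.xrefs) != sorted(o.xrefs)
                or t.definition != o.definition
            ):
                return False
        return True


def closure(
    graph: OntologyGraph,
    term: str,
    relations: Iterable[str] | None = None,
    direction: str = "up",
    reflexive: bool = False,
) -> set[str]:
    """Ancestor (``direction='up'``) or descendant (``'down'``) closure.

    Traverses only the named ``relations`` (default ``{is_a}``) so that
    subsumption queries never leak across gene-set comparison relations.
    With ``reflexive=True`` the starting term is included.
    """
    if term not in graph.terms:
        raise OntologyError(f"unknown term {term!r}")
    rels = {IS_A} if relations is None else set(relations)
    if not rels:
        raise OntologyError("relations must be non-empty")
    unknown = rels - graph.relations
    if unknown:
        raise OntologyError("unknown relation(s): " + ", ".join(sorted(unknown)))
    if direction not in ("up", "down"):
        raise OntologyError(f"direction must be 'up' or 'down', got {direction!r}")

    out: set[str] = set()
    stack = [term]
    child_idx = graph._child_index() if direction == "down" else None
    while stack:
        cur = stack.pop()
        if direction == "up":
            t = graph.terms[cur]
            nxt = [] if t.obsolete else [tgt for rel, tgt in t.parents if rel in rels]
        else:
            nxt = [src for rel, src in child_idx[cur] if rel in rels]  # type: ignore[index]
        for n in nxt:
            if n not in out and n != term:
                out.add(n)
                stack.append(n)
    if reflexive:
        out.add(term)
    return out


# -- OBO serialization ------------------------------------------------------

_INTERPRETED_TAGS = {"id", "name", "is_a", "relationship", "is_obsolete", "xref", "def"}


def _strip_comment(value: str) -> str:
    """Drop an OBO trailing ``! comment`` (unescaped ``!``)."""
    out = []
    prev = ""
    for ch in value:
        if ch == "!" and prev != "\\":
            break
        out.append(ch)
        prev = ch
    return "".join(out).strip()


def parse_obo(stream: str | IO[str]) -> OntologyGraph:
    """Parse OBO 1.2-style text into an :class:`OntologyGraph`.

    ``[Term]`` stanzas are interpreted; other stanza types are preserved
    verbatim.  A stanza without an ``id`` raises :class:`OboParseError`
    naming the line; a dangling edge target raises :class:`OntologyError`
    listing the missing ids.
    """
    if isinstance(stream, str):
        stream = StringIO(stream)

    header: list[str] = []
    graph: OntologyGraph | None = None
    stanza_lines: list[tuple[int, str]] = []
    stanza_type: str | None = None
    stanza_start = 0
    in_header = True
    pending_terms: list[OntologyTerm] = []
    other: list[list[str]] = []

    def flush() -> None:
        nonlocal stanza_lines, stanza_type
        if stanza_type is None:
            return
        if stanza_type != "Term":
            other.append([f"[{stanza_type}]"] + [ln for _, ln in stanza_lines])
        else:
            term_id: str | None = None
            kwargs: dict = {"name": "", "parents": [], "obsolete": False,
                            "xrefs": [], "definition": None, "extra_lines": []}
            for lineno, line in stanza_lines:
                if ":" not in line:
                    raise OboParseError(f"line {lineno}: tag line without ':' — {line!r}")
                tag, _, value = line.partition(":")
                tag = tag.strip()
                value = value.strip()
                if tag == "id":
                    term_id = _strip_comment(value)
                elif tag == "name":
                    kwargs["name"] = _strip_comment(value)
                elif tag == "is_a":
                    kwargs["parents"].append((IS_A, _strip_comment(value)))
                elif tag == "relationship":
                    parts = _strip_comment(value).split()
                    if len(parts) != 2:
                        raise OboParseError(
                            f"line {lineno}: relationship needs 'relation target' — {line!r}"
                        )
                    kwargs["parents"].append((parts[0], parts[1]))
                elif tag == "is_obsolete":
                    kwargs["obsolete"] = _strip_comment(value).lower() == "true"
                elif tag == "xref":
                    kwargs["xrefs"].append(_strip_comment(value))
                elif tag == "def":
                    kwargs["definition"] = value
                else:
                    kwargs["extra_lines"].append(line)
            if term_id is None:
                raise OboParseError(
                    f"[Term] stanza starting at line {stanza_start} has no id tag"
                )
            try:
                pending_terms.append(OntologyTerm(id=term_id, **kwargs))
            except OntologyError as exc:
                raise OboParseError(f"stanza at line {stanza_start}: {exc}") from exc
        stanza_lines = []
        stanza_type = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        m = re.match(r"^\[(\w+)\]\s*$", line)
        if m:
            flush()
            in_header = False
            stanza_type = m.group(1)
            stanza_start = lineno
            continue
        if not line.strip():
            continue
        if in_header:
            header.append(line)
        elif stanza_type is not None:
            stanza_lines.append((lineno, line))
        else:
            raise OboParseError(f"line {lineno}: content outside any stanza — {line!r}")
    flush()

    graph = OntologyGraph(header=header or None)
    graph.other_stanzas = other
    for term in pending_terms:
        graph.add_term(term)
    graph.validate()
    return graph


def write_obo(graph: OntologyGraph) -> str:
    """Serialize deterministically: terms sorted by id, tags in fixed order.

    ``write(parse(write(G))) == write(G)`` and the output is re-parsable by
    :func:`parse_obo`.
    """
    out: list[str] = list(graph.header)
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        out.append("")
        out.append("[Term]")
        out.append(f"id: {t.id}")
        if t.name:
            out.append(f"name: {t.name}")
        if t.definition is not None:
            out.append(f"def: {t.definition}")
        for rel, tgt in sorted(p for p in t.parents if p[0] == IS_A):
            out.append(f"is_a: {tgt}")
        for rel, tgt in sorted(p for p in t.parents if p[0] != IS_A):
            out.append(f"relationship: {rel} {tgt}")
        for xref in sorted(t.xrefs):
            out.append(f"xref: {xref}")
        if t.obsolete:
            out.append("is_obsolete: true")
        out.extend(t.extra_lines)
    for stanza in graph.other_stanzas:
        out.append("")
        out.extend(stanza)
    return "\n".join(out) + "\n"
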