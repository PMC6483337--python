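"""Phenotype ontology handling: OBO parsing, root-path enumeration and
path-based semantic similarity.

The similarity model works on the set of all directed ``is_a`` paths from a
term to the ontology root.  For two terms *c* and *c'* with path sets
``P(c, r)`` and ``P(c', r)``::

    sim(c, c') = max over p in P(c,r), p' in P(c',r) of |p & p'| / |p | p'|

i.e. the best Jaccard index over all pairs of root paths, where each path is
treated as a set of node identifiers including both the term itself and the
root.  Deeply nested (precise) annotations share long paths and therefore
score higher than shallow ones — a parent/child pair near the leaves scores
close to 1, the root and its child score only 1/2.

Case-level similarity between two phenotype profiles *d* and *d'* is the
symmetrised best-match average::

    sim(d, d') = 1/(2|d|)  * sum_{c in d}  max_{c' in d'} sim(c, c')
               + 1/(2|d'|) * sum_{c' in d'} max_{c in d}  sim(c, c')

Both measures are symmetric, bounded to [0, 1] and equal 1 on identical
inputs.  Root paths are enumerated once per ontology release and cached
(:class:`PathCache`), which reduces a similarity evaluation to a handful of
set operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "Term",
    "Ontology",
    "PathCache",
    "PhenotypeProfile",
    "OntologyError",
    "OntologyStructureError",
    "OntologyCycleError",
    "UnknownTermError",
    "ObsoleteTermError",
    "PathLimitError",
    "parse_obo",
    "enumerate_root_paths",
    "precompute_path_cache",
    "term_similarity",
    "case_similarity",
]

#: Per-term cap on enumerated root paths.  Dense multi-parent regions of an
#: ontology can explode combinatorially; real phenotype ontologies stay far
#: below this, so hitting the cap indicates a pathological input.
DEFAULT_PATH_LIMIT = 10_000


class OntologyError(Exception):
    """Base class for ontology-related failures."""


class OntologyStructureError(OntologyError):
    """Root missing/ambiguous or parent structure invalid."""


class OntologyCycleError(OntologyError):
    """The is_a relation contains a directed cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("is_a cycle detected: " + " -> ".join(cycle + cycle[:1]))


class UnknownTermError(OntologyError, KeyError):
    """A term accession does not resolve in the ontology or cache."""


class ObsoleteTermError(OntologyError):
    """An obsolete term was used where a live term is required."""


class PathLimitError(OntologyError):
    """A term exceeded the per-term root-path limit."""


@dataclass(frozen=True)
class Term:
    """A single ontology term (one ``[Term]`` stanza)."""

    id: str
    name: str = ""
    parent_ids: frozenset[str] = frozenset()
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()
    replaced_by: str | None = None


@dataclass
class Ontology:
    """An is_a DAG of terms with a single root.

    ``alt_index`` maps secondary accessions (``alt_id`` lines) to their
    primary term id.  Obsolete terms are kept so that ``replaced_by``
    redirects can be followed, but they carry no parents and never take part
    in path enumeration or similarity.
    """

    terms: dict[str, Term]
    root_id: str
    alt_index: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def live_terms(self) -> Iterable[Term]:
        return (t for t in self.terms.values() if not t.obsolete)

    def resolve(self, term_id: str) -> str | None:
        """Resolve an accession to a live primary term id.

        Follows ``alt_id`` aliases and, for obsolete terms, ``replaced_by``
        redirects (transitively, with a hop limit).  Returns ``None`` when
        the accession cannot be resolved to a live term.
        """
        seen: set[str] = set()
        current: str | None = term_id
        while current is not None and current not in seen:
            seen.add(current)
            current = self.alt_index.get(current, current)
            term = self.terms.get(current)
            if term is None:
                return None
            if not term.obsolete:
                return term.id
            current = term.replaced_by
        return None


@dataclass(frozen=True)
class PhenotypeProfile:
    """A non-empty set of live term accessions describing one case."""

    term_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_ids:
            raise ValueError("phenotype profile must contain at least one term")

    @classmethod
    def of(cls, *term_ids: str) -> "PhenotypeProfile":
        return cls(frozenset(term_ids))


def _first(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, (list, tuple)):
        return value[0] if value else None
    return value


def parse_obo(source: str | Path | IO[str], root_id: str | None = None) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Only ``is_a`` edges define the hierarchy; other relationship types
    (``part_of`` etc.) are ignored, following the usual convention for
    phenotype-term similarity.  ``alt_id`` lines become aliases and
    ``replaced_by`` redirects are kept on obsolete terms.

    The root is detected structurally as the unique live parentless term;
    pass ``root_id`` to override detection (useful for real ontology
    releases where the root accession is known a priori).
    """
    graph = obonet.read_obo(source, ignore_obsolete=False)

    terms: dict[str, Term] = {}
    alt_index: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents = frozenset() if obsolete else frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        alt_ids = tuple(data.get("alt_id", []))
        term = Term(
            id=node,
            name=_first(data.get("name")) or "",
            parent_ids=parents,
            obsolete=obsolete,
            alt_ids=alt_ids,
            replaced_by=_first(data.get("replaced_by")),
        )
        terms[node] = term
        for alias in alt_ids:
            alt_index[alias] = node

    live = {tid: t for tid, t in terms.items() if not t.obsolete}
    # Drop dangling parent references (edges into terms absent from the file
    # or obsolete) before structural checks.
    for tid, t in live.items():
        kept = frozenset(p for p in t.parent_ids if p in live)
        if kept != t.parent_ids:
            live[tid] = Term(t.id, t.name, kept, False, t.alt_ids, t.replaced_by)
            terms[tid] = live[tid]

    is_a = nx.DiGraph()
    is_a.add_nodes_from(live)
    for t in live.values():
        for p in t.parent_ids:
            is_a.add_edge(t.id, p)
    if not nx.is_directed_acyclic_graph(is_a):
        cycle_edges = nx.find_cycle(is_a)
        raise OntologyCycleError([u for u, _ in cycle_edges])

    roots = sorted(tid for tid, t in live.items() if not t.parent_ids)
    if root_id is not None:
        if root_id not in live:
            raise OntologyStructureError(f"configured root {root_id!r} not found among live terms")
        detected = root_id
    elif len(roots) == 1:
        detected = roots[0]
    elif not roots:
        raise OntologyStructureError("no parentless live term; ontology has no root")
    else:
        raise OntologyStructureError(f"multiple root candidates: {', '.join(roots)}")

    version = _first(graph.graph.get("data-version")) or _first(graph.graph.get("ontology")) or ""
    return Ontology(terms=terms, root_id=detected, alt_index=alt_index, version=str(version))


def enumerate_root_paths(ontology: Ontology, term_id: str) -> frozenset[frozenset[str]]:
    """Enumerate every distinct directed is_a path from *term_id* to the root.

    Each path is returned as a node set containing both endpoints; two paths
    identical as node sets count once.  The result does not depend on
    traversal order.
    """
    term = ontology[term_id]
    if term.obsolete:
        raise ObsoleteTermError(term_id)
    return _paths_memo(ontology, term_id, {}, limit=None)


def _paths_memo(
    ontology: Ontology,
    term_id: str,
    memo: dict[str, frozenset[frozenset[str]]],
    limit: int | None,
) -> frozenset[frozenset[str]]:
    if term_id in memo:
        return memo[term_id]
    if term_id == ontology.root_id:
        result = frozenset({frozenset({term_id})})
    else:
        term = ontology[term_id]
        if not term.parent_ids:
            raise OntologyStructureError(
                f"term {term_id} cannot reach the root {ontology.root_id}"
            )
        paths: set[frozenset[str]] = set()
        for parent in sorted(term.parent_ids):
            for parent_path in _paths_memo(ontology, parent, memo, limit):
                paths.add(parent_path | {term_id})
        result = frozenset(paths)
    if limit is not None and len(result) > limit:
        raise PathLimitError(
            f"term {term_id} has {len(result)} root paths (limit {limit})"
        )
    memo[term_id] = result
    return result


@dataclass
class PathCache:
    """Pre-computed root paths for every live term of one ontology release.

    Serialized as JSON ``{"ontology_version": ..., "paths": {term:
    [[node, ...], ...]}}`` with deterministic ordering, so identical caches
    are byte-identical on disk.
    """

    paths: dict[str, frozenset[frozenset[str]]]
    ontology_version: str = ""

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.paths

    def __getitem__(self, term_id: str) -> frozenset[frozenset[str]]:
        try:
            return self.paths[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    @property
    def n_paths(self) -> int:
        """Total number of stored root paths across all terms."""
        return sum(len(p) for p in self.paths.values())

    def to_json(self) -> str:
        payload = {
            "ontology_version": self.ontology_version,
            "paths": {
                term: sorted(sorted(p) for p in pathset)
                for term, pathset in sorted(self.paths.items())
            },
        }
        return json.dumps(payload, indent=None, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "PathCache":
        payload = json.loads(text)
        paths = {
            term: frozenset(frozenset(p) for p in pathlist)
            for term, pathlist in payload["paths"].items()
        }
        return cls(paths=paths, ontology_version=payload.get("ontology_version", ""))

    @classmethod
    def load(cls, path: str | Path) -> "PathCache":
        return cls.from_json(Path(path).read_text())


def precompute_path_cache(
    ontology: Ontology, path_limit: int = DEFAULT_PATH_LIMIT
) -> PathCache:
    """Enumerate and cache root paths for every live term.

    ``path_limit`` bounds the number of distinct paths any single term may
    hold; exceeding it raises :class:`PathLimitError` rather than silently
    truncating.
    """
    memo: dict[str, frozenset[frozenset[str]]] = {}
    for term in ontology.live_terms():
        _paths_memo(ontology, term.id, memo, limit=path_limit)
    return PathCache(paths=memo, ontology_version=ontology.version)


def term_similarity(cache: PathCache, c: str, c_prime: str) -> float:
    """Best path-Jaccard similarity between two terms, in [0, 1]."""
    paths_c = cache[c]
    paths_c2 = cache[c_prime]
    best = 0.0
    for p in paths_c:
        for p2 in paths_c2:
            inter = len(p & p2)
            if inter == 0:
                continue
            j = inter / len(p | p2)
            if j > best:
                best = j
    return best


def case_similarity(
    cache: PathCache,
    d: PhenotypeProfile | Iterable[str],
    d_prime: PhenotypeProfile | Iterable[str],
) -> float:
    """Symmetrised best-match average similarity between two profiles."""
    terms_d = sorted(d.term_ids if isinstance(d, PhenotypeProfile) else set(d))
    terms_d2 = sorted(d_prime.term_ids if isinstance(d_prime, PhenotypeProfile) else set(d_prime))
    if not terms_d or not terms_d2:
        raise ValueError("case similarity requires two non-empty profiles")

    # Cache the term-level matrix once; both directional sums reuse it.
    sim: dict[tuple[str, str], float] = {}
    for c in terms_d:
        for c2 in terms_d2:
            sim[(c, c2)] = term_similarity(cache, c, c2)

    forward = sum(max(sim[(c, c2)] for c2 in terms_d2) for c in terms_d) / len(terms_d)
    backward = sum(max(sim[(c, c2)] for c in terms_d) for c2 in terms_d2) / len(terms_d2)
    return 0.5 * forward + 0.5 * backward
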