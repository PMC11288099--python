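"""Graph data model, GFA v1 I/O, reverse-complement augmentation.

A pangenome graph ``G(V, E, sigma)`` is a directed graph in which every
vertex ``v`` carries a non-empty string label ``sigma(v)`` over the DNA
alphabet.  An edge ``(v, u)`` has length ``|sigma(v)|``: walking across
the edge spells the full label of its source vertex.  Cycles (including
self-loops) are permitted; they arise in practice from inversion and
duplication variants.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

__all__ = [
    "PangenomeGraph",
    "Query",
    "GFAError",
    "read_gfa",
    "write_gfa",
    "reverse_complement",
    "augment_reverse_complement",
    "weak_components",
]

_DNA = frozenset("ACGT")
_RC_TABLE = str.maketrans("ACGT", "TGCA")

#: suffix used for materialized reverse-complement companion vertices
RC_SUFFIX = "_rc"


class GFAError(ValueError):
    """Raised for malformed GFA input."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G)."""
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"label contains non-ACGT characters: {sorted(bad)}")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class Query:
    """A named query sequence over {A,C,G,T}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("query sequence must be non-empty")


class PangenomeGraph:
    """Directed graph with non-empty string labels on vertices.

    Vertex identifiers are opaque strings.  Adjacency is kept in plain
    dict-of-set form; all iteration orders exposed by this class are
    sorted by vertex id so that downstream algorithms are deterministic.
    """

    def __init__(self) -> None:
        self._label: dict[str, str] = {}
        self._out: dict[str, set[str]] = {}
        self._in: dict[str, set[str]] = {}
        self._n_edges = 0
        #: maps v -> its reverse-complement companion, populated by
        #: :func:`augment_reverse_complement`
        self.rc_of: dict[str, str] = {}

    # -- construction -------------------------------------------------

    def add_vertex(self, vid: str, label: str) -> None:
        if not label:
            raise ValueError(f"vertex {vid!r}: label must be non-empty")
        if vid in self._label:
            raise ValueError(f"duplicate vertex id {vid!r}")
        self._label[vid] = label
        self._out[vid] = set()
        self._in[vid] = set()

    def add_edge(self, v: str, u: str) -> None:
        if v not in self._label:
            raise ValueError(f"edge references unknown vertex {v!r}")
        if u not in self._label:
            raise ValueError(f"edge references unknown vertex {u!r}")
        if u not in self._out[v]:
            self._out[v].add(u)
            self._in[u].add(v)
            self._n_edges += 1

    # -- queries ------------------------------------------------------

    @property
    def vertices(self) -> list[str]:
        """Vertex ids in sorted order."""
        return sorted(self._label)

    @property
    def n_vertices(self) -> int:
        return len(self._label)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def __contains__(self, vid: str) -> bool:
        return vid in self._label

    def label(self, vid: str) -> str:
        return self._label[vid]

    def label_len(self, vid: str) -> int:
        return len(self._label[vid])

    def edges(self) -> Iterator[tuple[str, str]]:
        """All edges, sorted lexicographically."""
        for v in self.vertices:
            for u in sorted(self._out[v]):
                yield (v, u)

    def has_edge(self, v: str, u: str) -> bool:
        return v in self._out and u in self._out[v]

    def out_neighbors(self, v: str) -> list[str]:
        return sorted(self._out[v])

    def in_neighbors(self, v: str) -> list[str]:
        return sorted(self._in[v])

    def edge_length(self, v: str, u: str) -> int:
        """Length of edge ``(v, u)``, defined as ``|sigma(v)|``."""
        if not self.has_edge(v, u):
            raise KeyError(f"no edge ({v!r}, {u!r})")
        return len(self._label[v])

    def total_label_length(self) -> int:
        return sum(len(s) for s in self._label.values())

    def subgraph(self, vids: Iterable[str]) -> "PangenomeGraph":
        """Vertex-induced subgraph (edges with both endpoints retained)."""
        keep = set(vids)
        g = PangenomeGraph()
        for v in sorted(keep):
            g.add_vertex(v, self._label[v])
        for v in sorted(keep):
            for u in sorted(self._out[v] & keep):
                g.add_edge(v, u)
        g.rc_of = {v: u for v, u in self.rc_of.items() if v in keep and u in keep}
        return g

    def copy(self) -> "PangenomeGraph":
        return self.subgraph(self._label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PangenomeGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


# ---------------------------------------------------------------------
# GFA v1 reading / writing
# ---------------------------------------------------------------------


def read_gfa(stream: TextIO | str, revcomp: bool = False) -> PangenomeGraph:
    """Read a GFA v1 graph (S and L lines; H lines ignored).

    S lines must carry explicit sequences (``*`` is rejected).  An L line
    ``L a s1 b s2 cigar`` contributes the directed edge *oriented-a ->
    oriented-b*, where *oriented-x* is ``x`` for orientation ``+`` and the
    reverse-complement companion of ``x`` for orientation ``-``.  Minus
    orientations require ``revcomp=True``, which materializes companion
    vertices for every segment and closes the edge set under the
    complementary-edge rule (see :func:`augment_reverse_complement`).
    Overlaps other than ``0M``/``*`` are rejected: the distance model
    assumes non-overlapping vertex labels.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    segments: dict[str, str] = {}
    links: list[tuple[str, str, str, str, int]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("H"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: S line needs name and sequence")
            name, seq = fields[1], fields[2]
            if seq == "*":
                raise GFAError(
                    f"line {lineno}: segment {name!r} has no explicit sequence"
                )
            if name in segments:
                raise GFAError(f"line {lineno}: duplicate segment {name!r}")
            segments[name] = seq
        elif tag == "L":
            if len(fields) < 5:
                raise GFAError(f"line {lineno}: L line needs 4 fields after tag")
            a, s1, b, s2 = fields[1:5]
            cigar = fields[5] if len(fields) > 5 else "0M"
            if s1 not in "+-" or s2 not in "+-":
                raise GFAError(f"line {lineno}: bad orientation {s1!r}/{s2!r}")
            if cigar not in ("0M", "*"):
                raise GFAError(
                    f"line {lineno}: overlap {cigar!r} not supported (only 0M)"
                )
            links.append((a, s1, b, s2, lineno))
        else:
            # other record types (P, W, C, ...) are outside our scope
            raise GFAError(f"line {lineno}: unsupported record type {tag!r}")

    g = PangenomeGraph()
    for name in sorted(segments):
        g.add_vertex(name, segments[name])

    uses_minus = any(s1 == "-" or s2 == "-" for _, s1, _, s2, _ in links)
    if uses_minus and not revcomp:
        raise GFAError(
            "GFA uses '-' orientations; re-read with revcomp=True to "
            "materialize reverse-complement vertices"
        )

    for a, s1, b, s2, lineno in links:
        for name in (a, b):
            if name not in segments:
                raise GFAError(f"line {lineno}: L line references unknown segment {name!r}")

    if revcomp:
        g = augment_reverse_complement(g)

    for a, s1, b, s2, _ in links:
        va = a if s1 == "+" else g.rc_of[a]
        vb = b if s2 == "+" else g.rc_of[b]
        g.add_edge(va, vb)
        if revcomp:
            g.add_edge(g.rc_of[vb], g.rc_of[va])
    return g


def write_gfa(g: PangenomeGraph, stream: TextIO) -> None:
    """Write S lines sorted by id, then L lines sorted lexicographically."""
    stream.write("H\tVN:Z:1.0\n")
    for v in g.vertices:
        stream.write(f"S\t{v}\t{g.label(v)}\n")
    for v, u in g.edges():
        stream.write(f"L\t{v}\t+\t{u}\t+\t0M\n")


# ---------------------------------------------------------------------
# double-strand augmentation and weak components
# ---------------------------------------------------------------------


def augment_reverse_complement(g: PangenomeGraph) -> PangenomeGraph:
    """Add a reverse-complement companion for every vertex.

    For each vertex ``v`` a companion with label ``revcomp(sigma(v))`` is
    added, and for each edge ``(u, v)`` the complementary edge from the
    companion of ``v`` to the companion of ``u``.  This makes anchors on
    either strand of a double-stranded query representable.  Applying the
    augmentation to an already-augmented graph returns an unchanged copy
    (the operation is idempotent up to vertex naming).
    """
    if g.rc_of:
        # already closed under the companion construction
        return g.copy()
    out = PangenomeGraph()
    rc_of: dict[str, str] = {}
    for v in g.vertices:
        rc_id = v + RC_SUFFIX
        if rc_id in g:
            raise ValueError(
                f"cannot augment: companion id {rc_id!r} collides with a vertex"
            )
        rc_of[v] = rc_id
        rc_of[rc_id] = v
    for v in g.vertices:
        out.add_vertex(v, g.label(v))
    for v in g.vertices:
        out.add_vertex(rc_of[v], reverse_complement(g.label(v)))
    for u, v in g.edges():
        out.add_edge(u, v)
        out.add_edge(rc_of[v], rc_of[u])
    out.rc_of = rc_of
    return out


def weak_components(g: PangenomeGraph) -> list[PangenomeGraph]:
    """Split into weakly connected subgraphs, sorted by smallest vertex id.

    Each weak component is processed independently by preprocessing and
    chaining; edges never cross components.
    """
    parent: dict[str, str] = {v: v for v in g.vertices}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for v, u in g.edges():
        rv, ru = find(v), find(u)
        if rv != ru:
            parent[ru] = rv

    groups: dict[str, list[str]] = {}
    for v in g.vertices:
        groups.setdefault(find(v), []).append(v)
    comps = sorted(groups.values(), key=lambda vs: min(vs))
    return [g.subgraph(vs) for vs in comps]
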