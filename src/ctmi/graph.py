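"""Summary causal graphs with endpoint marks, and separating-set storage.

Nodes are whole time series.  Each edge carries a mark at either endpoint
drawn from {tail, arrow, circle}:

* ``skeleton`` / ``cpdag`` mode uses tails and arrows only; a directed
  edge ``p -> q`` is tail at ``p``, arrow at ``q``; tail–tail is
  undirected, and arrow–arrow (bidirected) is forbidden under causal
  sufficiency.
* ``pag`` mode additionally allows the circle (undetermined) mark, as in
  partial ancestral graphs.

Every node implicitly carries a lag-1 self-loop (first-order Markov
self-causation); self-loops are never tested or scored and are stored
only as flags.
"""

from __future__ import annotations

import json
from typing import Iterable, Iterator

import networkx as nx

__all__ = ["TAIL", "ARROW", "CIRCLE", "SummaryGraph", "SepsetStore"]

TAIL = "-"
ARROW = ">"
CIRCLE = "o"
_MARKS = {TAIL, ARROW, CIRCLE}


class SummaryGraph:
    """Mixed graph over series with marked endpoints."""

    def __init__(self, nodes: Iterable[str], mode: str = "skeleton") -> None:
        if mode not in {"skeleton", "cpdag", "pag"}:
            raise ValueError(f"unknown mode {mode!r}")
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self.mode = mode
        self._edges: dict[frozenset, dict[str, str]] = {}
        self.self_loops: dict[str, bool] = {n: True for n in self.nodes}

    # -- construction -----------------------------------------------------
    @classmethod
    def complete(cls, nodes: Iterable[str], mode: str = "skeleton") -> "SummaryGraph":
        g = cls(nodes, mode=mode)
        for i, p in enumerate(g.nodes):
            for q in g.nodes[i + 1:]:
                g.add_edge(p, q)
        return g

    def copy(self) -> "SummaryGraph":
        g = SummaryGraph(self.nodes, mode=self.mode)
        g._edges = {k: dict(v) for k, v in self._edges.items()}
        g.self_loops = dict(self.self_loops)
        return g

    def _key(self, p: str, q: str) -> frozenset:
        if p == q:
            raise ValueError("self-loops are implicit, not edges")
        if p not in self.self_loops or q not in self.self_loops:
            raise KeyError(f"unknown node in ({p!r}, {q!r})")
        return frozenset((p, q))

    def add_edge(self, p: str, q: str, mark_p: str | None = None, mark_q: str | None = None) -> None:
        default = CIRCLE if self.mode == "pag" else TAIL
        mark_p = default if mark_p is None else mark_p
        mark_q = default if mark_q is None else mark_q
        if mark_p not in _MARKS or mark_q not in _MARKS:
            raise ValueError("marks must be tail '-', arrow '>' or circle 'o'")
        self._edges[self._key(p, q)] = {p: mark_p, q: mark_q}

    def remove_edge(self, p: str, q: str) -> None:
        del self._edges[self._key(p, q)]

    # -- queries ----------------------------------------------------------
    def has_edge(self, p: str, q: str) -> bool:
        return self._key(p, q) in self._edges

    def adjacent(self, p: str) -> list[str]:
        return [next(iter(k - {p})) for k in self._edges if p in k]

    def edges(self) -> Iterator[tuple[str, str]]:
        """Edges as node pairs in canonical node order."""
        order = {n: i for i, n in enumerate(self.nodes)}
        for k in list(self._edges):
            p, q = sorted(k, key=order.get)
            yield p, q

    def n_edges(self) -> int:
        return len(self._edges)

    def mark(self, p: str, q: str, at: str) -> str:
        """Mark carried by edge (p, q) at endpoint ``at``."""
        return self._edges[self._key(p, q)][at]

    def set_mark(self, p: str, q: str, at: str, mark: str) -> None:
        if mark not in _MARKS:
            raise ValueError(f"invalid mark {mark!r}")
        self._edges[self._key(p, q)][at] = mark

    def orient(self, p: str, q: str) -> None:
        """Fully orient p -> q (tail at p, arrow at q)."""
        e = self._edges[self._key(p, q)]
        e[p] = TAIL
        e[q] = ARROW

    def is_directed(self, p: str, q: str) -> bool:
        """True iff the edge is p -> q (arrow at q, non-arrow at p)."""
        if not self.has_edge(p, q):
            return False
        e = self._edges[self._key(p, q)]
        return e[q] == ARROW and e[p] != ARROW

    def is_bidirected(self, p: str, q: str) -> bool:
        if not self.has_edge(p, q):
            return False
        e = self._edges[self._key(p, q)]
        return e[p] == ARROW and e[q] == ARROW

    def is_undetermined(self, p: str, q: str) -> bool:
        """Edge present but not oriented into either endpoint."""
        e = self._edges[self._key(p, q)]
        return ARROW not in (e[p], e[q])

    def directed_pairs(self) -> set[tuple[str, str]]:
        return {(p, q) for p, q in self.edges() if self.is_directed(p, q)} | {
            (q, p) for p, q in self.edges() if self.is_directed(q, p)
        }

    def bidirected_pairs(self) -> set[frozenset]:
        return {frozenset((p, q)) for p, q in self.edges() if self.is_bidirected(p, q)}

    def to_digraph(self) -> nx.DiGraph:
        """Directed edges only, as a networkx DiGraph (for cycle checks)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_pairs())
        return g

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for k, marks in self._edges.items():
            vals = set(marks.values())
            if self.mode in {"skeleton", "cpdag"}:
                if CIRCLE in vals:
                    raise ValueError("circle marks only allowed in pag mode")
                if vals == {ARROW}:
                    raise ValueError("bidirected edge forbidden under causal sufficiency")
        if self.mode == "cpdag" and not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise ValueError("directed subgraph contains a cycle")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryGraph):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        parts = []
        for p, q in self.edges():
            mp, mq = self.mark(p, q, p), self.mark(p, q, q)
            left = {"-": "-", ">": "<", "o": "o"}[mp]
            parts.append(f"{p} {left}-{mq} {q}")
        return f"SummaryGraph({self.mode}; " + "; ".join(parts) + ")"

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tmark_source\tmark_target\n")
            for p, q in self.edges():
                fh.write(f"{p}\t{q}\t{self.mark(p, q, p)}\t{self.mark(p, q, q)}\n")

    @classmethod
    def from_tsv(cls, path, nodes: Iterable[str] | None = None, mode: str = "pag") -> "SummaryGraph":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source"):
                raise ValueError("missing edge-list header")
            for line in fh:
                if line.strip():
                    rows.append(line.rstrip("\n").split("\t"))
        if nodes is None:
            nodes = sorted({r[0] for r in rows} | {r[1] for r in rows})
        g = cls(nodes, mode=mode)
        for p, q, mp, mq in rows:
            g.add_edge(p, q, mp, mq)
        return g

    def to_json_obj(self, sepsets: "SepsetStore | None" = None, extra: dict | None = None) -> dict:
        obj = {
            "mode": self.mode,
            "nodes": self.nodes,
            "edges": [
                {
                    "source": p,
                    "target": q,
                    "mark_source": self.mark(p, q, p),
                    "mark_target": self.mark(p, q, q),
                    **(extra.get(frozenset((p, q)), {}) if extra else {}),
                }
                for p, q in self.edges()
            ],
        }
        if sepsets is not None:
            obj["sepsets"] = [
                {"pair": sorted(k), "sepset": sorted(v)} for k, v in sepsets.items()
            ]
        return obj

    def to_json(self, path, sepsets: "SepsetStore | None" = None, extra: dict | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(sepsets, extra), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SummaryGraph":
        with open(path) as fh:
            obj = json.load(fh)
        g = cls(obj["nodes"], mode=obj.get("mode", "pag"))
        for e in obj["edges"]:
            g.add_edge(e["source"], e["target"], e["mark_source"], e["mark_target"])
        return g


class SepsetStore:
    """Separating sets keyed by unordered pair."""

    def __init__(self) -> None:
        self._store: dict[frozenset, set[str]] = {}

    def set(self, p: str, q: str, sepset: Iterable[str]) -> None:
        s = set(sepset)
        if p in s or q in s:
            raise ValueError("sepset must exclude the pair itself")
        self._store[frozenset((p, q))] = s

    def get(self, p: str, q: str) -> set[str] | None:
        return self._store.get(frozenset((p, q)))

    def contains(self, p: str, q: str, r: str) -> bool:
        s = self.get(p, q)
        return s is not None and r in s

    def items(self):
        return self._store.items()
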