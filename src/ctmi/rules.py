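"""Orientation rules for summary graphs.

Three rule families act on the skeleton produced by the constraint
phase:

* PC rules 0–3 (collider detection and Meek-style propagation) for the
  causally sufficient case, producing a CPDAG;
* FCI rules 0–4 and 8–10 (arrowhead/tail completion on partial ancestral
  graphs) for the latent-confounder case — the selection-bias rules are
  deliberately absent;
* entropy-reduction (ER) rules, which orient a remaining edge along the
  sign of the pair's optimal lag (or, at lag zero, from the smaller
  optimal window toward the larger), provided the two endpoints admit no
  *possible spurious correlation* — an alternative collider-free path.

Conflicting demands on one edge are handled conservatively: the first
orientation written in a pass stands; a later rule demanding the
opposite arrowhead reverts the edge to its undetermined state, logs the
conflict, and freezes the edge against further orientation (which also
bounds the number of rule firings).
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

from .graph import ARROW, CIRCLE, TAIL, SepsetStore, SummaryGraph

logger = logging.getLogger(__name__)

__all__ = [
    "possible_spurious_correlation",
    "possible_dsep",
    "apply_pc_rule0",
    "apply_pc_rules",
    "apply_er_rules",
    "apply_fci_rule0",
    "apply_fci_rules",
]


# ---------------------------------------------------------------------------
# path predicates
# ---------------------------------------------------------------------------

def _is_collider(g: SummaryGraph, w: str, s: str, v: str) -> bool:
    """True iff s is a collider on the subpath w *-> s <-* v.

    Circle marks are treated as non-arrows (conservative: fewer
    colliders, more paths count as potentially spurious).
    """
    return g.mark(w, s, s) == ARROW and g.mark(s, v, s) == ARROW


def possible_spurious_correlation(g: SummaryGraph, p: str, q: str) -> bool:
    """Is there a collider-free path between p and q besides the edge?

    Direct application of the spurious-correlation notion: some path
    between the two endpoints avoids the edge p–q and contains no
    collider, so their observed dependence need not be a direct causal
    one.
    """
    if not g.has_edge(p, q):
        raise ValueError(f"({p}, {q}) must be adjacent")

    def dfs(node: str, prev: str | None, visited: set[str]) -> bool:
        for nxt in g.adjacent(node):
            if node == p and nxt == q:
                continue  # skip the edge p-q itself
            if nxt in visited:
                continue
            if prev is not None and _is_collider(g, prev, node, nxt):
                continue
            if nxt == q:
                return True
            if dfs(nxt, node, visited | {nxt}):
                return True
        return False

    return dfs(p, None, {p})


def possible_dsep(g: SummaryGraph, p: str, q: str) -> set[str]:
    """Possible-Dsep set of (p, q).

    A node r belongs iff there is a path from p to r on which every
    internal node is either a collider or has adjacent neighbors on the
    path (a triangle).
    """
    out: set[str] = set()

    def dfs(path: list[str]) -> None:
        node = path[-1]
        for nxt in g.adjacent(node):
            if nxt in path:
                continue
            if len(path) >= 2:
                w, s = path[-2], node
                if not (_is_collider(g, w, s, nxt) or g.has_edge(w, nxt)):
                    continue
            if nxt not in (p, q):
                out.add(nxt)
            dfs(path + [nxt])

    dfs([p])
    return out


def _unshielded_triples(g: SummaryGraph) -> Iterable[tuple[str, str, str]]:
    """Ordered triples (p, r, q) with p–r, r–q edges and p, q nonadjacent."""
    for r in g.nodes:
        adj = g.adjacent(r)
        for p, q in itertools.combinations(adj, 2):
            if not g.has_edge(p, q):
                yield p, r, q
                yield q, r, p


# ---------------------------------------------------------------------------
# conflict-aware orientation
# ---------------------------------------------------------------------------

class _Orienter:
    """Writes arrowheads/tails, with first-writer-wins conflict policy.

    In cpdag mode a tail–tail edge is merely *undirected*, so writing an
    arrowhead over a tail is an ordinary orientation; only in pag mode is
    an explicit tail a committed mark.  Writing over an arrowhead is a
    conflict in every mode: the edge reverts to its undetermined state
    and is frozen against further orientation.
    """

    def __init__(self, g: SummaryGraph) -> None:
        self.g = g
        self.frozen: set[frozenset] = set()
        self.changed = False

    def _edge_key(self, p: str, q: str) -> frozenset:
        return frozenset((p, q))

    def put_mark(self, p: str, q: str, at: str, mark: str) -> bool:
        key = self._edge_key(p, q)
        if key in self.frozen or not self.g.has_edge(p, q):
            return False
        cur = self.g.mark(p, q, at)
        if cur == mark:
            return False
        if cur == ARROW and mark != ARROW:
            self._conflict(p, q)
            return False
        if self.g.mode == "pag" and cur == TAIL and mark == ARROW:
            self._conflict(p, q)
            return False
        if self.g.mode != "pag" and mark == ARROW:
            # in cpdag mode an arrowhead directs the edge; refuse to
            # close a directed cycle (summary graphs are acyclic)
            import networkx as nx

            other = next(iter(key - {at}))
            dg = self.g.to_digraph()
            dg.add_edge(other, at)
            if not nx.is_directed_acyclic_graph(dg):
                self._conflict(p, q)
                return False
        self.g.set_mark(p, q, at, mark)
        self.changed = True
        return True

    def _conflict(self, p: str, q: str) -> None:
        logger.warning("conflicting orientations for edge (%s, %s); left undetermined", p, q)
        default = CIRCLE if self.g.mode == "pag" else TAIL
        self.g.set_mark(p, q, p, default)
        self.g.set_mark(p, q, q, default)
        self.frozen.add(self._edge_key(p, q))

    def orient(self, p: str, q: str) -> bool:
        """p -> q: tail at p, arrow at q (skipped on conflict).

        In cpdag mode an orientation that would close a directed cycle
        counts as a conflict (summary graphs are assumed acyclic between
        distinct series).
        """
        import networkx as nx

        key = self._edge_key(p, q)
        if key in self.frozen or not self.g.has_edge(p, q):
            return False
        if self.g.mark(p, q, p) == ARROW:
            self._conflict(p, q)
            return False
        if self.g.mode != "pag":
            dg = self.g.to_digraph()
            dg.add_edge(p, q)
            if not nx.is_directed_acyclic_graph(dg):
                self._conflict(p, q)
                return False
        a = self.put_mark(p, q, q, ARROW)
        b = self.put_mark(p, q, p, TAIL)
        return a or b


def _strict_directed(g: SummaryGraph, a: str, b: str) -> bool:
    """Edge is exactly a -> b (tail at a, arrow at b)."""
    return g.has_edge(a, b) and g.mark(a, b, a) == TAIL and g.mark(a, b, b) == ARROW


# ---------------------------------------------------------------------------
# PC rules (CPDAG)
# ---------------------------------------------------------------------------

def apply_pc_rule0(g: SummaryGraph, sepsets: SepsetStore) -> SummaryGraph:
    """Collider rule: p–r–q unshielded, r not in sepset(p, q) => p->r<-q.

    Never removes or reverses an existing arrowhead: a triple whose
    orientation would require doing so is skipped.
    """
    orienter = _Orienter(g)
    for p, r, q in _unshielded_triples(g):
        if (p, r) > (q, r):
            continue  # handle each unordered triple once
        s = sepsets.get(p, q)
        if s is not None and r in s:
            continue
        if g.is_directed(r, p) or g.is_directed(r, q):
            continue  # would reverse an existing arrowhead
        orienter.put_mark(p, r, r, ARROW)
        orienter.put_mark(q, r, r, ARROW)
    return g


def apply_pc_rules(g: SummaryGraph, sepsets: SepsetStore, rule0: bool = True) -> SummaryGraph:
    """Apply PC-rule 0 once, then iterate rules 1–3 to a fixed point."""
    if rule0:
        apply_pc_rule0(g, sepsets)
    orienter = _Orienter(g)
    while True:
        orienter.changed = False
        _pc_rule1(g, sepsets, orienter)
        _pc_rule2(g, orienter)
        _pc_rule3(g, orienter)
        if not orienter.changed:
            break
    return g


def _pc_rule1(g: SummaryGraph, sepsets: SepsetStore, o: _Orienter) -> None:
    # p -> r - q unshielded, r in sepset(p, q): orient r -> q
    for p, r, q in _unshielded_triples(g):
        if g.is_directed(p, r) and g.is_undetermined(r, q):
            s = sepsets.get(p, q)
            if s is not None and r in s:
                o.orient(r, q)


def _pc_rule2(g: SummaryGraph, o: _Orienter) -> None:
    # directed path p => q plus an edge p - q: orient p -> q
    import networkx as nx

    dg = g.to_digraph()
    for p, q in list(g.edges()):
        for a, b in ((p, q), (q, p)):
            # the undirected edge a-b is absent from dg, so any directed
            # path found here passes through at least one other node
            if g.is_undetermined(a, b) and nx.has_path(dg, a, b):
                o.orient(a, b)


def _pc_rule3(g: SummaryGraph, o: _Orienter) -> None:
    # p -> r <- q collider, p - s - q unshielded, s adjacent r: s -> r
    for p, r, q in _unshielded_triples(g):
        if not (g.is_directed(p, r) and g.is_directed(q, r)):
            continue
        for s in g.nodes:
            if s in (p, q, r) or not g.has_edge(s, r):
                continue
            if (
                g.has_edge(p, s)
                and g.has_edge(q, s)
                and g.is_undetermined(p, s)
                and g.is_undetermined(q, s)
                and g.is_undetermined(s, r)
            ):
                o.orient(s, r)


# ---------------------------------------------------------------------------
# ER rules (entropy reduction)
# ---------------------------------------------------------------------------

def apply_er_rules(
    g: SummaryGraph,
    cache,
    lag_rule_only: bool = False,
    latent: bool = False,
) -> SummaryGraph:
    """Orient remaining edges along the optimal lag / window asymmetry.

    ``cache`` maps unordered pairs to the pairwise optimum (an object
    with ``p``, ``q``, ``gamma_bar``, ``lambda_pq``, ``lambda_qp``).  In
    latent mode only the arrowhead at the effect end is written (the
    cause-end mark stays undetermined).
    """
    orienter = _Orienter(g)
    for p, q in list(g.edges()):
        if not g.is_undetermined(p, q):
            continue
        res = cache.get(frozenset((p, q)))
        if res is None:
            continue
        if possible_spurious_correlation(g, p, q):
            continue
        # express the optimum with p as the reference endpoint
        gamma = res.gamma_bar if res.p == p else -res.gamma_bar
        lam_p = res.lambda_pq if res.p == p else res.lambda_qp
        lam_q = res.lambda_qp if res.p == p else res.lambda_pq
        cause = effect = None
        if gamma > 0:
            cause, effect = p, q
        elif gamma < 0:
            cause, effect = q, p
        elif not lag_rule_only and lam_p < lam_q:
            cause, effect = p, q
        elif not lag_rule_only and lam_q < lam_p:
            cause, effect = q, p
        if cause is None:
            continue
        if latent:
            orienter.put_mark(cause, effect, effect, ARROW)
        else:
            orienter.orient(cause, effect)
    return g


# ---------------------------------------------------------------------------
# FCI rules (PAG)
# ---------------------------------------------------------------------------

def apply_fci_rule0(g: SummaryGraph, sepsets: SepsetStore) -> SummaryGraph:
    """Collider rule with circle marks: p *-o r o-* q => p *-> r <-* q."""
    orienter = _Orienter(g)
    for p, r, q in _unshielded_triples(g):
        if (p, r) > (q, r):
            continue
        s = sepsets.get(p, q)
        if s is not None and r in s:
            continue
        orienter.put_mark(p, r, r, ARROW)
        orienter.put_mark(q, r, r, ARROW)
    return g


def _pd_edge(g: SummaryGraph, a: str, b: str) -> bool:
    """Edge a *-* b is potentially directed a -> b."""
    return g.mark(a, b, a) != ARROW and g.mark(a, b, b) != TAIL


def _uncovered_pd_paths(g: SummaryGraph, src: str, dst: str):
    """All uncovered potentially directed paths from src to dst."""
    results = []

    def dfs(path: list[str]) -> None:
        node = path[-1]
        if node == dst:
            if len(path) >= 2:
                results.append(list(path))
            return
        for nxt in g.adjacent(node):
            if nxt in path:
                continue
            if not _pd_edge(g, node, nxt):
                continue
            if len(path) >= 2 and g.has_edge(path[-2], nxt):
                continue  # covered triple
            dfs(path + [nxt])

    dfs([src])
    return results


def _discriminating_paths(g: SummaryGraph, r: str, q: str):
    """Discriminating paths <p, ..., s, r, q> for r.

    Every vertex strictly between p and r is a collider on the path and
    a parent of q, and p is not adjacent to q.
    """
    paths = []
    if not g.has_edge(r, q):
        return paths

    def dfs(path: list[str]) -> None:
        # path runs backwards: [q, r, s, ...]; candidate p is the next node
        node = path[-1]
        for w in g.adjacent(node):
            if w in path:
                continue
            if len(path) >= 3:
                # node lies strictly between the p-candidate and r: it
                # must be a collider on the path and a parent of q
                if not (
                    g.mark(w, node, node) == ARROW
                    and g.mark(path[-2], node, node) == ARROW
                    and _strict_directed(g, node, q)
                ):
                    continue
            if not g.has_edge(w, q):
                if len(path) >= 3:  # at least three edges in total
                    paths.append(list(reversed(path + [w])))
            else:
                dfs(path + [w])

    dfs([q, r])
    return paths


def apply_fci_rules(g: SummaryGraph, sepsets: SepsetStore, rule0: bool = False) -> SummaryGraph:
    """Iterate FCI rules 1–4 and 8–10 to a fixed point."""
    if rule0:
        apply_fci_rule0(g, sepsets)
    orienter = _Orienter(g)
    while True:
        orienter.changed = False
        _fci_rule1(g, sepsets, orienter)
        _fci_rule2(g, orienter)
        _fci_rule3(g, orienter)
        _fci_rule4(g, sepsets, orienter)
        _fci_rule8(g, orienter)
        _fci_rule9(g, orienter)
        _fci_rule10(g, orienter)
        if not orienter.changed:
            break
    return g


def _fci_rule1(g: SummaryGraph, sepsets: SepsetStore, o: _Orienter) -> None:
    # p *-> r o-* q unshielded, r in sepset(p, q): orient r -> q
    for p, r, q in _unshielded_triples(g):
        if g.mark(p, r, r) == ARROW and g.mark(r, q, r) == CIRCLE:
            s = sepsets.get(p, q)
            if s is not None and r in s:
                o.put_mark(r, q, q, ARROW)
                o.put_mark(r, q, r, TAIL)


def _fci_rule2(g: SummaryGraph, o: _Orienter) -> None:
    # p -> r *-> q  or  p *-> r -> q, with circle at q on p *-o q: p *-> q
    for p, q in [(a, b) for a, b in itertools.permutations(g.nodes, 2) if g.has_edge(a, b)]:
        if g.mark(p, q, q) != CIRCLE:
            continue
        for r in g.nodes:
            if r in (p, q) or not (g.has_edge(p, r) and g.has_edge(r, q)):
                continue
            chain1 = _strict_directed(g, p, r) and g.mark(r, q, q) == ARROW
            chain2 = g.mark(p, r, r) == ARROW and _strict_directed(g, r, q)
            if chain1 or chain2:
                o.put_mark(p, q, q, ARROW)
                break


def _fci_rule3(g: SummaryGraph, o: _Orienter) -> None:
    # p *-> r <-* q unshielded; p *-o s o-* q unshielded; s *-o r: s *-> r
    for p, r, q in _unshielded_triples(g):
        if not (g.mark(p, r, r) == ARROW and g.mark(q, r, r) == ARROW):
            continue
        for s in g.nodes:
            if s in (p, q, r):
                continue
            if not (g.has_edge(p, s) and g.has_edge(q, s) and g.has_edge(s, r)):
                continue
            if g.mark(p, s, s) == CIRCLE and g.mark(q, s, s) == CIRCLE and g.mark(s, r, r) == CIRCLE:
                o.put_mark(s, r, r, ARROW)


def _fci_rule4(g: SummaryGraph, sepsets: SepsetStore, o: _Orienter) -> None:
    # discriminating path <p, ..., s, r, q> for r
    for r in g.nodes:
        for q in g.adjacent(r):
            if g.mark(r, q, r) != CIRCLE:
                continue
            for path in _discriminating_paths(g, r, q):
                p, s = path[0], path[-3]
                sep = sepsets.get(p, q)
                if sep is not None and r in sep:
                    o.put_mark(r, q, q, ARROW)
                    o.put_mark(r, q, r, TAIL)
                else:
                    o.put_mark(s, r, s, ARROW)
                    o.put_mark(s, r, r, ARROW)
                    o.put_mark(r, q, r, ARROW)
                    o.put_mark(r, q, q, ARROW)
                break


def _fci_rule8(g: SummaryGraph, o: _Orienter) -> None:
    # p -> r -> q (or p -o r -> q) and p o-> q: tail at p
    for p, q in [(a, b) for a, b in itertools.permutations(g.nodes, 2) if g.has_edge(a, b)]:
        if not (g.mark(p, q, p) == CIRCLE and g.mark(p, q, q) == ARROW):
            continue
        for r in g.nodes:
            if r in (p, q) or not (g.has_edge(p, r) and g.has_edge(r, q)):
                continue
            first = _strict_directed(g, p, r) or (
                g.mark(p, r, p) == TAIL and g.mark(p, r, r) == CIRCLE
            )
            if first and _strict_directed(g, r, q):
                o.put_mark(p, q, p, TAIL)
                break


def _fci_rule9(g: SummaryGraph, o: _Orienter) -> None:
    # p o-> q with an uncovered pd path p, r, ..., q where r not adjacent q
    for p, q in [(a, b) for a, b in itertools.permutations(g.nodes, 2) if g.has_edge(a, b)]:
        if not (g.mark(p, q, p) == CIRCLE and g.mark(p, q, q) == ARROW):
            continue
        for path in _uncovered_pd_paths(g, p, q):
            if len(path) < 3:
                continue  # the edge itself is not a valid witness
            r = path[1]
            if r != q and not g.has_edge(r, q):
                o.put_mark(p, q, p, TAIL)
                break


def _fci_rule10(g: SummaryGraph, o: _Orienter) -> None:
    for p, q in [(a, b) for a, b in itertools.permutations(g.nodes, 2) if g.has_edge(a, b)]:
        if not (g.mark(p, q, p) == CIRCLE and g.mark(p, q, q) == ARROW):
            continue
        parents = [r for r in g.nodes if r not in (p, q) and _strict_directed(g, r, q)]
        done = False
        for r, s in itertools.permutations(parents, 2):
            paths_r = _uncovered_pd_paths(g, p, r)
            paths_s = _uncovered_pd_paths(g, p, s)
            for u1 in paths_r:
                for u2 in paths_s:
                    mu, om = u1[1], u2[1]
                    if mu != om and not g.has_edge(mu, om):
                        o.put_mark(p, q, p, TAIL)
                        done = True
                        break
                if done:
                    break
            if done:
                break
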