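"""Summary-graph structure learning: PCTMI and FCITMI.

Both algorithms share the PC-stable-style skeleton phase: starting from
the complete graph over series, conditioning sets of growing cardinality
are tested with the (conditional) CTMI permutation test.  Within a
cardinality level all candidate tests are gathered first, sorted by
increasing estimated dependence, and then popped and tested — adjacency
is re-checked at pop time, which makes the procedure order-independent
given deterministic tests.  Candidate conditioning series are restricted
to those whose cached optimal lag places them not strictly in the future
of both endpoints.

PCTMI (causal sufficiency) orients the skeleton with the lag-based
entropy-reduction rule first (more reliable than the collider rule for
lagged relations at realistic sample sizes), then PC-rules 0–3, then the
entropy-reduction rules on whatever remains.  FCITMI additionally runs a
Possible-Dsep removal phase and the FCI rule set, producing a partial
ancestral graph; its entropy-reduction variants write arrowheads only.

The statistical test can be replaced by a perfect d-separation oracle
(``DSeparationOracle``), which is how the algorithms' correctness is
exercised independently of estimation error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import networkx as nx

from .errors import CTMIError
from .estimator import EstimatorConfig, local_permutation_test
from .graph import SepsetStore, SummaryGraph
from .measure import CTMIResult, conditional_ctmi, ctmi, prepare_panel
from .rules import (
    apply_er_rules,
    apply_fci_rule0,
    apply_fci_rules,
    apply_pc_rule0,
    apply_pc_rules,
    possible_dsep,
)
from .timeseries import SearchSpace, TimeSeriesPanel

logger = logging.getLogger(__name__)

__all__ = [
    "CITester",
    "CTMITester",
    "DSeparationOracle",
    "build_skeleton",
    "pctmi",
    "fcitmi",
]


class CITester(Protocol):
    """Interface of the dependence engine used by the discovery loop."""

    nodes: list[str]

    def pairwise(self, p: str, q: str) -> CTMIResult:
        """Pairwise optimum (value, optimal lag and windows)."""
        ...

    def value(self, p: str, q: str, R: tuple[str, ...]) -> float:
        """Measure value used for sorting candidate tests."""
        ...

    def p_value(self, p: str, q: str, R: tuple[str, ...]) -> float:
        """Permutation p-value of the (conditional) independence test."""
        ...


@dataclass
class CTMITester:
    """CTMI-based tester with per-(pair, set) caching.

    Standardizes the panel once (with seeded tie-break jitter) and caches
    every optimization and test so that repeated queries from the
    discovery loops are free.
    """

    panel: TimeSeriesPanel
    space: SearchSpace
    cfg: EstimatorConfig = field(default_factory=EstimatorConfig)
    search: str = "exhaustive"
    n_tests: int = 0

    def __post_init__(self) -> None:
        self.nodes = list(self.panel.names)
        self._prepared = prepare_panel(self.panel, self.cfg)
        self._pair_cache: dict[frozenset, CTMIResult] = {}
        self._cond_cache: dict = {}
        self._p_cache: dict = {}

    def pairwise(self, p: str, q: str) -> CTMIResult:
        key = frozenset((p, q))
        if key not in self._pair_cache:
            res = ctmi(
                self._prepared, p, q, self.space, self.cfg,
                search=self.search, standardize=False,
            )
            self._pair_cache[key] = res
        res = self._pair_cache[key]
        if res.p == p:
            return res
        return CTMIResult(
            p=p, q=q, value=res.value, gamma_bar=-res.gamma_bar,
            lambda_pq=res.lambda_qp, lambda_qp=res.lambda_pq,
            n=res.n, sample=res.sample,
        )

    def _conditional(self, p, q, R):
        key = (frozenset((p, q)), frozenset(R))
        if key not in self._cond_cache:
            base = self._pair_cache[frozenset((p, q))]
            self._cond_cache[key] = conditional_ctmi(
                self._prepared, base.p, base.q, list(R), base,
                self.space, self.cfg, standardize=False,
            )
        return self._cond_cache[key]

    def value(self, p: str, q: str, R: tuple[str, ...]) -> float:
        if not R:
            return self.pairwise(p, q).value
        return self._conditional(p, q, R).value

    def p_value(self, p: str, q: str, R: tuple[str, ...]) -> float:
        key = (frozenset((p, q)), frozenset(R))
        if key in self._p_cache:
            return self._p_cache[key]
        if R:
            res = self._conditional(p, q, R)
        else:
            self.pairwise(p, q)
            res = self._pair_cache[frozenset((p, q))]
        sample = res.sample
        pv, _ = local_permutation_test(
            sample.x_block, sample.y_block, sample.z_block(), self.cfg
        )
        self._p_cache[key] = pv
        self.n_tests += 1
        return pv


@dataclass
class DSeparationOracle:
    """Perfect conditional-independence information from a ground truth.

    ``truth_edges`` are the directed inter-series edges (with their lags)
    of the generating summary graph, ``hidden`` the unobserved series.
    Independence is decided by d-separation on the DAG over all series
    (self-loops play no role between distinct series); the pairwise
    "optimum" reports the generating lag, with unit windows unless
    per-edge windows are supplied.
    """

    nodes: list[str]
    truth_edges: Sequence[tuple[str, str, int]]
    hidden: Sequence[str] = ()
    windows: dict | None = None
    n_tests: int = 0

    def __post_init__(self) -> None:
        self._dag = nx.DiGraph()
        self._dag.add_nodes_from(list(self.nodes) + list(self.hidden))
        self._dag.add_edges_from((c, e) for c, e, _ in self.truth_edges)
        if not nx.is_directed_acyclic_graph(self._dag):
            raise ValueError("ground truth must be acyclic")
        self._lags = {(c, e): g for c, e, g in self.truth_edges}

    def _dsep(self, p: str, q: str, R: tuple[str, ...]) -> bool:
        return nx.is_d_separator(self._dag, {p}, {q}, set(R))

    def pairwise(self, p: str, q: str) -> CTMIResult:
        dep = not self._dsep(p, q, ())
        if (p, q) in self._lags:
            gamma = self._lags[(p, q)]
        elif (q, p) in self._lags:
            gamma = -self._lags[(q, p)]
        else:
            gamma = 0
        lam_pq, lam_qp = (1, 1)
        if self.windows and frozenset((p, q)) in self.windows:
            lam_pq, lam_qp = self.windows[frozenset((p, q))]
            if (q, p) in self._lags:
                lam_pq, lam_qp = lam_qp, lam_pq
        return CTMIResult(
            p=p, q=q, value=1.0 if dep else 0.0, gamma_bar=gamma,
            lambda_pq=lam_pq, lambda_qp=lam_qp, n=0,
        )

    def value(self, p: str, q: str, R: tuple[str, ...]) -> float:
        return 0.0 if self._dsep(p, q, R) else 1.0

    def p_value(self, p: str, q: str, R: tuple[str, ...]) -> float:
        self.n_tests += 1
        return 1.0 if self._dsep(p, q, R) else 0.0


def _lag_admissible(tester: CITester, p: str, q: str, R: Sequence[str]) -> bool:
    """Conditioners must not lie strictly in the future of both endpoints."""
    for r in R:
        if tester.pairwise(r, p).gamma_bar >= 0 or tester.pairwise(r, q).gamma_bar >= 0:
            continue
        return False
    return True


def build_skeleton(
    tester: CITester,
    alpha: float = 0.05,
    max_cond: int | None = None,
) -> tuple[SummaryGraph, SepsetStore, dict]:
    """PC-stable-style skeleton with CTMI tests.

    Returns the skeleton, the separating sets, and the cache of pairwise
    optima (one entry per unordered pair; entries for surviving edges
    feed the entropy-reduction orientation rules).
    """
    nodes = list(tester.nodes)
    g = SummaryGraph.complete(nodes, mode="skeleton")
    sepsets = SepsetStore()
    cache: dict[frozenset, CTMIResult] = {}
    for p, q in itertools.combinations(nodes, 2):
        cache[frozenset((p, q))] = tester.pairwise(p, q)

    n = 0
    while any(len(g.adjacent(v)) >= n + 1 for v in nodes):
        if max_cond is not None and n > max_cond:
            break
        candidates = []
        seen = set()
        for q in nodes:
            adj_q = g.adjacent(q)
            if len(adj_q) < n + 1:
                continue
            for p in adj_q:
                for R in itertools.combinations([a for a in adj_q if a != p], n):
                    key = (frozenset((p, q)), frozenset(R))
                    if key in seen:
                        continue
                    seen.add(key)
                    if not _lag_admissible(tester, p, q, R):
                        continue
                    try:
                        y = tester.value(p, q, tuple(R))
                    except CTMIError as exc:
                        logger.warning(
                            "measure failed for (%s,%s|%s): %s; edge retained",
                            p, q, R, exc,
                        )
                        continue
                    candidates.append((y, p, q, tuple(R)))
        candidates.sort(key=lambda t: t[0])
        for y, p, q, R in candidates:
            if not g.has_edge(p, q):
                continue
            adj = set(g.adjacent(p)) | set(g.adjacent(q))
            if not set(R) <= adj:
                continue
            try:
                z = tester.p_value(p, q, R)
            except CTMIError as exc:
                logger.warning("test failed for (%s,%s|%s): %s; edge retained", p, q, R, exc)
                continue
            if z > alpha:
                g.remove_edge(p, q)
                sepsets.set(p, q, R)
        n += 1
    return g, sepsets, cache


def pctmi(
    panel: TimeSeriesPanel | None = None,
    space: SearchSpace | None = None,
    cfg: EstimatorConfig | None = None,
    tester: CITester | None = None,
    search: str = "exhaustive",
    er_first: bool = True,
) -> SummaryGraph:
    """Infer a (partially oriented) summary CPDAG under causal sufficiency.

    Pipeline: skeleton -> lag-based entropy-reduction orientation of
    lagged edges (``er_first=False`` restores the textbook order) ->
    collider rule -> propagation rules to fixed point -> entropy-reduction
    rules on remaining pairs.  All lagged relations come out oriented;
    instantaneous ones may stay undirected.
    """
    if tester is None:
        if panel is None:
            raise ValueError("either a panel or a tester is required")
        space = space or SearchSpace(gamma_max=5)
        cfg = cfg or EstimatorConfig()
        tester = CTMITester(panel=panel, space=space, cfg=cfg, search=search)
    alpha = tester.cfg.alpha if hasattr(tester, "cfg") else 0.05
    g, sepsets, cache = build_skeleton(tester, alpha=alpha)
    g.mode = "cpdag"
    if er_first:
        apply_er_rules(g, cache, lag_rule_only=True)
    apply_pc_rule0(g, sepsets)
    apply_pc_rules(g, sepsets, rule0=False)
    apply_er_rules(g, cache)
    g.validate()
    return g


def fcitmi(
    panel: TimeSeriesPanel | None = None,
    space: SearchSpace | None = None,
    cfg: EstimatorConfig | None = None,
    tester: CITester | None = None,
    search: str = "exhaustive",
    pdsep_max_cond: int = 3,
) -> SummaryGraph:
    """Infer a summary PAG allowing hidden common causes.

    After the shared skeleton phase and a first collider pass, edges are
    re-tested against subsets of the Possible-Dsep sets (cardinality
    capped at ``pdsep_max_cond``), all marks are reset to circles, and
    the FCI rule set plus the latent entropy-reduction rules complete
    the orientation.
    """
    if tester is None:
        if panel is None:
            raise ValueError("either a panel or a tester is required")
        space = space or SearchSpace(gamma_max=5)
        cfg = cfg or EstimatorConfig()
        tester = CTMITester(panel=panel, space=space, cfg=cfg, search=search)
    alpha = tester.cfg.alpha if hasattr(tester, "cfg") else 0.05
    g, sepsets, cache = build_skeleton(tester, alpha=alpha)
    g.mode = "pag"
    for p, q in g.edges():
        g.add_edge(p, q)  # reset to circle-circle in pag mode
    apply_fci_rule0(g, sepsets)

    # Possible-Dsep removal phase, with the same sort-then-pop strategy
    for n in range(1, pdsep_max_cond + 1):
        candidates = []
        seen = set()
        for p, q in list(g.edges()):
            pool = (possible_dsep(g, p, q) | possible_dsep(g, q, p)) - {p, q}
            for R in itertools.combinations(sorted(pool), n):
                key = (frozenset((p, q)), frozenset(R))
                if key in seen:
                    continue
                seen.add(key)
                if not _lag_admissible(tester, p, q, R):
                    continue
                try:
                    y = tester.value(p, q, tuple(R))
                except CTMIError as exc:
                    logger.warning("measure failed for (%s,%s|%s): %s", p, q, R, exc)
                    continue
                candidates.append((y, p, q, tuple(R)))
        candidates.sort(key=lambda t: t[0])
        for y, p, q, R in candidates:
            if not g.has_edge(p, q):
                continue
            try:
                z = tester.p_value(p, q, R)
            except CTMIError as exc:
                logger.warning("test failed for (%s,%s|%s): %s; edge retained", p, q, R, exc)
                continue
            if z > alpha:
                g.remove_edge(p, q)
                sepsets.set(p, q, R)

    # reorient everything and run the FCI rule set
    for p, q in g.edges():
        g.add_edge(p, q)
    apply_fci_rule0(g, sepsets)
    apply_fci_rules(g, sepsets)
    apply_er_rules(g, cache, latent=True)
    g.validate()
    return g
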