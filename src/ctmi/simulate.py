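"""Structural-equation time-series generator and benchmark structures.

Each series follows

    X_t^q = a_qq * X_{t-1}^q + sum_parents a_pq * f(X_{t-gamma}^p) + s * xi_t^q

from the zero initial state, with coefficients drawn once per edge
uniformly on +-[coef_low, coef_high], a nonlinearity per edge drawn
uniformly from {absolute value, tanh, sine, cosine}, and Gaussian
innovations xi ~ N(0, noise_var) scaled by ``noise_scale`` (defaults:
variance 15, scale 0.1, so the innovation standard deviation is about
0.39).  Hidden series are simulated and then dropped from the output
panel; the returned ground-truth summary graph connects the observed
children of each dropped hidden cause with a bidirected edge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .graph import ARROW, TAIL, SummaryGraph
from .timeseries import TimeSeriesPanel

logger = logging.getLogger(__name__)

__all__ = ["StructureSpec", "generate_panel", "builtin_structures", "decimate"]

_NONLINEARITIES = {
    "abs": np.abs,
    "tanh": np.tanh,
    "sin": np.sin,
    "cos": np.cos,
}


@dataclass(frozen=True)
class StructureSpec:
    """Ground-truth causal structure for the generator.

    ``edges`` are lagged directed inter-series relations (cause, effect,
    lag >= 0); every node additionally causes itself at lag 1.  ``hidden``
    nodes are simulated but removed from the output.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]
    hidden: tuple[str, ...] = ()
    noise_scale: float = 0.1
    noise_var: float = 15.0
    coef_low: float = 0.1
    coef_high: float = 1.0
    nonlinearities: tuple[str, ...] = ("abs", "tanh", "sin", "cos")

    def __post_init__(self) -> None:
        dag = nx.DiGraph()
        dag.add_nodes_from(self.nodes)
        for c, e, g in self.edges:
            if c == e:
                raise ValueError("self-loops are implicit; list inter-series edges only")
            if g < 0:
                raise ValueError("lags must be nonnegative")
            dag.add_edge(c, e)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("summary structure must be acyclic")
        if not set(self.hidden) <= set(self.nodes):
            raise ValueError("hidden nodes must be listed in nodes")
        for f in self.nonlinearities:
            if f not in _NONLINEARITIES:
                raise ValueError(f"unknown nonlinearity {f!r}")

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.hidden)

    def truth_graph(self) -> SummaryGraph:
        """Ground-truth summary graph over the observed nodes.

        Directed edges between observed series; a bidirected edge between
        every pair of observed children of a dropped hidden cause.
        """
        hidden = set(self.hidden)
        g = SummaryGraph(self.observed, mode="pag" if hidden else "cpdag")
        for c, e, _ in self.edges:
            if c not in hidden and e not in hidden:
                g.add_edge(c, e, TAIL, ARROW)
        for h in hidden:
            children = [e for c, e, _ in self.edges if c == h and e not in hidden]
            for i, a in enumerate(children):
                for b in children[i + 1:]:
                    if not g.has_edge(a, b):
                        g.add_edge(a, b, ARROW, ARROW)
        return g


def generate_panel(
    spec: StructureSpec,
    T: int = 1000,
    seed: int = 0,
    burn_in: int = 0,
) -> tuple[TimeSeriesPanel, SummaryGraph]:
    """Simulate the structural process and return (panel, truth graph).

    Trajectories that explode numerically (|X| > 1e12, possible with the
    absolute-value nonlinearity) are regenerated with a fresh coefficient
    draw from the same stream, with a logged warning.
    """
    if T < 10:
        raise ValueError("T must be at least 10")
    max_lag = max((g for _, _, g in spec.edges), default=0)
    if max_lag >= T:
        raise ValueError("lags must be smaller than T")
    rng = np.random.default_rng(seed)
    total = T + burn_in

    for attempt in range(10):
        self_coef = {n: _draw_coef(rng, spec) for n in spec.nodes}
        edge_coef = {e: _draw_coef(rng, spec) for e in spec.edges}
        edge_fun = {
            e: _NONLINEARITIES[rng.choice(spec.nonlinearities)] for e in spec.edges
        }
        noise = rng.normal(
            0.0, math.sqrt(spec.noise_var), size=(total + 1, len(spec.nodes))
        )
        pos = {n: i for i, n in enumerate(spec.nodes)}
        x = np.zeros((total + 1, len(spec.nodes)))
        parents: dict[str, list] = {n: [] for n in spec.nodes}
        for (c, e, g) in spec.edges:
            parents[e].append((c, g, edge_coef[(c, e, g)], edge_fun[(c, e, g)]))
        for t in range(1, total + 1):
            for n in spec.nodes:
                j = pos[n]
                v = self_coef[n] * x[t - 1, j]
                for c, g, a, f in parents[n]:
                    if t - g >= 0:
                        v += a * f(x[t - g, pos[c]])
                x[t, j] = v + spec.noise_scale * noise[t, j]
        if np.abs(x).max() <= 1e12:
            break
        logger.warning("explosive trajectory (attempt %d); redrawing coefficients", attempt + 1)
    else:
        raise RuntimeError("could not generate a stable trajectory in 10 attempts")

    data = {n: x[1 + burn_in:, pos[n]] for n in spec.observed}
    return TimeSeriesPanel(data), spec.truth_graph()


def _draw_coef(rng: np.random.Generator, spec: StructureSpec) -> float:
    mag = rng.uniform(spec.coef_low, spec.coef_high)
    return mag if rng.random() < 0.5 else -mag


def builtin_structures(lag: int = 1) -> dict[str, StructureSpec]:
    """The benchmark structures: fork, v-structure, diamond, and a
    7-observed / 2-hidden latent template.

    Inter-series lags default to 1.  The latent template is a synthetic
    reconstruction, not a copy of any published figure: two hidden common
    causes, each with two observed children, and each confounded child
    also has an observed parent — the configuration in which a partial
    ancestral graph can actually identify the bidirected edges.
    """
    return {
        "fork": StructureSpec(
            nodes=("X1", "X2", "X3"),
            edges=(("X1", "X2", lag), ("X1", "X3", lag)),
        ),
        "v_structure": StructureSpec(
            nodes=("X1", "X2", "X3"),
            edges=(("X1", "X3", lag), ("X2", "X3", lag)),
        ),
        "diamond": StructureSpec(
            nodes=("X1", "X2", "X3", "X4"),
            edges=(
                ("X1", "X2", lag),
                ("X1", "X3", lag),
                ("X2", "X4", lag),
                ("X3", "X4", lag),
            ),
        ),
        "7ts2h": StructureSpec(
            nodes=("X1", "X2", "X3", "X4", "X5", "X6", "X7", "H1", "H2"),
            edges=(
                ("X1", "X2", lag),
                ("H1", "X2", lag),
                ("H1", "X3", lag),
                ("X4", "X3", lag),
                ("X4", "X5", lag),
                ("H2", "X5", lag),
                ("H2", "X6", lag),
                ("X7", "X6", lag),
            ),
            hidden=("H1", "H2"),
        ),
    }


def decimate(
    panel: TimeSeriesPanel,
    keep_every: int | Mapping[str, int],
) -> TimeSeriesPanel:
    """Retain every m-th observation per series, updating rate metadata.

    The new common time unit is the smallest interval on which every
    decimated series has an integer number of observations.
    """
    if isinstance(keep_every, int):
        keep = {n: keep_every for n in panel.names}
    else:
        keep = {n: int(keep_every.get(n, 1)) for n in panel.names}
    for n, m in keep.items():
        if m < 1:
            raise ValueError("keep_every must be positive")
        if m >= panel.n_obs(n):
            raise ValueError(f"keep_every={m} leaves series {n!r} empty")
    # new unit = U old units such that rate * U / m is an integer for all
    unit = math.lcm(*(m // math.gcd(m, panel.rates[n]) for n, m in keep.items()))
    data = {n: panel.series(n)[:: keep[n]] for n in panel.names}
    rates = {n: panel.rates[n] * unit // keep[n] for n in panel.names}
    return TimeSeriesPanel(data, rates=rates, starts=dict(panel.starts))
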