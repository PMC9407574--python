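"""Causal temporal mutual information (CTMI) and its conditional form.

CTMI between two series maximizes the estimated conditional mutual
information between their window embeddings over all compatible lags and
window sizes, conditioning on the one-step past of both series (the
first-order Markov self-causal assumption).  Ties are broken by taking
the largest lag first, then the smallest window of the first series, then
the smallest window of the second.

The conditional form holds the optimal pair (lag, windows) fixed and
*minimizes* the estimate over lags and windows of the conditioning
series, so that a separating set is found whenever one exists.  Ties are
broken by the largest conditioning lag, then the smallest window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptySampleError, EstimationInfeasibleError, SampleSizeError
from .estimator import CMIEstimate, EstimatorConfig, knn_cmi, local_permutation_test
from .timeseries import JointSample, SearchSpace, TimeSeriesPanel, align_joint_sample

logger = logging.getLogger(__name__)

__all__ = [
    "CTMIResult",
    "CondCTMIResult",
    "DecisionResult",
    "prepare_panel",
    "ctmi",
    "conditional_ctmi",
    "independence_decision",
]


@dataclass
class CTMIResult:
    """Optimum of the pairwise dependence search.

    ``value`` is the maximal estimated CMI in nats (kept signed for
    ranking; floor at 0 for reporting).  ``gamma_bar`` is the optimal lag
    from ``p`` to ``q`` in ticks, ``lambda_pq``/``lambda_qp`` the optimal
    window sizes.
    """

    p: str
    q: str
    value: float
    gamma_bar: int
    lambda_pq: int
    lambda_qp: int
    n: int
    sample: JointSample | None = field(default=None, repr=False)

    @property
    def reported_value(self) -> float:
        return max(self.value, 0.0)

    def to_record(self) -> dict:
        return {
            "pair": [self.p, self.q],
            "value": self.reported_value,
            "gamma_bar": self.gamma_bar,
            "lambda_pq": self.lambda_pq,
            "lambda_qp": self.lambda_qp,
            "n": self.n,
        }


@dataclass
class CondCTMIResult:
    """Minimum of the conditional dependence search.

    Inherits the pair's (gamma_bar, lambda_pq, lambda_qp) from the
    unconditional optimum; records the optimal lag and window of every
    conditioning series.
    """

    p: str
    q: str
    cond: tuple[str, ...]
    value: float
    gamma_bar: int
    lambda_pq: int
    lambda_qp: int
    cond_gammas: tuple[int, ...]
    cond_lambdas: tuple[int, ...]
    n: int
    sample: JointSample | None = field(default=None, repr=False)

    @property
    def reported_value(self) -> float:
        return max(self.value, 0.0)


@dataclass
class DecisionResult:
    """Outcome of the CTMI independence decision for a (pair, set) triple."""

    dependent: bool
    p_value: float
    result: CTMIResult | CondCTMIResult


def prepare_panel(panel: TimeSeriesPanel, cfg: EstimatorConfig) -> TimeSeriesPanel:
    """Standardize each series and add seeded tie-break jitter.

    The sup-distance is scale-sensitive, so every series is brought to
    zero mean and unit variance before estimation; a tiny uniform jitter
    breaks exact distance ties once at load time.
    """
    rng = np.random.default_rng(cfg.seed)

    def _prep(v: np.ndarray) -> np.ndarray:
        sd = np.nanstd(v)
        if sd == 0 or not np.isfinite(sd):
            sd = 1.0
        out = (v - np.nanmean(v)) / sd
        return out + rng.uniform(0.0, cfg.noise_amp, size=out.shape)

    return panel.transform(_prep)


def _estimate_at(
    panel: TimeSeriesPanel,
    p: str,
    q: str,
    lam_pq: int,
    lam_qp: int,
    gamma: int,
    cond: Sequence[tuple[str, int, int]],
    cfg: EstimatorConfig,
) -> tuple[float, JointSample] | None:
    """CMI estimate at one grid point; None when no usable sample exists."""
    try:
        sample = align_joint_sample(panel, p, q, lam_pq, lam_qp, gamma, cond)
    except EmptySampleError:
        return None
    if sample.n <= cfg.k:
        return None
    est = knn_cmi(sample.x_block, sample.y_block, sample.z_block(), cfg)
    return est.value, sample


def ctmi(
    panel: TimeSeriesPanel,
    p: str,
    q: str,
    space: SearchSpace,
    cfg: EstimatorConfig | None = None,
    search: str = "exhaustive",
    standardize: bool = True,
) -> CTMIResult:
    """Maximize estimated CMI over compatible lags and window sizes.

    ``search='exhaustive'`` scans the full grid ``|gamma| <= gamma_max``,
    ``1 <= lambda <= lambda_max``; ``search='greedy'`` hill-climbs the
    window sizes from (1, 1) at every lag, growing one window at a time
    while the estimate increases (cheaper; same optimum whenever the
    estimate is monotone along the climb path).
    """
    cfg = cfg or EstimatorConfig()
    if p == q:
        raise ValueError("p and q must be distinct series")
    if standardize:
        panel = prepare_panel(panel, cfg)

    candidates: list[tuple[float, int, int, int, JointSample]] = []

    if search == "exhaustive":
        for gamma in space.lag_range:
            for lpq in space.window_range:
                for lqp in space.window_range:
                    out = _estimate_at(panel, p, q, lpq, lqp, gamma, (), cfg)
                    if out is not None:
                        candidates.append((out[0], gamma, lpq, lqp, out[1]))
    elif search == "greedy":
        # hill-climb the window sizes from (1, 1) at every lag, growing
        # one window at a time while the estimate improves by more than
        # the estimator's resolution
        for gamma in space.lag_range:
            out = _estimate_at(panel, p, q, 1, 1, gamma, (), cfg)
            if out is None:
                continue
            cur_val, cur_sample = out
            lpq = lqp = 1
            candidates.append((cur_val, gamma, lpq, lqp, cur_sample))
            while True:
                moves = []
                if lpq < space.lambda_max:
                    moves.append((lpq + 1, lqp))
                if lqp < space.lambda_max:
                    moves.append((lpq, lqp + 1))
                best_move = None
                for nlpq, nlqp in moves:
                    out = _estimate_at(panel, p, q, nlpq, nlqp, gamma, (), cfg)
                    if out is not None and out[0] > cur_val + cfg.resolution:
                        if best_move is None or out[0] > best_move[0]:
                            best_move = (out[0], nlpq, nlqp, out[1])
                if best_move is None:
                    break
                cur_val, lpq, lqp, cur_sample = best_move
                candidates.append((cur_val, gamma, lpq, lqp, cur_sample))
    else:
        raise ValueError(f"unknown search strategy {search!r}")

    if not candidates:
        raise EstimationInfeasibleError(
            f"no usable joint sample for ({p},{q}) anywhere on the search grid"
        )
    # among candidates within one resolution of the maximum, apply the
    # deterministic tie-break: largest gamma, then smallest lambda_pq,
    # then smallest lambda_qp
    vmax = max(c[0] for c in candidates)
    candidates.sort(key=lambda c: (-c[1], c[2], c[3]))
    value, gamma, lpq, lqp, sample = next(
        c for c in candidates if c[0] >= vmax - cfg.resolution
    )
    return CTMIResult(
        p=p, q=q, value=value, gamma_bar=gamma,
        lambda_pq=lpq, lambda_qp=lqp, n=sample.n, sample=sample,
    )


def conditional_ctmi(
    panel: TimeSeriesPanel,
    p: str,
    q: str,
    R: Sequence[str],
    base: CTMIResult,
    space: SearchSpace,
    cfg: EstimatorConfig | None = None,
    standardize: bool = True,
    sweeps: int | None = None,
) -> CondCTMIResult:
    """Minimize estimated CMI over conditioning lags and windows.

    The pair's optimal (gamma_bar, lambda_pq, lambda_qp) is held fixed
    from ``base``.  Each conditioning series ``r`` contributes a window
    of size ``lambda_k`` starting ``Gamma_k`` ticks before the ``p``
    block, with ``Gamma_k >= -gamma_bar`` so that the conditioner never
    lies strictly in the future of both blocks.  With several
    conditioners the (Gamma, lambda) pairs are optimized by coordinate
    descent, the others held at (0, 1); a single conditioner needs one
    sweep (the scan is then exhaustive).
    """
    cfg = cfg or EstimatorConfig()
    R = list(R)
    if not R:
        raise ValueError("R must be nonempty; use ctmi for the marginal case")
    if p in R or q in R:
        raise ValueError("R must be disjoint from {p, q}")
    if standardize:
        panel = prepare_panel(panel, cfg)

    # Orient the pair so that the fixed lag is nonnegative, as the
    # conditional definition assumes.
    if base.gamma_bar < 0:
        p, q = q, p
        gamma = -base.gamma_bar
        lam_pq, lam_qp = base.lambda_qp, base.lambda_pq
    else:
        gamma = base.gamma_bar
        lam_pq, lam_qp = base.lambda_pq, base.lambda_qp

    K = len(R)
    cur = [(0, 1)] * K
    n_sweeps = sweeps if sweeps is not None else (1 if K == 1 else 2)
    best_val: float | None = None
    best_sample: JointSample | None = None

    for _ in range(n_sweeps):
        for idx in range(K):
            cands: list[tuple[float, int, int, JointSample]] = []
            for g_k in range(space.gamma_max, -gamma - 1, -1):
                for lam_k in space.window_range:
                    trial = list(cur)
                    trial[idx] = (g_k, lam_k)
                    cond = [
                        (R[j], trial[j][0], trial[j][1]) for j in range(K)
                    ]
                    out = _estimate_at(panel, p, q, lam_pq, lam_qp, gamma, cond, cfg)
                    if out is not None:
                        cands.append((out[0], g_k, lam_k, out[1]))
            if not cands:
                raise EstimationInfeasibleError(
                    f"no usable joint sample for ({p},{q} | {R})"
                )
            # within one resolution of the minimum, ties resolve to the
            # largest conditioning lag, then the smallest window
            vmin = min(c[0] for c in cands)
            cands.sort(key=lambda c: (-c[1], c[2]))
            chosen = next(c for c in cands if c[0] <= vmin + cfg.resolution)
            cur[idx] = (chosen[1], chosen[2])
            best_val = chosen[0]
            best_sample = chosen[3]

    assert best_val is not None and best_sample is not None
    return CondCTMIResult(
        p=p, q=q, cond=tuple(R), value=best_val,
        gamma_bar=gamma, lambda_pq=lam_pq, lambda_qp=lam_qp,
        cond_gammas=tuple(g for g, _ in cur),
        cond_lambdas=tuple(l for _, l in cur),
        n=best_sample.n, sample=best_sample,
    )


def independence_decision(
    panel: TimeSeriesPanel,
    p: str,
    q: str,
    R: Sequence[str] = (),
    space: SearchSpace | None = None,
    cfg: EstimatorConfig | None = None,
    search: str = "exhaustive",
    base: CTMIResult | None = None,
) -> DecisionResult:
    """Dependence decision for a pair given a (possibly empty) set.

    Runs the (conditional) CTMI optimization, then the local permutation
    test on the optimizing joint sample; the pair is declared dependent
    iff ``p <= alpha``.
    """
    cfg = cfg or EstimatorConfig()
    space = space or SearchSpace(gamma_max=5)
    prepared = prepare_panel(panel, cfg)
    if base is None:
        base = ctmi(prepared, p, q, space, cfg, search=search, standardize=False)
    if R:
        result: CTMIResult | CondCTMIResult = conditional_ctmi(
            prepared, p, q, R, base, space, cfg, standardize=False
        )
    else:
        result = base
    sample = result.sample
    assert sample is not None
    p_value, _ = local_permutation_test(
        sample.x_block, sample.y_block, sample.z_block(), cfg
    )
    return DecisionResult(dependent=p_value <= cfg.alpha, p_value=p_value, result=result)
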