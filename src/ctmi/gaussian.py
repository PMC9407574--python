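"""Closed-form Gaussian oracles for linear lagged models.

For jointly Gaussian variables the conditional mutual information has the
log-determinant form

    I(X; Y | Z) = 1/2 [ ln det S_xz + ln det S_yz - ln det S_z - ln det S ],

which this module evaluates exactly on the covariance implied by a linear
structural model with lagged effects and independent innovations.  These
oracles serve as an independent reference for the kNN estimator and for
the window/lag optimization: covariances are accumulated by expanding
every variable into its innovation coefficients from the zero initial
state, so unit-root (random-walk) components are handled exactly at any
finite time index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "gaussian_cmi",
    "LinearLaggedModel",
    "random_walk_cascade",
]


def gaussian_cmi(
    cov: np.ndarray,
    ix: Sequence[int],
    iy: Sequence[int],
    iz: Sequence[int] = (),
) -> float:
    """Conditional mutual information of a Gaussian vector, in nats."""
    cov = np.asarray(cov, dtype=float)
    ix, iy, iz = list(ix), list(iy), list(iz)

    def logdet(idx: list[int]) -> float:
        if not idx:
            return 0.0
        sign, ld = np.linalg.slogdet(cov[np.ix_(idx, idx)])
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance block not positive definite")
        return ld

    return 0.5 * (
        logdet(ix + iz) + logdet(iy + iz) - logdet(iz) - logdet(ix + iy + iz)
    )


@dataclass
class LinearLaggedModel:
    """Linear structural model X_t^q = sum a * X_{t-lag}^p + xi_t^q.

    ``edges`` maps ``(cause, effect, lag)`` to a coefficient; self-effects
    are ordinary entries with ``cause == effect`` and ``lag >= 1``.  All
    series start at 0 and innovations are independent with the given
    variances (default 1).
    """

    names: Sequence[str]
    edges: dict[tuple[str, str, int], float]
    noise_var: dict[str, float] = field(default_factory=dict)

    def _coefficients(self, t_max: int) -> np.ndarray:
        """coef[s, t, s', t'] of innovation xi_{t'}^{s'} in X_t^s."""
        d = len(self.names)
        pos = {n: i for i, n in enumerate(self.names)}
        coef = np.zeros((d, t_max + 1, d, t_max + 1))
        for t in range(1, t_max + 1):
            for s in self.names:
                i = pos[s]
                coef[i, t, i, t] = 1.0  # own innovation
                for (c, e, lag), a in self.edges.items():
                    if e == s and t - lag >= 0:
                        coef[i, t] += a * coef[pos[c], t - lag]
        return coef

    def covariance(self, variables: Sequence[tuple[str, int]]) -> np.ndarray:
        """Exact covariance matrix of the listed (series, time) variables."""
        t_max = max(t for _, t in variables)
        if any(t < 0 for _, t in variables):
            raise ValueError("time indices must be nonnegative")
        coef = self._coefficients(t_max)
        pos = {n: i for i, n in enumerate(self.names)}
        var = np.array([self.noise_var.get(n, 1.0) for n in self.names])
        rows = np.stack(
            [coef[pos[s], t].reshape(-1) for s, t in variables]
        )
        weights = np.repeat(var, t_max + 1)
        return (rows * weights) @ rows.T

    def window_cmi(
        self,
        p: str,
        q: str,
        lam_pq: int,
        lam_qp: int,
        gamma: int,
        t: int = 30,
        cond: Sequence[tuple[str, int, int]] = (),
    ) -> float:
        """Closed-form CMI between window blocks conditioned on the pasts.

        Mirrors the joint-sample construction: the ``p`` window starts at
        time ``t``, the ``q`` window at ``t + gamma``, the pasts one step
        behind each block, and each conditioning entry ``(r, Gamma, lam)``
        starts at ``t - Gamma``.  ``t`` must be large enough for the
        covariance to be meaningful for the model at hand.
        """
        xs = [(p, t + j) for j in range(lam_pq)]
        ys = [(q, t + gamma + j) for j in range(lam_qp)]
        zs = [(p, t - 1), (q, t + gamma - 1)]
        for r, g_k, lam_k in cond:
            zs.extend((r, t - g_k + j) for j in range(lam_k))
        variables = xs + ys + zs
        cov = self.covariance(variables)
        nx, ny = len(xs), len(ys)
        return gaussian_cmi(
            cov,
            ix=list(range(nx)),
            iy=list(range(nx, nx + ny)),
            iz=list(range(nx + ny, len(variables))),
        )


    def simulate(self, T: int, seed: int = 0, discard: int = 3):
        """Draw one trajectory of length T from the zero initial state.

        Returns a :class:`~ctmi.timeseries.TimeSeriesPanel`; the first
        ``discard`` steps (holding the zero state) are dropped.
        """
        from .timeseries import TimeSeriesPanel

        rng = np.random.default_rng(seed)
        pos = {n: i for i, n in enumerate(self.names)}
        total = T + discard
        x = np.zeros((total + 1, len(self.names)))
        sd = {n: np.sqrt(self.noise_var.get(n, 1.0)) for n in self.names}
        noise = rng.normal(size=(total + 1, len(self.names)))
        for t in range(1, total + 1):
            for s in self.names:
                i = pos[s]
                v = sd[s] * noise[t, i]
                for (c, e, lag), a in self.edges.items():
                    if e == s and t - lag >= 0:
                        v += a * x[t - lag, pos[c]]
                x[t, i] = v
        return TimeSeriesPanel({n: x[1 + discard:, pos[n]] for n in self.names})


def random_walk_cascade() -> LinearLaggedModel:
    """Two-series worked model: a random walk driving a second series.

    ``X^1`` is a pure random walk; ``X^2`` accumulates its own past plus
    the first series at lags 1 and 2, all with unit coefficients and unit
    innovation variance.  The only lag-0 dependence between the two
    series is through shared history, so conditioning on both one-step
    pasts makes the instantaneous pair exactly independent.
    """
    return LinearLaggedModel(
        names=("X1", "X2"),
        edges={
            ("X1", "X1", 1): 1.0,
            ("X2", "X2", 1): 1.0,
            ("X1", "X2", 1): 1.0,
            ("X1", "X2", 2): 1.0,
        },
    )
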