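"""k-nearest-neighbor conditional mutual information and permutation test.

The estimator follows the digamma (Kraskov/Frenzel–Pompe) construction
under the supremum distance: with ``eps_i`` the distance from joint point
``i`` to its k-th neighbor in the full ``(x, y, z)`` space, and counts of
points strictly inside ``eps_i`` in the ``(x, z)``, ``(y, z)`` and ``(z)``
subspaces,

    I_hat = psi(k) + mean_i[ psi(n_z_i) - psi(n_xz_i) - psi(n_yz_i) ].

Counts here include the query point itself, which is the usual way of
writing the Frenzel–Pompe ``psi(n + 1)`` correction.  With an empty
conditioning block the marginal-space counts replace the ``z`` term and
``psi(n)`` replaces ``psi(n_z_i)``, i.e. the plain Kraskov MI estimator.

Significance is assessed by a local permutation scheme: rows of ``x`` are
shuffled only among rows whose conditioning values are close (nearest
neighbors in ``z`` under the sup-distance), drawing without replacement as
far as possible, so that the permuted data preserve the dependence of
``x`` on ``z`` while breaking any residual dependence on ``y``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree
from scipy.special import digamma

from .errors import SampleSizeError

logger = logging.getLogger(__name__)

__all__ = [
    "EstimatorConfig",
    "CMIEstimate",
    "sup_distance",
    "knn_cmi",
    "local_permutation_test",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Estimation and testing parameters.

    Parameters
    ----------
    k
        Neighbor count of the digamma estimator.
    permutations
        Number of permutations B of the significance test; p-values are
        quantized in multiples of 1/B.
    alpha
        Significance level of the independence decision.
    seed
        Seed for every source of randomness (permutations, tie-break
        noise).
    perm_neighborhood
        Size of the local-permutation neighborhood in the conditioning
        space.
    noise_amp
        Amplitude of the uniform jitter added once per series to break
        distance ties (standard kNN-estimator practice).
    resolution
        Statistical resolution of the estimator in nats: two estimates
        closer than this are treated as equal by the deterministic
        lag/window tie-break rules of the dependence search (the
        across-sample standard deviation of the estimator is about
        0.005-0.015 nats at n = 1000, k = 10).
    """

    k: int = 10
    permutations: int = 100
    alpha: float = 0.05
    seed: int = 0
    perm_neighborhood: int = 5
    noise_amp: float = 1e-10
    resolution: float = 0.01

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.perm_neighborhood < 1:
            raise ValueError("perm_neighborhood must be >= 1")
        if self.resolution < 0:
            raise ValueError("resolution must be nonnegative")


@dataclass(frozen=True)
class CMIEstimate:
    """A conditional mutual information estimate in nats.

    The value may be slightly negative by estimation error; callers that
    need a rate floor it at zero for reporting.
    """

    value: float
    n: int
    k: int


def sup_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Supremum (Chebyshev) distance between two concatenated windows."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


@njit(cache=True)
def _ksg_counts(x, y, z, k):  # pragma: no cover - exercised via knn_cmi
    """Neighbor counts of the digamma CMI estimator (sup-distance).

    Returns, for each point, the counts (including the point itself) of
    points strictly inside the k-th-neighbor radius in the (x,z), (y,z)
    and (z) subspaces.  ``z`` may have zero columns, in which case the
    third count is the full sample size.
    """
    n = x.shape[0]
    dx = x.shape[1]
    dy = y.shape[1]
    dz = z.shape[1]
    n_xz = np.empty(n, dtype=np.int64)
    n_yz = np.empty(n, dtype=np.int64)
    n_z = np.empty(n, dtype=np.int64)
    d_xz = np.empty(n, dtype=np.float64)
    d_yz = np.empty(n, dtype=np.float64)
    d_z = np.empty(n, dtype=np.float64)
    d_joint = np.empty(n, dtype=np.float64)
    for i in range(n):
        for j in range(n):
            mz = 0.0
            for c in range(dz):
                t = abs(z[i, c] - z[j, c])
                if t > mz:
                    mz = t
            mx = mz
            for c in range(dx):
                t = abs(x[i, c] - x[j, c])
                if t > mx:
                    mx = t
            my = mz
            for c in range(dy):
                t = abs(y[i, c] - y[j, c])
                if t > my:
                    my = t
            d_z[j] = mz
            d_xz[j] = mx
            d_yz[j] = my
            d_joint[j] = mx if mx > my else my
        # self distance is 0, so the k-th neighbor is entry k of the
        # sorted joint distances
        eps = np.partition(d_joint.copy(), k)[k]
        cxz = 0
        cyz = 0
        cz = 0
        for j in range(n):
            if d_xz[j] < eps:
                cxz += 1
            if d_yz[j] < eps:
                cyz += 1
            if d_z[j] < eps:
                cz += 1
        n_xz[i] = cxz
        n_yz[i] = cyz
        n_z[i] = cz if dz > 0 else n
    return n_xz, n_yz, n_z


def _as_block(a: np.ndarray | None, n: int) -> np.ndarray:
    if a is None:
        return np.empty((n, 0), dtype=float)
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return np.ascontiguousarray(a)


def knn_cmi(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    cfg: EstimatorConfig | None = None,
) -> CMIEstimate:
    """Estimate I(x; y | z) in nats with the digamma kNN estimator.

    ``x``, ``y`` and ``z`` are row-aligned blocks; ``z`` may be ``None``
    or have zero columns, giving the unconditional Kraskov estimator.
    The formula is exactly symmetric in ``x`` and ``y``.
    """
    cfg = cfg or EstimatorConfig()
    x = _as_block(x, 0)
    y = _as_block(y, x.shape[0])
    n = x.shape[0]
    z = _as_block(z, n)
    if y.shape[0] != n or z.shape[0] != n:
        raise ValueError("x, y, z must be row-aligned")
    if n <= cfg.k:
        raise SampleSizeError(f"need n > k, got n={n}, k={cfg.k}")
    n_xz, n_yz, n_z = _ksg_counts(x, y, z, cfg.k)
    # counts can be zero only in the degenerate all-duplicates case
    # (eps = 0); clamp before the digamma
    if (n_xz < 1).any() or (n_yz < 1).any() or (n_z < 1).any():
        logger.warning("zero neighbor counts clamped to 1 (duplicate points)")
        n_xz = np.maximum(n_xz, 1)
        n_yz = np.maximum(n_yz, 1)
        n_z = np.maximum(n_z, 1)
    value = digamma(cfg.k) + float(
        np.mean(digamma(n_z) - digamma(n_xz) - digamma(n_yz))
    )
    return CMIEstimate(value=value, n=n, k=cfg.k)


def _local_permutations(
    z: np.ndarray,
    n_perm: int,
    neighborhood: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Row permutations restricted to neighborhoods of similar z values.

    Follows the usual local scheme: each row is reassigned the index of
    one of its ``neighborhood`` nearest rows in z (sup-distance), drawing
    without replacement as far as possible.
    """
    n = z.shape[0]
    if z.shape[1] == 0:
        return np.stack([rng.permutation(n) for _ in range(n_perm)])
    m = min(neighborhood, n)
    tree = cKDTree(z)
    _, nbrs = tree.query(z, k=m, p=np.inf)
    nbrs = np.atleast_2d(nbrs)
    if nbrs.shape[0] != n:
        nbrs = nbrs.reshape(n, -1)
    perms = np.empty((n_perm, n), dtype=np.int64)
    for b in range(n_perm):
        used = np.zeros(n, dtype=bool)
        perm = np.empty(n, dtype=np.int64)
        order = rng.permutation(n)
        for i in order:
            cand = rng.permutation(nbrs[i])
            chosen = -1
            for j in cand:
                if not used[j]:
                    chosen = j
                    break
            if chosen < 0:
                # every neighbor already used: fall back to a random
                # neighbor (draw with replacement)
                chosen = cand[0]
            used[chosen] = True
            perm[i] = chosen
        perms[b] = perm
    return perms


def local_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    cfg: EstimatorConfig | None = None,
) -> tuple[float, CMIEstimate]:
    """Permutation p-value for the null hypothesis I(x; y | z) = 0.

    ``p = (1/B) * sum_b 1[I_hat(x_b; y | z) >= I_hat(x; y | z)]`` where
    ``x_b`` permutes rows of ``x`` within local neighborhoods of ``z``
    (unrestricted when ``z`` is empty).  Returns the p-value and the
    observed estimate.
    """
    cfg = cfg or EstimatorConfig()
    x = _as_block(x, 0)
    n = x.shape[0]
    y = _as_block(y, n)
    z = _as_block(z, n)
    observed = knn_cmi(x, y, z, cfg)
    rng = np.random.default_rng(cfg.seed)
    perms = _local_permutations(z, cfg.permutations, cfg.perm_neighborhood, rng)
    count = 0
    for b in range(cfg.permutations):
        est_b = knn_cmi(x[perms[b]], y, z, cfg)
        if est_b.value >= observed.value:
            count += 1
    return count / cfg.permutations, observed
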