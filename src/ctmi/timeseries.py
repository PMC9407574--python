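"""Window-based representations of multivariate time series.

A summary-graph view of a multivariate series treats each component series
as a single node.  Dependence between two series is then measured between
*windows* — short vectors of consecutive observations — taken at a constant
temporal offset (the lag).  This module holds the panel container, the
search space of admissible lags and window sizes, and the machinery that
aligns two (or more) series into a joint sample of window rows, for equal
or different sampling rates.

Conventions
-----------
* Array indices are 0-based internally.
* Lags are expressed in sub-unit *ticks*.  One time unit is divided into
  ``lcm(rates)`` ticks so that every series' observations fall on the tick
  grid.  With equal rates one tick equals one observation step.
* A lag ``gamma`` between series ``p`` and ``q`` means that the window of
  ``q`` starts ``gamma`` ticks after the window of ``p`` (positive lag:
  ``p`` leads ``q``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySampleError, InvalidWindowError

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesPanel",
    "SearchSpace",
    "JointSample",
    "window_embedding",
    "align_joint_sample",
    "read_panel",
]


class TimeSeriesPanel:
    """Named real-valued series with per-series sampling rates.

    Parameters
    ----------
    data
        Mapping from series name to a 1-d sequence of observations.
        NaN entries are tolerated; rows touching them are dropped during
        alignment.
    rates
        Observations per common time unit for each series (default 1 for
        all).  Must be positive integers.
    starts
        Per-series start offset in sub-unit ticks (default 0).
    """

    def __init__(
        self,
        data: Mapping[str, Sequence[float]],
        rates: Mapping[str, int] | None = None,
        starts: Mapping[str, int] | None = None,
    ) -> None:
        self.names: list[str] = list(data)
        self._values: dict[str, np.ndarray] = {}
        for name in self.names:
            arr = np.asarray(data[name], dtype=float).ravel()
            if arr.size < 2:
                raise ValueError(f"series {name!r} must have length >= 2")
            if np.isinf(arr).any():
                raise ValueError(f"series {name!r} contains non-finite values")
            self._values[name] = arr
        self.rates: dict[str, int] = {n: 1 for n in self.names}
        if rates:
            for n, r in rates.items():
                if n not in self._values:
                    raise KeyError(f"unknown series {n!r} in rates")
                if int(r) != r or r <= 0:
                    raise ValueError("rates must be positive integers")
                self.rates[n] = int(r)
        self.starts: dict[str, int] = {n: 0 for n in self.names}
        if starts:
            for n, s in starts.items():
                if n not in self._values:
                    raise KeyError(f"unknown series {n!r} in starts")
                self.starts[n] = int(s)

    # -- basic access -----------------------------------------------------
    def series(self, name: str) -> np.ndarray:
        return self._values[name]

    def n_obs(self, name: str) -> int:
        return self._values[name].size

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __len__(self) -> int:
        return len(self.names)

    @property
    def equal_rates(self) -> bool:
        rates = set(self.rates.values())
        starts = set(self.starts.values())
        return len(rates) == 1 and len(starts) == 1

    def min_length(self) -> int:
        return min(v.size for v in self._values.values())

    def tick_unit(self, names: Iterable[str] | None = None) -> int:
        """Number of ticks per time unit for the given subset of series."""
        names = list(names) if names is not None else self.names
        return math.lcm(*(self.rates[n] for n in names))

    def spacing(self, name: str, names: Iterable[str] | None = None) -> int:
        """Tick spacing between consecutive observations of ``name``."""
        return self.tick_unit(names) // self.rates[name]

    def transform(self, func) -> "TimeSeriesPanel":
        """Return a copy with ``func`` applied to every series array."""
        return TimeSeriesPanel(
            {n: func(self._values[n]) for n in self.names},
            rates=dict(self.rates),
            starts=dict(self.starts),
        )

    def to_frame(self) -> pd.DataFrame:
        """Equal-length panel as a DataFrame (ragged panels are NaN-padded)."""
        length = max(v.size for v in self._values.values())
        cols = {}
        for n in self.names:
            v = self._values[n]
            cols[n] = np.concatenate([v, np.full(length - v.size, np.nan)])
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SearchSpace:
    """Admissible lags and window sizes for the dependence search.

    ``lambda_max`` defaults to ``gamma_max + 1``; setting ``extended=True``
    uses ``2 * gamma_max + 1`` instead, which guarantees that a window of
    maximal size centered on any instant covers every admissible lagged
    sub-window (useful when the identifiability argument, rather than the
    default search practice, is the priority).
    """

    gamma_max: int
    lambda_max: int | None = None
    extended: bool = False

    def __post_init__(self) -> None:
        if self.gamma_max < 0:
            raise ValueError("gamma_max must be nonnegative")
        if self.lambda_max is None:
            lam = 2 * self.gamma_max + 1 if self.extended else self.gamma_max + 1
            object.__setattr__(self, "lambda_max", lam)
        if self.lambda_max < 1:
            raise ValueError("lambda_max must be positive")

    @property
    def lag_range(self) -> range:
        """Lags ordered by the tie-break priority (largest first)."""
        return range(self.gamma_max, -self.gamma_max - 1, -1)

    @property
    def window_range(self) -> range:
        """Window sizes ordered by the tie-break priority (smallest first)."""
        return range(1, self.lambda_max + 1)

    def validate_for(self, panel: TimeSeriesPanel) -> None:
        if self.lambda_max >= panel.min_length():
            raise InvalidWindowError(
                f"lambda_max={self.lambda_max} must be smaller than the "
                f"shortest series (length {panel.min_length()})"
            )


@dataclass
class JointSample:
    """Row-aligned window blocks of two series plus past/conditioning blocks.

    Every block has the same number of rows ``n``; row ``i`` of ``y_block``
    starts exactly ``gamma`` ticks after row ``i`` of ``x_block``.  The
    past columns are single-observation windows ending strictly before the
    corresponding block (the first-order Markov past of each series).
    """

    x_block: np.ndarray
    y_block: np.ndarray
    x_past: np.ndarray
    y_past: np.ndarray
    cond_blocks: list[np.ndarray] = field(default_factory=list)
    gamma: int = 0
    lambdas: tuple[int, int] = (1, 1)
    cond_specs: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.x_block.shape[0]

    def z_block(self) -> np.ndarray:
        """Conditioning matrix: the two past columns plus any extra blocks."""
        return np.hstack([self.x_past, self.y_past, *self.cond_blocks])


def window_embedding(
    series: np.ndarray,
    lam: int,
    offsets: Sequence[int] | None = None,
) -> np.ndarray:
    """Embed a series into overlapping windows of length ``lam``.

    Row ``i`` is ``(series[o_i], ..., series[o_i + lam - 1])`` for offset
    ``o_i``.  With ``offsets=None`` all ``N - lam + 1`` windows are returned.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    if lam < 1 or lam > n:
        raise InvalidWindowError(f"window size {lam} invalid for series of length {n}")
    view = np.lib.stride_tricks.sliding_window_view(series, lam)
    if offsets is None:
        return view.copy()
    offsets = np.asarray(offsets, dtype=int)
    if offsets.size and (offsets.min() < 0 or offsets.max() > n - lam):
        raise IndexError("window offsets out of range")
    return view[offsets].copy()


def _candidate_ticks(
    panel: TimeSeriesPanel,
    names: list[str],
    p: str,
    lam_pq: int,
) -> tuple[np.ndarray, int]:
    """All window start ticks for ``p`` that leave room for one past step."""
    u_p = panel.spacing(p, names)
    n_p = panel.n_obs(p)
    # observation index i_p must allow a past observation (i_p >= 1) and a
    # full window (i_p + lam_pq - 1 <= n_p - 1)
    idx = np.arange(1, n_p - lam_pq + 1, dtype=int)
    ticks = panel.starts[p] + idx * u_p
    return ticks, u_p


def align_joint_sample(
    panel: TimeSeriesPanel,
    p: str,
    q: str,
    lam_pq: int,
    lam_qp: int,
    gamma_pq: int,
    cond: Sequence[tuple[str, int, int]] = (),
) -> JointSample:
    """Build the maximal joint sample of paired windows at a constant lag.

    Window starts of ``q`` lead those of ``p`` by exactly ``gamma_pq``
    ticks.  Each conditioning entry ``(r, Gamma, lam)`` attaches a window
    of ``r`` of size ``lam`` starting ``Gamma`` ticks *before* the start of
    the ``p`` block.  Rows with any unavailable index (or NaN observation)
    are dropped.
    """
    if p == q:
        raise ValueError("p and q must be distinct series")
    for name in (p, q, *(c[0] for c in cond)):
        if name not in panel:
            raise KeyError(f"unknown series {name!r}")
    involved = [p, q, *(c[0] for c in cond)]
    for name, lam in ((p, lam_pq), (q, lam_qp), *((c[0], c[2]) for c in cond)):
        if lam < 1 or lam > panel.n_obs(name):
            raise InvalidWindowError(
                f"window size {lam} invalid for series {name!r} "
                f"(length {panel.n_obs(name)})"
            )

    ticks_p, _ = _candidate_ticks(panel, involved, p, lam_pq)

    def _indices_at(name: str, tick_start: np.ndarray, lam: int) -> tuple[np.ndarray, np.ndarray]:
        """Observation index of ``name`` starting at each tick, validity mask."""
        u = panel.spacing(name, involved)
        rel = tick_start - panel.starts[name]
        ok = (rel % u == 0)
        idx = np.where(ok, rel // u, -1)
        # past observation must exist (idx >= 1) and window must fit
        ok &= (idx >= 1) & (idx + lam - 1 <= panel.n_obs(name) - 1)
        return idx, ok

    idx_q, ok_q = _indices_at(q, ticks_p + gamma_pq, lam_qp)
    mask = ok_q
    cond_idx = []
    for r, g_k, lam_k in cond:
        idx_r, ok_r = _indices_at(r, ticks_p - g_k, lam_k)
        cond_idx.append(idx_r)
        mask = mask & ok_r
    if not mask.any():
        raise EmptySampleError(
            f"no joint observation for ({p},{q}) at gamma={gamma_pq}, "
            f"windows=({lam_pq},{lam_qp})"
        )

    u_p = panel.spacing(p, involved)
    idx_p = (ticks_p - panel.starts[p]) // u_p
    idx_p = idx_p[mask]
    idx_q = idx_q[mask]
    cond_idx = [ci[mask] for ci in cond_idx]

    x_block = window_embedding(panel.series(p), lam_pq, idx_p)
    y_block = window_embedding(panel.series(q), lam_qp, idx_q)
    x_past = window_embedding(panel.series(p), 1, idx_p - 1)
    y_past = window_embedding(panel.series(q), 1, idx_q - 1)
    cond_blocks = [
        window_embedding(panel.series(r), lam_k, ci)
        for (r, _, lam_k), ci in zip(cond, cond_idx)
    ]

    blocks = [x_block, y_block, x_past, y_past, *cond_blocks]
    finite = np.ones(x_block.shape[0], dtype=bool)
    for b in blocks:
        finite &= np.isfinite(b).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("dropped %d joint rows containing NaN values", dropped)
        blocks = [b[finite] for b in blocks]
    if blocks[0].shape[0] == 0:
        raise EmptySampleError("all joint rows contain missing values")

    x_block, y_block, x_past, y_past, *cond_blocks = blocks
    return JointSample(
        x_block=x_block,
        y_block=y_block,
        x_past=x_past,
        y_past=y_past,
        cond_blocks=list(cond_blocks),
        gamma=gamma_pq,
        lambdas=(lam_pq, lam_qp),
        cond_specs=list(cond),
    )


def read_panel(
    path,
    sep: str | None = None,
    time_col: str | None = None,
    rates: Mapping[str, int] | None = None,
) -> TimeSeriesPanel:
    """Read a panel from a CSV/TSV file (header row = series names).

    Trailing empty cells are allowed for series with fewer observations
    than the longest column (their sampling rates are supplied through
    ``rates``).  An optional leading time column is dropped.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if time_col is not None:
        df = df.drop(columns=[time_col])
    data = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        # strip trailing NaN padding from ragged columns
        valid = np.flatnonzero(np.isfinite(v))
        if valid.size == 0:
            raise ValueError(f"column {col!r} has no finite values")
        data[col] = v[: valid[-1] + 1]
    return TimeSeriesPanel(data, rates=rates)
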