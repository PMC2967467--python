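"""Synchronization likelihood (SL) between pairs of time-series.

SL quantifies generalized (linear and nonlinear) coupling between two
series as the average probability that a pattern recurrence in one
series coincides in time with a pattern recurrence in the other.
Patterns are time-delay embedding vectors; "recurrence" at time i means
another embedded vector lies within a per-time-point critical distance
chosen so that a fixed small fraction ``pref`` of candidates qualify.
SL is ``pref`` in expectation for independent series and exactly 1 for
identical ones.

The per-time-point critical distance is defined by a rank statistic
(the r-th nearest candidate, r = ceil(pref * n_candidates)), which makes
the measure deterministic, tie-tolerant and invariant under per-series
affine rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SlParams",
    "SyncMatrix",
    "DegenerateSeriesError",
    "embed",
    "critical_distance",
    "sl_pair",
    "sl_matrix",
    "global_sync_mean",
]


class DegenerateSeriesError(ValueError):
    """A series is constant (all inter-pattern distances vanish)."""


@dataclass(frozen=True)
class SlParams:
    """Embedding and recurrence parameters for the SL computation.

    Parameters
    ----------
    lag : int
        Embedding time lag in samples (>= 1).
    dim : int
        Embedding dimension (>= 2).
    theiler : int
        Theiler window ``w``: candidate recurrences must satisfy
        ``|i - j| > w`` to suppress autocorrelation artifacts.
    pref : float
        Reference probability in (0, 1): the fraction of candidates
        counted as recurrences at every time point.
    """

    lag: int = 1
    dim: int = 6
    theiler: int = 6
    pref: float = 0.01

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if self.dim < 2:
            raise ValueError(f"dim must be >= 2, got {self.dim}")
        if self.theiler < 0:
            raise ValueError(f"theiler must be >= 0, got {self.theiler}")
        if not 0.0 < self.pref < 1.0:
            raise ValueError(f"pref must lie in (0, 1), got {self.pref}")

    @property
    def min_length(self) -> int:
        """Shortest series length accepted by :func:`embed`."""
        return (self.dim - 1) * self.lag + 2 * (self.theiler + 1)


@dataclass(frozen=True)
class SyncMatrix:
    """Symmetric matrix of pairwise SL values for one subject.

    The diagonal is fixed at 1 by convention (self-synchronization) and
    excluded from every downstream statistic and from graph building.
    """

    values: np.ndarray
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("SyncMatrix values must be square")
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region_labels length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("SyncMatrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal SL values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def embed(series: np.ndarray, params: SlParams) -> np.ndarray:
    """Time-delay embedding of a scalar series.

    Returns the ``M x dim`` matrix of state vectors with
    ``M = len(series) - (dim - 1) * lag``; row ``i`` is
    ``(x_i, x_{i+lag}, ..., x_{i+(dim-1)*lag})``.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < params.min_length:
        raise ValueError(
            f"series of length {n} is too short for embedding: need at least "
            f"{params.min_length} samples with dim={params.dim}, lag={params.lag}, "
            f"theiler={params.theiler}"
        )
    m = n - (params.dim - 1) * params.lag
    idx = np.arange(m)[:, None] + params.lag * np.arange(params.dim)[None, :]
    return x[idx]


def _candidate_mask(n_vectors: int, theiler: int) -> np.ndarray:
    """Boolean mask of valid recurrence candidates: |i - j| > w."""
    i = np.arange(n_vectors)
    return np.abs(i[:, None] - i[None, :]) > theiler


def _critical_distances(dist: np.ndarray, mask: np.ndarray, pref: float) -> np.ndarray:
    """Per-row critical distance: the r-th smallest candidate distance,
    r = ceil(pref * n_candidates)."""
    n = dist.shape[0]
    masked = np.where(mask, dist, np.inf)
    order = np.sort(masked, axis=1)
    n_cand = mask.sum(axis=1)
    if np.any(n_cand < 1):
        raise ValueError("Theiler window leaves no recurrence candidates")
    ranks = np.ceil(pref * n_cand).astype(int)
    ranks = np.maximum(ranks, 1)
    eps = order[np.arange(n), ranks - 1]
    return eps


def critical_distance(embedded: np.ndarray, i: int, params: SlParams) -> float:
    """Critical distance at time point ``i``.

    The Euclidean distance of the r-th nearest candidate vector to
    vector ``i`` (candidates: ``|i - j| > theiler``), with
    ``r = ceil(pref * n_candidates)``, so the realized fraction of
    candidates within the returned distance is as close to ``pref``
    from above as the rank statistic allows.
    """
    emb = np.asarray(embedded, dtype=float)
    n = emb.shape[0]
    if not 0 <= i < n:
        raise IndexError(f"index {i} out of range for {n} vectors")
    d = np.linalg.norm(emb - emb[i], axis=1)
    cand = d[np.abs(np.arange(n) - i) > params.theiler]
    if cand.size == 0:
        raise ValueError("Theiler window leaves no recurrence candidates")
    if np.max(cand) == 0.0:
        raise DegenerateSeriesError(
            "all candidate distances are zero (constant series)"
        )
    r = max(1, math.ceil(params.pref * cand.size))
    return float(np.partition(cand, r - 1)[r - 1])


def _recurrence_matrix(series: np.ndarray, params: SlParams) -> np.ndarray:
    """Boolean M x M matrix: entry (i, j) true when j is a candidate
    (|i-j| > w) and a recurrence of i (distance <= eps_i; ties count)."""
    emb = embed(series, params)
    dist = squareform(pdist(emb))
    mask = _candidate_mask(emb.shape[0], params.theiler)
    masked_max = np.where(mask, dist, -np.inf).max()
    if masked_max == 0.0:
        raise DegenerateSeriesError(
            "all candidate distances are zero (constant series)"
        )
    eps = _critical_distances(dist, mask, params.pref)
    return (dist <= eps[:, None]) & mask


def _sl_from_recurrences(rec_x: np.ndarray, rec_y: np.ndarray) -> float:
    """Symmetrized SL from two recurrence matrices on a shared time grid."""
    hits = (rec_x & rec_y).sum(axis=1)
    base_x = rec_x.sum(axis=1)
    base_y = rec_y.sum(axis=1)
    s_xy = np.mean(hits / base_x)
    s_yx = np.mean(hits / base_y)
    return float(np.clip(0.5 * (s_xy + s_yx), 0.0, 1.0))


def sl_pair(x: np.ndarray, y: np.ndarray, params: SlParams | None = None) -> float:
    """Synchronization likelihood between two equal-length series.

    For each time point i the candidates ``|i - j| > theiler`` that are
    simultaneous recurrences in X and Y are counted and normalized by
    the X-recurrence count; the average over i gives the X->Y direction,
    and the result is the mean of the two directions, clipped to [0, 1].
    """
    if params is None:
        params = SlParams()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    rec_x = _recurrence_matrix(x, params)
    rec_y = _recurrence_matrix(y, params)
    return _sl_from_recurrences(rec_x, rec_y)


def sl_matrix(subject, params: SlParams | None = None) -> SyncMatrix:
    """All-pairs SL matrix for one subject's regional time-series.

    ``subject`` is a :class:`slnet.synthetic.RegionalTimeSeries` or any
    object with ``values`` (R x Tn array) and an optional
    ``region_labels`` attribute.

    Recurrence structure is computed once per region, and the pairwise
    coincidence counts for all R(R-1)/2 pairs are accumulated row-by-row
    with matrix products, which is algebraically identical to calling
    :func:`sl_pair` per pair.
    """
    if params is None:
        params = SlParams()
    values = np.asarray(subject.values, dtype=float)
    labels = tuple(getattr(subject, "region_labels", None) or
                   [f"region_{k:03d}" for k in range(values.shape[0])])
    n_regions = values.shape[0]
    recs = []
    for k in range(n_regions):
        try:
            recs.append(_recurrence_matrix(values[k], params))
        except DegenerateSeriesError as exc:
            raise DegenerateSeriesError(
                f"region '{labels[k]}' is degenerate: {exc}"
            ) from exc
    rec = np.asarray(recs)                     # R x M x M bool
    base = rec.sum(axis=2).astype(float)       # R x M
    sl = np.ones((n_regions, n_regions))
    for a in range(n_regions):
        ha = (rec[a][None, :, :] & rec).sum(axis=2)      # R x M coincidences
        s_ab = (ha / base[a][None, :]).mean(axis=1)      # direction a -> b
        s_ba = (ha / base).mean(axis=1)                  # direction b -> a
        sl[a, :] = np.clip(0.5 * (s_ab + s_ba), 0.0, 1.0)
    sl = 0.5 * (sl + sl.T)                     # symmetric to machine precision
    np.fill_diagonal(sl, 1.0)
    return SyncMatrix(values=sl, region_labels=labels)


def global_sync_mean(matrix: SyncMatrix) -> float:
    """Whole-brain mean synchronization S: mean of strictly off-diagonal
    entries of the SL matrix."""
    v = matrix.values
    off = ~np.eye(v.shape[0], dtype=bool)
    return float(v[off].mean())
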