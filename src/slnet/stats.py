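"""Group comparison statistics: per-level t-tests, a cluster-based
permutation test over adjacent threshold/degree levels, and regional
synchronization difference maps.

The cluster-based permutation test controls the family-wise error over
the T or K levels: per-level two-sample t statistics are thresholded at
the 2.5th/97.5th quantiles of the Student-t sampling distribution,
supra-threshold values at adjacent levels are joined into clusters,
cluster sums form the cluster-level statistics, and the maximum
absolute cluster sum is referred to its permutation distribution under
random repartitions of the subjects that preserve group sizes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "LevelStats",
    "Cluster",
    "ClusterResult",
    "RegionalDiffMap",
    "level_tstats",
    "cluster_permutation_test",
    "regional_difference_map",
    "block_summary",
]


@dataclass(frozen=True)
class LevelStats:
    """Per-level two-sample t statistics (group1 minus group2)."""

    levels: tuple
    t_values: np.ndarray
    df: int


@dataclass(frozen=True)
class Cluster:
    """A maximal run of adjacent supra-threshold levels of one sign."""

    start: int          # index of first level in the run
    stop: int           # index of last level (inclusive)
    levels: tuple       # the level values spanned
    stat: float         # summed t values within the cluster
    sign: int           # +1 or -1


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple
    max_stat: float
    p_value: float
    n_permutations: int
    method: str
    threshold: tuple


@dataclass(frozen=True)
class RegionalDiffMap:
    """Signed significance map of pairwise SL differences.

    ``signs[i, j]`` is +1 where group1's mean SL exceeds group2's at
    p < alpha (two-tailed, uncorrected), -1 for the reverse, else 0.
    """

    signs: np.ndarray
    p_values: np.ndarray
    t_values: np.ndarray
    alpha: float
    region_labels: tuple


def _tstat_matrix(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (group1 - group2) along axis 0,
    vectorized over remaining axes; zero pooled variance yields t = 0."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss1 = ((x1 - m1) ** 2).sum(axis=0)
    ss2 = ((x2 - m2) ** 2).sum(axis=0)
    pooled = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / np.where(se > 0, se, 1.0), 0.0)
    return t


def level_tstats(group1: np.ndarray, group2: np.ndarray,
                 levels=None, welch: bool = False) -> LevelStats:
    """Two-sample t statistics per level.

    Parameters
    ----------
    group1, group2 : arrays of shape (n_subjects, n_levels)
        Per-subject metric values on a shared level grid.
    levels : optional sequence of level values (T or K).
    welch : use Welch's t instead of the pooled-variance Student t.

    The orientation is group1 minus group2.
    """
    x1 = np.atleast_2d(np.asarray(group1, dtype=float))
    x2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("groups must share the same level grid")
    if levels is None:
        levels = tuple(range(x1.shape[1]))
    if len(levels) != x1.shape[1]:
        raise ValueError("levels length must match the value columns")
    if welch:
        t = sps.ttest_ind(x1, x2, axis=0, equal_var=False).statistic
        t = np.nan_to_num(t, nan=0.0)
    else:
        t = _tstat_matrix(x1, x2)
        if np.any((x1.std(axis=0) == 0) & (x2.std(axis=0) == 0)
                  & (x1.mean(axis=0) == x2.mean(axis=0))):
            warnings.warn("zero pooled variance at some level; t reported as 0",
                          RuntimeWarning, stacklevel=2)
    df = x1.shape[0] + x2.shape[0] - 2
    return LevelStats(levels=tuple(levels), t_values=np.asarray(t, dtype=float),
                      df=df)


def _find_clusters(t: np.ndarray, lo: float, hi: float, levels) -> list[Cluster]:
    clusters: list[Cluster] = []
    supra = np.where(t > hi, 1, np.where(t < lo, -1, 0))
    start = None
    sign = 0
    for i in range(len(t) + 1):
        s = supra[i] if i < len(t) else 0
        if start is not None and s != sign:
            clusters.append(Cluster(
                start=start, stop=i - 1,
                levels=tuple(levels[start:i]),
                stat=float(t[start:i].sum()), sign=sign))
            start = None
        if s != 0 and start is None:
            start = i
            sign = s
    return clusters


def _max_abs_cluster_stat(t: np.ndarray, lo: float, hi: float) -> float:
    """Maximum absolute cluster sum of a t profile (0 when no cluster)."""
    best = 0.0
    run = 0.0
    state = 0
    for v in list(t) + [0.0]:
        s = 1 if v > hi else (-1 if v < lo else 0)
        if state != 0 and s != state:
            best = max(best, abs(run))
            run = 0.0
        if s != 0:
            if state != s:
                run = 0.0
            run += v
        state = s
    return best


def _null_stats_for_partitions(values: np.ndarray, idx_sets: np.ndarray,
                               n1: int, lo: float, hi: float) -> np.ndarray:
    """Max-|cluster-sum| statistic for each repartition.

    ``values`` is the pooled (n_subjects, n_levels) array; ``idx_sets``
    is (n_partitions, n1) of row indices assigned to group 1.
    """
    n = values.shape[0]
    out = np.empty(idx_sets.shape[0])
    mask = np.zeros(n, dtype=bool)
    for k, idx in enumerate(idx_sets):
        mask[:] = False
        mask[idx] = True
        t = _tstat_matrix(values[mask], values[~mask])
        out[k] = _max_abs_cluster_stat(t, lo, hi)
    return out


def cluster_permutation_test(group1: np.ndarray, group2: np.ndarray,
                             levels=None, n_permutations: int = 5000,
                             seed=0, method: str = "auto",
                             exhaustive_limit: int = 20000) -> ClusterResult:
    """Cluster-based permutation test over adjacent T or K levels.

    Observed per-level t values are thresholded at the 2.5th/97.5th
    quantiles of the t distribution with df = n1 + n2 - 2; maximal runs
    of same-signed supra-threshold levels form clusters scored by their
    summed t.  The two-sided test refers the maximum absolute cluster
    sum to its distribution under random repartitions of the pooled
    subjects into groups of the original sizes.

    When the number of distinct repartitions C(n1+n2, n1) does not
    exceed ``exhaustive_limit`` (and method is "auto" or "exhaustive"),
    all repartitions are enumerated and the p-value is the exact
    fraction with a statistic at least as large as the observed one
    (the observed labeling is one of them).  Otherwise ``n_permutations``
    Monte-Carlo repartitions are drawn and
    p = (count >= observed + 1) / (n_permutations + 1).
    """
    x1 = np.atleast_2d(np.asarray(group1, dtype=float))
    x2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      RuntimeWarning, stacklevel=2)
    if levels is None:
        levels = tuple(range(x1.shape[1]))
    obs = level_tstats(x1, x2, levels=levels)
    lo = float(sps.t.ppf(0.025, obs.df))
    hi = float(sps.t.ppf(0.975, obs.df))
    clusters = _find_clusters(obs.t_values, lo, hi, list(levels))
    max_stat = max((abs(c.stat) for c in clusters), default=0.0)

    pooled = np.vstack([x1, x2])
    n = n1 + n2
    total = math.comb(n, n1)
    if method not in ("auto", "exhaustive", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")
    use_exhaustive = (method == "exhaustive" or
                      (method == "auto" and total <= exhaustive_limit))
    if not clusters:
        p = 1.0
        n_used = total if use_exhaustive else n_permutations
        return ClusterResult(clusters=(), max_stat=0.0, p_value=p,
                             n_permutations=n_used,
                             method="exhaustive" if use_exhaustive else "montecarlo",
                             threshold=(lo, hi))
    if use_exhaustive:
        idx_sets = np.array(list(itertools.combinations(range(n), n1)),
                            dtype=int)
        null = _null_stats_for_partitions(pooled, idx_sets, n1, lo, hi)
        p = float((null >= max_stat - 1e-12).sum()) / total
        n_used = total
        how = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        idx_sets = np.empty((n_permutations, n1), dtype=int)
        for k in range(n_permutations):
            idx_sets[k] = rng.choice(n, size=n1, replace=False)
        null = _null_stats_for_partitions(pooled, idx_sets, n1, lo, hi)
        p = (float((null >= max_stat - 1e-12).sum()) + 1.0) / (n_permutations + 1.0)
        n_used = n_permutations
        how = "montecarlo"
    return ClusterResult(clusters=tuple(clusters), max_stat=float(max_stat),
                         p_value=float(p), n_permutations=n_used, method=how,
                         threshold=(lo, hi))


def regional_difference_map(group1_matrices, group2_matrices,
                            alpha: float = 0.05) -> RegionalDiffMap:
    """Two-tailed uncorrected t-test of SL per region pair.

    ``group*_matrices`` are lists of :class:`slnet.sl.SyncMatrix` with
    identical region labels.  The sign matrix marks pairs with
    group1 > group2 (+1) or group1 < group2 (-1) at p < alpha; no
    multiple-comparison correction is applied by design, so only
    regional (block-level) patterns should be interpreted.
    """
    labels = group1_matrices[0].region_labels
    for m in list(group1_matrices) + list(group2_matrices):
        if m.region_labels != labels:
            raise ValueError("all matrices must share the same region labels")
    x1 = np.stack([m.values for m in group1_matrices])
    x2 = np.stack([m.values for m in group2_matrices])
    t = _tstat_matrix(x1, x2)
    df = x1.shape[0] + x2.shape[0] - 2
    p = 2.0 * sps.t.sf(np.abs(t), df)
    signs = np.where(p < alpha, np.sign(t).astype(int), 0)
    np.fill_diagonal(signs, 0)
    np.fill_diagonal(p, 1.0)
    np.fill_diagonal(t, 0.0)
    signs = np.asarray(signs, dtype=int)
    return RegionalDiffMap(signs=signs, p_values=p, t_values=t,
                           alpha=alpha, region_labels=labels)


def block_summary(diff_map: RegionalDiffMap, registry,
                  exclude_cerebellum: bool = False):
    """Aggregate signed significances into per-block-pair counts.

    ``registry`` is the ROI registry DataFrame (columns: region,
    hemisphere, block, cerebellum).  Returns a DataFrame with one row
    per unordered block pair and columns ``n_increase`` / ``n_decrease``
    (counts of +1 and -1 region pairs).
    """
    import pandas as pd

    reg = registry.set_index("region")
    missing = [r for r in diff_map.region_labels if r not in reg.index]
    if missing:
        raise ValueError(f"regions missing from registry: {missing[:5]}")
    blocks = [reg.loc[r, "block"] for r in diff_map.region_labels]
    cereb = [bool(reg.loc[r, "cerebellum"]) for r in diff_map.region_labels]
    counts: dict[tuple[str, str], list[int]] = {}
    n = len(blocks)
    for i in range(n):
        for j in range(i + 1, n):
            if exclude_cerebellum and (cereb[i] or cereb[j]):
                continue
            s = diff_map.signs[i, j]
            key = tuple(sorted((blocks[i], blocks[j])))
            c = counts.setdefault(key, [0, 0])
            if s > 0:
                c[0] += 1
            elif s < 0:
                c[1] += 1
    rows = [{"block_a": a, "block_b": b, "n_increase": c[0], "n_decrease": c[1]}
            for (a, b), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["block_a", "block_b",
                                       "n_increase", "n_decrease"])
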