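"""Diversity, dissimilarity, ordination, and shared-taxa set analysis.

Implements the community-level machinery of the pipeline: analytic
rarefaction (expected richness under hypergeometric subsampling),
Shannon diversity, Bray-Curtis dissimilarity matrices, rank-based
ANOSIM with a permutation p-value, covariance PCA of relative-abundance
profiles, and Venn-region partitions of genus sets with percentages of
the union.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# alpha diversity


def observed_richness(counts) -> int:
    counts = np.asarray(counts, dtype=float)
    return int((counts > 0).sum())


def shannon_diversity(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over positive counts (natural log)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all-zero count vector")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def rarefaction_expected(counts, depth: int) -> float:
    """Expected number of distinct taxa in a random subsample of *depth*.

    Analytic hypergeometric expectation
    ``sum_i [1 - C(N - N_i, depth) / C(N, depth)]`` evaluated with
    log-gamma for numerical stability at large N.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if depth < 0 or depth > n_total:
        raise ValueError(f"depth {depth} outside [0, {n_total}]")
    if depth == 0:
        return 0.0

    def _logcomb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = n_total - counts
    with np.errstate(invalid="ignore"):
        log_p_absent = np.where(
            rest >= depth, _logcomb(rest, depth) - _logcomb(n_total, depth), -np.inf
        )
    return float(np.sum(1.0 - np.exp(log_p_absent)))


def rarefaction_curve(counts, depths=None) -> pd.DataFrame:
    """Expected-richness curve over a grid of depths (TSV-ready)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depths is None:
        depths = np.unique(np.linspace(0, total, 21).astype(int))
    rows = [(int(d), rarefaction_expected(counts, int(d))) for d in depths]
    return pd.DataFrame(rows, columns=["depth", "expected_richness"])


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min(u, v)) / (sum u + sum v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = u.sum() + v.sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(u, v).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix, zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        x = self.data.to_numpy(dtype=float)
        if x.shape[0] != x.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(x, x.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.diag(x) == 0):
            raise ValueError("diagonal must be exactly zero")
        if (x < 0).any():
            raise ValueError("dissimilarities must be non-negative")

    @property
    def labels(self) -> list[str]:
        return list(self.data.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.data.to_numpy(dtype=float), checks=False)


def bray_curtis_matrix(matrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between samples (matrix columns)."""
    counts = matrix.counts if hasattr(matrix, "counts") else pd.DataFrame(matrix)
    x = counts.to_numpy(dtype=float).T  # samples x features
    condensed = pdist(x, metric="braycurtis")
    dm = pd.DataFrame(squareform(condensed), index=counts.columns, columns=counts.columns)
    np.fill_diagonal(dm.values, 0.0)
    return DistanceMatrix(dm)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    """ANOSIM statistic R in [-1, 1] with permutation p-value."""

    R: float
    p: float
    n_perm: int
    exhaustive: bool = False


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n_pairs = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (n_pairs / 2.0))


def _within_mask(groups: np.ndarray) -> np.ndarray:
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    return groups[iu[0]] == groups[iu[1]]


def _n_distinct_assignments(sizes) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs and mid-ranks for ties.  The p-value permutes the
    group labels with the (exceedances + 1) / (n_perm + 1) convention;
    when the number of distinct label assignments is at most ``n_perm``
    the permutation distribution is enumerated exhaustively instead of
    sampled.
    """
    labels = dist.labels
    if hasattr(groups, "get") and not isinstance(groups, pd.Series):
        gvec = np.asarray([groups[l] for l in labels])
    elif isinstance(groups, pd.Series):
        gvec = groups.reindex(labels).to_numpy()
    else:
        gvec = np.asarray(list(groups))
        if len(gvec) != len(labels):
            raise ValueError("groups length must match number of samples")
    uniq, inv = np.unique(gvec, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sizes = np.bincount(inv)
    if (sizes < 2).all():
        raise ValueError("no within-group pairs: all groups are singletons")

    ranks = rankdata(dist.condensed(), method="average")
    within = _within_mask(inv)
    r_obs = _anosim_r(ranks, within)

    total = _n_distinct_assignments(sizes)
    tol = 1e-12
    if total <= n_perm:
        # exhaustive: every distinct assignment of labels to positions
        n = len(inv)
        exceed = 0
        for combo in _distinct_assignments(inv):
            w = _within_mask(np.asarray(combo))
            if _anosim_r(ranks, w) >= r_obs - tol:
                exceed += 1
        return AnosimResult(R=r_obs, p=exceed / total, n_perm=total - 1, exhaustive=True)

    rng = np.random.default_rng(seed)
    exceed = 0
    perm = inv.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _anosim_r(ranks, _within_mask(perm)) >= r_obs - tol:
            exceed += 1
    return AnosimResult(R=r_obs, p=(exceed + 1) / (n_perm + 1), n_perm=n_perm)


def _distinct_assignments(inv: np.ndarray):
    """Yield every distinct permutation of the multiset of group codes."""
    # recursive multiset-permutation generator (counts-based, no dedupe scan)
    counts = list(np.bincount(inv))
    n = len(inv)
    current = [0] * n

    def rec(pos):
        if pos == n:
            yield tuple(current)
            return
        for g, c in enumerate(counts):
            if c > 0:
                counts[g] -= 1
                current[pos] = g
                yield from rec(pos + 1)
                counts[g] += 1

    yield from rec(0)


# ---------------------------------------------------------------------------
# PCA ordination


@dataclass
class OrdinationResult:
    """PCA of samples on centered (unscaled) abundance profiles."""

    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # features x components
    explained: np.ndarray      # variance fractions, sum <= 1
    eigenvalues: np.ndarray    # covariance eigenvalues (s^2 / (n-1))


def pca_ordination(matrix) -> OrdinationResult:
    """Covariance PCA with samples as observations.

    Features are centered across samples (no unit-variance scaling);
    components come from the singular decomposition of the centered
    data.  Sign convention: within each component the loading of
    largest magnitude is positive.
    """
    counts = matrix.counts if hasattr(matrix, "counts") else pd.DataFrame(matrix)
    x = counts.to_numpy(dtype=float).T  # samples x features
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n - 1, x.shape[1])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total_var = float((s**2).sum())
    explained = (s**2) / total_var if total_var > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(u * s, index=counts.columns, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=counts.index, columns=comp_names),
        explained=explained,
        eigenvalues=(s**2) / (n - 1),
    )


# ---------------------------------------------------------------------------
# Venn partition


@dataclass
class VennSummary:
    """Exclusive Venn-region counts with percentages of the union."""

    regions: dict            # tuple(sorted member-set names) -> count
    percentages: dict        # same keys -> % of union, 1 decimal
    union_size: int
    set_names: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(k), self.regions[k], self.percentages[k])
            for k in sorted(self.regions, key=lambda k: (len(k), k))
        ]
        return pd.DataFrame(rows, columns=["region", "count", "pct_of_union"])


def venn_partition(sets) -> VennSummary:
    """Partition 2 or 3 named sets into exclusive Venn regions.

    *sets* is a mapping name -> iterable, or a sequence of (name, set)
    pairs (duplicate names rejected).  Every region (non-empty subset of
    the names) is reported with its exclusive member count and its
    percentage of the union, rounded to 1 decimal.
    """
    if isinstance(sets, dict):
        items = list(sets.items())
    else:
        items = [(name, s) for name, s in sets]
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    if not (2 <= len(items) <= 3):
        raise ValueError("venn_partition supports 2 or 3 sets")
    named = {name: set(s) for name, s in items}
    union = set().union(*named.values())
    regions = {}
    percentages = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set().union(*(named[n] for n in names if n not in combo), set())
            members = inside - outside
            key = tuple(sorted(combo))
            regions[key] = len(members)
            percentages[key] = (
                round(100.0 * len(members) / len(union), 1) if union else 0.0
            )
    return VennSummary(
        regions=regions, percentages=percentages, union_size=len(union),
        set_names=tuple(names),
    )
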