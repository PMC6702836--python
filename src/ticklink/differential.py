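"""Per-feature two-sample exact tests, FDR control, ANOVA with post-hoc.

The two-sample path mirrors the classic metagenome-profile comparison:
for every feature the two samples' hit counts form a 2x2 contingency
table against the remaining hits, tested with a two-sided Fisher exact
test (minimum-likelihood convention), corrected across features with
Benjamini-Hochberg, and reported with a 95% Newcombe-Wilson hybrid
score confidence interval on the difference of proportions.  Exact
tests always consume raw integer counts.

The multi-group path is one-way ANOVA with eta-squared effect sizes and
Tukey-Kramer post-hoc pairwise comparisons (studentized-range
distribution).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .profile_io import ThresholdConfig

#: Relative tolerance in the "probability <= observed" comparison of the
#: minimum-likelihood two-sided Fisher test; absorbs floating-point ties.
_FISHER_REL_TOL = 1e-12


def _logcomb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_pmf(x, n, c1, r1):
    """Vectorized hypergeometric pmf over the support (log-gamma based)."""
    logp = _logcomb(c1, x) + _logcomb(n - c1, r1 - x) - _logcomb(n, r1)
    return np.exp(logp)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention).

    *table* is ``[[a, b], [c, d]]``.  All tables with the observed
    margins are enumerated via the hypergeometric pmf; the p-value sums
    the probabilities not exceeding the observed table's probability
    (within relative tolerance 1e-12).  Degenerate margins give p = 1.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("contingency table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    included = pmf <= p_obs * (1.0 + _FISHER_REL_TOL)
    if included.all():
        return 1.0
    p = float(pmf[included].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over p sorted ascending,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _wilson_interval(k: int, n: int, z: float) -> tuple[float, float]:
    if n == 0:
        return 0.0, 1.0
    p = k / n
    z2 = z * z
    denom = 1 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def newcombe_ci(k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05):
    """Newcombe-Wilson hybrid score CI for the difference of proportions."""
    z = stats.norm.ppf(1 - alpha / 2)
    p1 = k1 / n1 if n1 else 0.0
    p2 = k2 / n2 if n2 else 0.0
    l1, u1 = _wilson_interval(k1, n1, z)
    l2, u2 = _wilson_interval(k2, n2, z)
    d = p1 - p2
    lo = d - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    hi = d + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return float(lo), float(hi)


def two_sample_feature_test(
    matrix, sample_a: str, sample_b: str, thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Fisher-exact comparison of two samples, feature by feature.

    For each feature r the table is ``[[counts(r, A), total_A - counts],
    [counts(r, B), total_B - counts]]``; q-values are BH-adjusted across
    all features of the matrix's level; ``enriched_in`` names the sample
    with the larger proportion when q < q_alpha, else "none".  Returns
    the plot-ready extended-error-bar table.
    """
    thresholds = thresholds or ThresholdConfig()
    counts = matrix.counts if hasattr(matrix, "counts") else pd.DataFrame(matrix)
    for s in (sample_a, sample_b):
        if s not in counts.columns:
            raise ValueError(f"sample {s!r} not found in matrix")
    col_a = counts[sample_a].to_numpy()
    col_b = counts[sample_b].to_numpy()
    for col, name in ((col_a, sample_a), (col_b, sample_b)):
        if not np.allclose(col, np.round(col)):
            raise ValueError(f"sample {name!r} has non-integer counts; "
                             "exact tests require raw counts")
    ka = np.round(col_a).astype(np.int64)
    kb = np.round(col_b).astype(np.int64)
    na, nb = int(ka.sum()), int(kb.sum())

    rows = []
    for feat, a, b in zip(counts.index, ka, kb):
        p = fisher_two_sided([[a, na - a], [b, nb - b]])
        pa = a / na if na else 0.0
        pb = b / nb if nb else 0.0
        lo, hi = newcombe_ci(int(a), na, int(b), nb)
        rows.append((feat, pa, pb, pa - pb, lo, hi, p))
    out = pd.DataFrame(
        rows,
        columns=["feature", "prop_a", "prop_b", "difference", "ci_low", "ci_high", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = out["q"] < thresholds.q_alpha
    out["enriched_in"] = np.select(
        [sig & (out["difference"] > 0), sig & (out["difference"] < 0)],
        [sample_a, sample_b],
        default="none",
    )
    return out


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer


@dataclass
class AnovaResult:
    """One-way ANOVA with eta-squared effect size and optional post-hoc."""

    F: float
    p: float
    eta2: float
    df_between: int
    df_within: int
    msw: float
    group_means: dict
    group_sizes: dict
    posthoc: pd.DataFrame | None = None


def anova_effect(groups: dict, posthoc: bool = True) -> AnovaResult:
    """One-way ANOVA over labelled groups of observations.

    F = MSB/MSW, eta2 = SSB/SST; when MSW = 0 with SSB > 0 the F
    statistic is +inf with p = 0.  Raises on zero total variance.
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(x) == 0 for x in data):
        raise ValueError("every group needs at least 1 observation")
    n = sum(len(x) for x in data)
    k = len(data)
    if n - k < 1:
        raise ValueError("need at least one group with >= 2 observations")
    allx = np.concatenate(data)
    grand = allx.mean()
    sst = float(((allx - grand) ** 2).sum())
    if sst == 0:
        raise ValueError("degenerate: zero total variance")
    ssb = float(sum(len(x) * (x.mean() - grand) ** 2 for x in data))
    ssw = sst - ssb
    df_b, df_w = k - 1, n - k
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = msb / msw
        p = float(stats.f.sf(f_stat, df_b, df_w))
    means = {g: float(x.mean()) for g, x in zip(labels, data)}
    sizes = {g: len(x) for g, x in zip(labels, data)}
    ph = None
    if posthoc and msw > 0:
        ph = tukey_kramer(means, sizes, msw, df_w)
    return AnovaResult(
        F=float(f_stat), p=p, eta2=ssb / sst, df_between=df_b, df_within=df_w,
        msw=msw, group_means=means, group_sizes=sizes, posthoc=ph,
    )


def tukey_kramer(means: dict, sizes: dict, msw: float, df_w: int) -> pd.DataFrame:
    """Tukey-Kramer pairwise post-hoc comparisons.

    q_ij = |mean_i - mean_j| / sqrt((MSW/2)(1/n_i + 1/n_j)); the p-value
    comes from the studentized-range distribution with (k, df_w).
    """
    if msw <= 0:
        raise ValueError("MSW must be positive")
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if df_w < 1:
        raise ValueError("df_within must be >= 1")
    rows = []
    for gi, gj in itertools.combinations(means, 2):
        se = np.sqrt((msw / 2.0) * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        q = abs(means[gi] - means[gj]) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append((gi, gj, float(q), min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "q_stat", "p"])


def anova_feature_test(
    matrix, group_map: dict, thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across sample groups.

    *group_map* maps sample ids to group labels.  Features with zero
    total variance are reported with F = 0, p = 1, eta2 = 0.  q-values
    are BH-adjusted across features; ``significant`` requires both
    q < q_alpha and eta2 > eta2_min (the effect-size floor used when
    ranking category-level differences).
    """
    thresholds = thresholds or ThresholdConfig()
    counts = matrix.counts if hasattr(matrix, "counts") else pd.DataFrame(matrix)
    by_group: dict[str, list[str]] = {}
    for s in counts.columns:
        if s in group_map:
            by_group.setdefault(group_map[s], []).append(s)
    if len(by_group) < 2:
        raise ValueError("need samples from at least 2 groups")
    rows = []
    for feat in counts.index:
        groups = {g: counts.loc[feat, cols].to_numpy(dtype=float)
                  for g, cols in by_group.items()}
        try:
            res = anova_effect(groups, posthoc=False)
            rows.append((feat, res.F, res.p, res.eta2))
        except ValueError:
            rows.append((feat, 0.0, 1.0, 0.0))
    out = pd.DataFrame(rows, columns=["feature", "F", "p", "eta2"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] < thresholds.q_alpha) & (out["eta2"] > thresholds.eta2_min)
    return out
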