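"""Two-group differential expression tests.

Three tests are provided per feature of a log2-scale matrix:

* ``ttest`` — Welch two-sample t (unequal variances), two-sided.
* ``wilcoxon`` — Wilcoxon rank-sum / Mann-Whitney, two-sided; exact null
  distribution for small tie-free samples, otherwise the normal
  approximation with continuity correction and midrank tie handling.
* ``moderated_t`` — empirical-Bayes moderated t: per-feature sample
  variances are shrunk toward a prior fitted by moment-matching the
  distribution of log sample variances (digamma/trigamma inversion), and
  the t statistic is referred to a t distribution with prior + residual
  degrees of freedom.  This is the standard variance-shrinkage scheme for
  small-sample microarray designs.

A fourth method name, ``deseq2`` (negative-binomial count model), is
recognised but deliberately not implemented: these tests operate on
(log-scale) continuous intensities, not counts.

A feature "passes" when its raw p-value is below ``p_threshold`` (default
0.05) and its |log2 ratio| (case mean minus control mean) is at least
``ratio_threshold`` (default 0.5).  Benjamini-Hochberg q-values are
reported per matrix alongside raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ExpressionMatrix, SampleGroups

DE_METHODS = ("ttest", "wilcoxon", "moderated_t")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1, where p_(1) <= ...
    <= p_(m) are the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# per-group summaries (NaN-aware)
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray, idx: np.ndarray):
    sub = values[:, idx]
    finite = np.isfinite(sub)
    n = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(finite, sub, 0.0), axis=1) / np.maximum(n, 1), np.nan)
        centred = np.where(finite, sub - mean[:, None], 0.0)
        ss = (centred**2).sum(axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def _welch(n1, m1, v1, n2, m2, v2):
    se2 = v1 / n1 + v2 / n2
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = ~np.isfinite(se2) | (se2 <= 0)
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 25  # exact null up to this group size (tie-free); normal approx beyond


def _wilcoxon_one(x, y):
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        return 0.0, 1.0, True
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, True
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(x.size, y.size) <= _EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"  # midranks, tie-corrected variance, continuity correction
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue), False


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, iterations: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on a stable scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(iterations):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-12:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (d0, s0^2) for gene variances.

    Moment-matching on e_g = log s2_g - digamma(d_g/2) + log(d_g/2): the
    excess variance of e over its sampling component trigamma(d_g/2)
    identifies trigamma(d0/2); the mean identifies s0^2.  If the observed
    variance is no larger than the sampling component, the prior df is
    infinite and s0^2 is the mean sample variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[np.isfinite(s2)])) if np.isfinite(s2).any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    return float(d0), s0_sq


def _moderated_t(n1, m1, v1, n2, m2, v2):
    d_res = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d_res
    d0, s0_sq = fit_variance_prior(s2, d_res.astype(float))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full(s2.shape, np.inf)
    else:
        s2_post = (d0 * s0_sq + d_res * np.where(np.isfinite(s2), s2, 0.0)) / (d0 + d_res)
        df_total = d0 + d_res
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = ~np.isfinite(se) | (se <= 0)
    t = np.where(degenerate, 0.0, t)
    finite_df = np.where(np.isfinite(df_total), df_total, 1.0)
    p = np.where(
        np.isfinite(df_total),
        2.0 * stats.t.sf(np.abs(t), finite_df),
        2.0 * stats.norm.sf(np.abs(t)),
    )
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate, d0, s0_sq


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def differential_test(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    method: str = "ttest",
    p_threshold: float = 0.05,
    ratio_threshold: float = 0.5,
) -> pd.DataFrame:
    """Test every feature for a two-group difference.

    Returns a frame indexed by feature id with columns ``statistic``,
    ``p_value``, ``q_value`` (BH over all features of this matrix),
    ``log_ratio`` (case mean − control mean, log2 scale), ``passes``
    (p < p_threshold and |log_ratio| >= ratio_threshold) and ``degenerate``
    (zero variance in both groups; such features get p = 1, never an
    exception).
    """
    if method == "deseq2":
        raise NotImplementedError(
            "the negative-binomial count model ('deseq2') is not provided: "
            "these tests operate on log-scale continuous intensities; "
            "choose one of " + ", ".join(DE_METHODS)
        )
    if method not in DE_METHODS:
        raise ValueError(f"unknown DE method {method!r}; choose from {DE_METHODS}")
    ctrl_idx, case_idx = groups.indices_for(expr.sample_ids, minimum_per_group=2)
    values = expr.values
    n1, m1, v1 = _group_stats(values, ctrl_idx)
    n2, m2, v2 = _group_stats(values, case_idx)
    too_small = (n1 < 2) | (n2 < 2)

    if method == "ttest":
        stat, p, degenerate = _welch(n1, m1, v1, n2, m2, v2)
    elif method == "moderated_t":
        stat, p, degenerate, _, _ = _moderated_t(n1, m1, v1, n2, m2, v2)
    else:
        stat = np.zeros(values.shape[0])
        p = np.ones(values.shape[0])
        degenerate = np.zeros(values.shape[0], dtype=bool)
        for g in range(values.shape[0]):
            stat[g], p[g], degenerate[g] = _wilcoxon_one(
                values[g, ctrl_idx], values[g, case_idx]
            )

    stat = np.where(too_small, 0.0, stat)
    p = np.where(too_small, 1.0, p)
    degenerate = degenerate | too_small
    log_ratio = m2 - m1
    q = bh_adjust(np.clip(p, 0.0, 1.0))
    passes = (p < p_threshold) & (np.abs(log_ratio) >= ratio_threshold) & np.isfinite(log_ratio)
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "log_ratio": log_ratio,
            "passes": passes,
            "degenerate": degenerate,
        }
    ).set_index("feature_id")


def passing_features(de_table: pd.DataFrame) -> list[str]:
    """Feature ids flagged as differentially expressed, in matrix order."""
    return de_table.index[de_table["passes"]].tolist()
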