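"""miRNA-gene correlation analysis and interaction-database intersection.

A repressive miRNA is expected to anti-correlate with its target gene
across samples, so candidate (DE miRNA, DE gene) pairs are scored with a
correlation coefficient (Pearson, Spearman, or Kendall tau-b) over all
samples and kept when r falls at or below a cutoff (default −0.5, a
moderate negative correlation).  Pairs are then intersected with a table
of predicted/validated interactions: the number of prediction sources
supporting a pair (its support count) and its validated flag drive the
final filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, InteractionDB
from .errors import SampleMismatchError

CORRELATION_METHODS = ("pearson", "kendall", "spearman")


def correlate(x, y, method: str = "pearson") -> float:
    """Correlation between two equal-length vectors.

    ``pearson`` is the product-moment coefficient, ``spearman`` is Pearson
    on midranks, ``kendall`` is tau-b (tie-corrected).  A vector with zero
    variance (or fewer than 3 paired finite observations) yields NaN — an
    undefined correlation, reported but never an exception.
    """
    if method not in CORRELATION_METHODS:
        raise ValueError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.kendalltau(x, y).statistic)  # tau-b


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix between a (p x n) and b (q x n)."""
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((a_c**2).sum(axis=1))
    b_sd = np.sqrt((b_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a_c @ b_c.T) / np.outer(a_sd, b_sd)
    r[(a_sd == 0), :] = np.nan
    r[:, (b_sd == 0)] = np.nan
    return np.where(np.isfinite(r), np.clip(r, -1.0, 1.0), np.nan)


def align_samples(mirna_expr: ExpressionMatrix, gene_expr: ExpressionMatrix):
    """Return the two matrices restricted to their (identical) sample set.

    The sample sets must coincide; ordering differences are repaired by
    reordering the gene matrix to the miRNA matrix's order.  A genuine set
    mismatch raises :class:`SampleMismatchError` naming the offending ids.
    """
    m_set, g_set = set(mirna_expr.sample_ids), set(gene_expr.sample_ids)
    if m_set != g_set:
        only_m = sorted(m_set - g_set)
        only_g = sorted(g_set - m_set)
        raise SampleMismatchError(
            f"sample sets differ: only in miRNA matrix {only_m}, only in gene matrix {only_g}"
        )
    return mirna_expr, gene_expr.reorder_samples(mirna_expr.sample_ids)


def correlate_de_pairs(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    de_mirnas,
    de_genes,
    method: str = "pearson",
    cutoff: float = -0.5,
) -> pd.DataFrame:
    """Correlate every (DE miRNA, DE gene) combination across all samples.

    Both phenotype groups are pooled.  Returns one row per pair with
    columns ``mirna``, ``gene``, ``r``, ``method``, ``passes_cutoff``
    (r <= cutoff; NaN correlations never pass).
    """
    if method not in CORRELATION_METHODS:
        raise ValueError(f"unknown correlation method {method!r}")
    de_mirnas = list(de_mirnas)
    de_genes = list(de_genes)
    cols = ["mirna", "gene", "r", "method", "passes_cutoff"]
    if not de_mirnas or not de_genes:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(cols, [str, str, float, str, bool])})
    mirna_expr, gene_expr = align_samples(mirna_expr, gene_expr)
    mv = mirna_expr.subset_features(de_mirnas).values
    gv = gene_expr.subset_features(de_genes).values

    if method == "pearson":
        r = _pearson_matrix(mv, gv)
    elif method == "spearman":
        r = _pearson_matrix(_rank_rows(mv), _rank_rows(gv))
    else:
        r = np.empty((len(de_mirnas), len(de_genes)))
        for i in range(len(de_mirnas)):
            for j in range(len(de_genes)):
                r[i, j] = correlate(mv[i], gv[j], "kendall")
    # non-finite inputs fall back to the pairwise-complete scalar path
    if method in ("pearson", "spearman"):
        bad_m = ~np.isfinite(mv).all(axis=1)
        bad_g = ~np.isfinite(gv).all(axis=1)
        for i in np.flatnonzero(bad_m):
            for j in range(len(de_genes)):
                r[i, j] = correlate(mv[i], gv[j], method)
        for j in np.flatnonzero(bad_g):
            for i in range(len(de_mirnas)):
                r[i, j] = correlate(mv[i], gv[j], method)

    mirna_col = np.repeat(de_mirnas, len(de_genes))
    gene_col = np.tile(de_genes, len(de_mirnas))
    flat = r.ravel()
    with np.errstate(invalid="ignore"):
        passes = np.where(np.isfinite(flat), flat <= cutoff, False)
    return pd.DataFrame(
        {
            "mirna": mirna_col,
            "gene": gene_col,
            "r": flat,
            "method": method,
            "passes_cutoff": passes.astype(bool),
        }
    )


def annotate_pairs(
    pairs: pd.DataFrame,
    db: InteractionDB,
    min_support: int = 1,
    require_validated: bool = False,
) -> pd.DataFrame:
    """Annotate pairs with database support and filter on it.

    Each pair gains ``support_count`` and ``validated`` (0/False when the
    pair is absent from the database).  A pair is kept when
    ``support_count >= min_support``, or when ``require_validated`` is set
    and the pair is experimentally validated (validated pairs then survive
    regardless of prediction support).  ``min_support=0`` keeps everything.
    """
    annotated = db.lookup(pairs)
    keep = annotated["support_count"] >= min_support
    if require_validated:
        keep = keep | annotated["validated"]
    return annotated[keep].reset_index(drop=True)


def support_stratified_summary(
    pairs: pd.DataFrame,
    r_thresholds=(-0.1, -0.3, -0.5),
    support_thresholds=(1, 3),
) -> pd.DataFrame:
    """Proportion of negatively correlated pairs per prediction-support stratum.

    For each r threshold, counts pairs with r < threshold within the
    support = 0 stratum and within each support >= s stratum.  Pairs with
    undefined (NaN) correlation are excluded from both numerator and
    denominator.
    """
    defined = pairs[np.isfinite(pairs["r"])]
    strata = [("support=0", defined["support_count"] == 0)]
    for s in support_thresholds:
        strata.append((f"support>={s}", defined["support_count"] >= s))
    rows = []
    for r_thr in r_thresholds:
        for label, mask in strata:
            sub = defined[mask]
            n_below = int((sub["r"] < r_thr).sum())
            n_total = int(len(sub))
            rows.append(
                {
                    "r_threshold": r_thr,
                    "stratum": label,
                    "n_pairs": n_total,
                    "n_below": n_below,
                    "proportion": (n_below / n_total) if n_total else 0.0,
                }
            )
    return pd.DataFrame(rows)
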