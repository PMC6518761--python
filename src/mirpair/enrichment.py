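"""Hypergeometric pathway enrichment with a permutation empirical p-value.

Given a query of genes (here: genes anti-correlated with a DE miRNA and
supported by the interaction database) and a universe of N genes, a
pathway holding K universe genes and overlapping the size-n query in k
genes is scored with the hypergeometric upper tail P(X >= k).  The tail
is summed exactly in log space (log-gamma binomials + log-sum-exp) so
tiny p-values stay accurate.

Because an enrichment can look significant by chance when many pathways
are inspected, each pathway additionally receives an empirical p-value:
B random queries of the same size are drawn uniformly from the universe,
the pathway's hypergeometric p is recomputed for each, and the observed p
is ranked within this null with an add-one correction,
p_emp = (b + 1) / (B + 1).  With the default B = 5000 the smallest
reportable value is 1/5001 ≈ 0.0002.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .datatypes import GeneSetCollection
from .diff_expr import bh_adjust
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 5000


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Exact summation of the tail in log space.  ``k = 0`` gives 1 by
    definition; inconsistent counts raise ``ValueError``.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    lo, hi = k, min(K, n)
    if hi < max(0, n - (N - K)):  # pragma: no cover - excluded by the checks above
        raise ValueError("empty support")
    i = np.arange(max(lo, max(0, n - (N - K))), hi + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def upper_tail_table(K: int, n: int, N: int) -> np.ndarray:
    """Vector of P(X >= k) for k = 0 .. min(K, n) (shared by the permutation null)."""
    return np.array([hypergeom_upper_tail(k, K, n, N) for k in range(min(K, n) + 1)])


def enrich(query_genes, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of every collection set against a query.

    Query genes outside the universe are dropped with a warning.  Sets with
    no universe genes are skipped.  Returns one row per tested set, sorted
    by ``p_hyper`` ascending (ties broken by set name), with BH ``q_hyper``
    across the tested sets and an unset ``p_empirical`` column.
    """
    universe = set(universe)
    if not universe:
        raise DegenerateInputError("empty universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning(
            "%d of %d query genes are outside the universe and were dropped",
            len(outside), len(query),
        )
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for gene_set in collection:
        in_universe = gene_set.genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        rows.append(
            {
                "set_name": gene_set.name,
                "category": gene_set.category,
                "set_size_full": len(gene_set.genes),
                "set_size_in_universe": K,
                "hits": k,
                "p_hyper": hypergeom_upper_tail(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "category", "set_size_full", "set_size_in_universe",
                     "hits", "p_hyper", "q_hyper", "p_empirical"]
        )
    out = pd.DataFrame(rows)
    out["q_hyper"] = bh_adjust(out["p_hyper"].to_numpy())
    out["p_empirical"] = np.nan
    out = out.sort_values(["p_hyper", "set_name"], kind="mergesort", ignore_index=True)
    return out


def _null_overlap_counts(rng, universe_sorted, member_matrix, query_size, n_perm):
    """Overlap counts of ``n_perm`` random size-``query_size`` queries with each set.

    Returns an (n_perm, n_sets) integer array.  Sampling is without
    replacement within each draw, uniform over the universe.
    """
    N = len(universe_sorted)
    idx = np.argsort(rng.random((n_perm, N)), axis=1)[:, :query_size]
    return member_matrix[idx].sum(axis=1)


def permutation_empirical_p(
    result,
    collection: GeneSetCollection,
    universe,
    query_size: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> float:
    """Empirical p for one enrichment result row (mapping with set_name, p_hyper)."""
    table = add_empirical_p(
        pd.DataFrame([{"set_name": result["set_name"], "p_hyper": result["p_hyper"]}]),
        collection, universe, query_size, n_perm=n_perm, seed=seed,
    )
    return float(table["p_empirical"].iloc[0])


def add_empirical_p(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    universe,
    query_size: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach permutation empirical p-values to an enrichment table.

    One shared stream of B = ``n_perm`` random queries of the observed size
    is drawn from the universe; for every set the hypergeometric p is
    recomputed per draw and p_empirical = (b + 1)/(B + 1) with
    b = #{null p <= observed p}.  Deterministic given ``seed``.
    """
    universe_sorted = sorted(set(universe))
    N = len(universe_sorted)
    if query_size > N:
        raise DegenerateInputError(f"query size {query_size} exceeds universe size {N}")
    out = results.copy()
    if out.empty or query_size == 0:
        out["p_empirical"] = np.nan
        return out
    pos = {g: i for i, g in enumerate(universe_sorted)}
    set_names = out["set_name"].tolist()
    member_matrix = np.zeros((N, len(set_names)), dtype=bool)
    for j, name in enumerate(set_names):
        for g in collection[name].genes:
            if g in pos:
                member_matrix[pos[g], j] = True
    rng = np.random.default_rng(seed)
    counts = _null_overlap_counts(rng, universe_sorted, member_matrix, query_size, n_perm)
    p_emp = np.empty(len(set_names))
    for j, name in enumerate(set_names):
        K = int(member_matrix[:, j].sum())
        lookup = upper_tail_table(K, query_size, N)
        null_p = lookup[counts[:, j]]
        observed = float(out["p_hyper"].iloc[j])
        b = int((null_p <= observed).sum())
        p_emp[j] = (b + 1) / (n_perm + 1)
    out["p_empirical"] = p_emp
    return out
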