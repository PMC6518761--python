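"""Function-driven workflow: genome-wide gene-set scoring, then in-set pairs.

Instead of pre-filtering genes by per-gene significance, every gene set is
scored directly from genome-wide expression: for each test (case) sample,
per-gene log2 fold changes against the mean of the control samples are
formed, the set's fold changes are compared with the genome-wide background
by a two-sample t statistic, the t is mapped to a normal score, and the
per-sample scores are combined by a Stouffer sum.  Because every test
sample's fold changes share the same control-mean estimate per gene, the
per-sample scores are equicorrelated with rho = 1/(n_control + 1); the
Stouffer denominator is therefore sqrt(m * (1 + (m - 1) * rho)) rather
than sqrt(m), which makes the combined score standard normal under the
null.  Both directions (up- and down-regulation) are reported per set.

The top-ranked sets are then mined for candidate miRNA-gene pairs: for
each selected set, interaction-database pairs linking a DE miRNA to a set
gene are correlated across all samples and counted at a (looser) cutoff,
default r <= -0.3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetCollection, InteractionDB, SampleGroups
from .errors import DegenerateInputError
from .pair_analysis import align_samples, correlate_de_pairs

_Z_CLIP = 37.0  # |z| beyond this underflows the normal tail in double precision


def _t_to_z(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Map t statistics to standard-normal scores, tail-accurately."""
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    sf = stats.t.sf(np.abs(t), df)
    sf = np.clip(sf, 1e-300, 1.0)
    z = -stats.norm.ppf(sf)  # positive magnitude
    z = np.clip(z, -_Z_CLIP, _Z_CLIP)
    return np.sign(t) * z


def score_gene_sets(
    gene_expr: ExpressionMatrix,
    groups: SampleGroups,
    collection: GeneSetCollection,
    min_set_size: int = 10,
) -> pd.DataFrame:
    """Score every gene set in both directions, with no per-gene filtering.

    Returns two rows per scored set (direction 'up' and 'down') with the
    combined z and its one-sided normal p.  Sets with fewer than
    ``min_set_size`` measured genes are skipped.  Sorted by p ascending,
    ties by set name then direction.
    """
    ctrl_idx, case_idx = groups.indices_for(gene_expr.sample_ids, minimum_per_group=1)
    if len(ctrl_idx) == 0:
        raise DegenerateInputError("no control samples")
    if len(case_idx) == 0:
        raise DegenerateInputError("no test samples")
    values = gene_expr.values
    ctrl_mean = values[:, ctrl_idx].mean(axis=1)
    fold = values[:, case_idx] - ctrl_mean[:, None]  # genes x test samples
    n_genes, m = fold.shape
    bg_mean = fold.mean(axis=0)
    bg_var = fold.var(axis=0, ddof=1)
    feature_pos = {g: i for i, g in enumerate(gene_expr.feature_ids)}
    rho = 1.0 / (len(ctrl_idx) + 1.0)
    denom = np.sqrt(m * (1.0 + (m - 1.0) * rho))

    rows = []
    for gene_set in collection:
        idx = np.array(sorted(feature_pos[g] for g in gene_set.genes if g in feature_pos))
        n_set = idx.size
        if n_set < min_set_size:
            continue
        if n_set > n_genes:  # pragma: no cover - impossible by construction
            raise DegenerateInputError(f"set {gene_set.name!r} larger than universe")
        sub = fold[idx]
        set_mean = sub.mean(axis=0)
        set_var = sub.var(axis=0, ddof=1)
        se2 = set_var / n_set + bg_var / n_genes
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (set_mean - bg_mean) / np.sqrt(se2)
            df = se2**2 / (
                (set_var / n_set) ** 2 / (n_set - 1)
                + (bg_var / n_genes) ** 2 / (n_genes - 1)
            )
        ok = np.isfinite(t) & np.isfinite(df) & (se2 > 0)
        z = np.zeros(m)
        z[ok] = _t_to_z(t[ok], df[ok])
        combined = z.sum() / denom
        p_up = float(stats.norm.sf(combined))
        p_down = float(stats.norm.cdf(combined))
        for direction, p in (("up", p_up), ("down", p_down)):
            rows.append(
                {
                    "set_name": gene_set.name,
                    "category": gene_set.category,
                    "direction": direction,
                    "z": combined,
                    "p": p,
                    "set_size_in_universe": int(n_set),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "category", "direction", "z", "p", "set_size_in_universe"],
    )
    return out.sort_values(["p", "set_name", "direction"], kind="mergesort", ignore_index=True)


def top_sets(scores: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k most significant sets (best direction per set), p ascending.

    Each set appears once, represented by its better-scoring direction;
    ties break lexicographically by set name for run-to-run stability.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    best = (
        scores.sort_values(["p", "set_name", "direction"], kind="mergesort")
        .drop_duplicates(subset="set_name", keep="first")
        .reset_index(drop=True)
    )
    return best.head(k).reset_index(drop=True)


def in_set_pairs(
    set_genes,
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    de_mirnas,
    db: InteractionDB,
    cor_method: str = "pearson",
    pair_cutoff: float = -0.3,
):
    """Candidate miRNA-gene pairs inside one gene set.

    Candidates are interaction-database records linking a DE miRNA to a
    measured set gene (any prediction support, or validated).  Correlations
    are computed over all samples.  Returns a report dict (set size in the
    measured universe, number of set genes targeted, number of pairs at
    r <= ``pair_cutoff``) and the per-pair table.
    """
    measured = set(gene_expr.feature_ids)
    genes_in_universe = sorted(set(set_genes) & measured)
    de_mirnas = [m for m in de_mirnas if m in set(mirna_expr.feature_ids)]
    rec = db.records
    cand = rec[
        rec["mirna"].isin(de_mirnas)
        & rec["gene"].isin(genes_in_universe)
        & ((rec["support_count"] >= 1) | rec["validated"])
    ][["mirna", "gene", "support_count", "validated"]]

    if cand.empty:
        pairs = pd.DataFrame(
            columns=["mirna", "gene", "r", "method", "passes_cutoff", "support_count", "validated"]
        )
        report = {
            "set_size_in_universe": len(genes_in_universe),
            "n_targeted_genes": 0,
            "n_pairs_below_cutoff": 0,
        }
        return report, pairs

    mirna_expr, gene_expr = align_samples(mirna_expr, gene_expr)
    sub_m = sorted(cand["mirna"].unique())
    sub_g = sorted(cand["gene"].unique())
    all_pairs = correlate_de_pairs(
        mirna_expr, gene_expr, sub_m, sub_g, method=cor_method, cutoff=pair_cutoff
    )
    pairs = cand.merge(all_pairs, on=["mirna", "gene"], how="left")
    pairs = pairs[["mirna", "gene", "r", "method", "passes_cutoff", "support_count", "validated"]]
    pairs = pairs.sort_values(["mirna", "gene"], kind="mergesort", ignore_index=True)
    n_below = int(pairs["passes_cutoff"].fillna(False).sum())
    report = {
        "set_size_in_universe": len(genes_in_universe),
        "n_targeted_genes": int(pairs["gene"].nunique()),
        "n_pairs_below_cutoff": n_below,
    }
    return report, pairs
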