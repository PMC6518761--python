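"""End-to-end orchestration of the two workflows.

``general_workflow`` runs the six-step analysis on in-memory objects:
optional normalization, differential expression on both matrices, optional
miRNA name conversion, all-pairs correlation of DE miRNAs against DE
genes, interaction-database intersection, and pathway enrichment (with a
permutation empirical p).  ``function_driven_workflow`` scores every gene
set genome-wide without DE pre-filtering, keeps the top k, and mines
in-set miRNA-gene pairs.

``run_general`` / ``run_function_driven`` wrap these with file IO driven
by a :class:`PipelineConfig`: they read the delimited inputs, execute, and
write every stage's table plus a run log and a machine-readable JSON
summary into the output directory.  All randomness (the permutation test)
derives from the single config seed through a fixed per-stage spawn key,
and tables are written with stable sorts, so a config reruns to a
byte-identical directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .datatypes import (
    AliasTable,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionDB,
    SampleGroups,
)
from .diff_expr import differential_test, passing_features
from .enrichment import add_empirical_p, enrich
from .errors import MirpairError
from .function_driven import in_set_pairs, score_gene_sets, top_sets
from .pair_analysis import (
    annotate_pairs,
    correlate_de_pairs,
    support_stratified_summary,
)
from .preprocess import convert_mirna_names, log2_transform, normalize, rename_features

logger = logging.getLogger(__name__)

_PERMUTATION_STAGE = 0  # spawn key for the permutation test's bit stream


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for one run.

    Defaults follow the published workflow: p threshold 0.05, |log2 ratio|
    threshold 0.5, correlation cutoff −0.5, 5000 permutations, in-set pair
    cutoff −0.3, top 5 sets.
    """

    mirna_path: str = ""
    gene_path: str = ""
    groups_path: str = ""
    db_path: str = ""
    gmt_paths: list = field(default_factory=list)
    alias_path: str | None = None
    out_dir: str = "mirpair_out"

    control_label: str = "control"
    delimiter: str = "\t"
    log2_input: bool = False          # apply log2(x+1) to raw intensities
    normalize_method: str = "none"    # none | quantile
    mirna_version: str | None = None  # convert miRNA names to this version

    de_method: str = "moderated_t"    # ttest | wilcoxon | moderated_t
    p_threshold: float = 0.05
    ratio_threshold: float = 0.5

    cor_method: str = "pearson"       # pearson | kendall | spearman
    cor_cutoff: float = -0.5
    min_support: int = 1
    keep_validated: bool = True       # validated pairs survive the support filter

    n_perm: int = 5000
    universe: str = "measured"        # measured | collection

    pair_cutoff: float = -0.3         # function-driven in-set pair cutoff
    top_k: int = 5
    min_set_size: int = 10

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise MirpairError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _stage_seed(seed: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(stage,))


def _load_inputs(config: PipelineConfig):
    mirna = mio.read_expression(config.mirna_path, config.delimiter)
    gene = mio.read_expression(config.gene_path, config.delimiter)
    groups = mio.read_sample_groups(config.groups_path, control=config.control_label,
                                    delimiter=config.delimiter)
    db = mio.read_interaction_db(config.db_path, delimiter=config.delimiter)
    sets = []
    for p in config.gmt_paths:
        sets.extend(list(mio.read_gmt(p)))
    collection = GeneSetCollection(sets)
    aliases = mio.read_alias_table(config.alias_path) if config.alias_path else None
    return mirna, gene, groups, db, collection, aliases


def _prepare(mirna, gene, config: PipelineConfig, aliases: AliasTable | None):
    if config.log2_input:
        mirna, gene = log2_transform(mirna), log2_transform(gene)
    mirna = normalize(mirna, config.normalize_method)
    gene = normalize(gene, config.normalize_method)
    if config.mirna_version is not None:
        if aliases is None:
            raise MirpairError("mirna_version set but no alias table given")
        mapping = convert_mirna_names(mirna.feature_ids, aliases, config.mirna_version)
        mirna = rename_features(mirna, mapping)
    return mirna, gene


def _universe(gene_expr: ExpressionMatrix, collection: GeneSetCollection, mode: str):
    if mode == "measured":
        return set(gene_expr.feature_ids) & set(collection.all_genes())
    if mode == "collection":
        return set(collection.all_genes())
    raise ValueError(f"unknown universe mode {mode!r}")


# ---------------------------------------------------------------------------
# general workflow (in memory)
# ---------------------------------------------------------------------------

def general_workflow(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    groups: SampleGroups,
    db: InteractionDB,
    collection: GeneSetCollection,
    config: PipelineConfig | None = None,
    aliases: AliasTable | None = None,
) -> dict:
    """Run the six-step general workflow on in-memory objects.

    Returns a dict of result tables: ``de_mirna``, ``de_gene``, ``pairs``
    (every computed pair, annotated), ``pairs_kept`` (passing the
    correlation cutoff and the database filter), ``support_summary``,
    ``enrichment``, and a ``summary`` dict of headline counts.
    """
    config = config or PipelineConfig()
    mirna_expr, gene_expr = _prepare(mirna_expr, gene_expr, config, aliases)

    de_mirna = differential_test(
        mirna_expr, groups, config.de_method, config.p_threshold, config.ratio_threshold
    )
    de_gene = differential_test(
        gene_expr, groups, config.de_method, config.p_threshold, config.ratio_threshold
    )
    de_mirna_ids = passing_features(de_mirna)
    de_gene_ids = passing_features(de_gene)

    pairs = correlate_de_pairs(
        mirna_expr, gene_expr, de_mirna_ids, de_gene_ids,
        method=config.cor_method, cutoff=config.cor_cutoff,
    )
    pairs = db.lookup(pairs)
    kept = annotate_pairs(
        pairs[pairs["passes_cutoff"]], db,
        min_support=config.min_support, require_validated=config.keep_validated,
    )
    summary_table = support_stratified_summary(pairs)

    universe = _universe(gene_expr, collection, config.universe)
    query = sorted(set(kept["gene"]) & universe)
    if universe and len(collection):
        enrichment = enrich(query, collection, universe)
        if len(enrichment) and query:
            enrichment = add_empirical_p(
                enrichment, collection, universe, len(query),
                n_perm=config.n_perm,
                seed=_stage_seed(config.seed, _PERMUTATION_STAGE),
            )
    else:
        enrichment = enrich(query, collection, universe) if universe else pd.DataFrame()

    summary = {
        "n_mirnas_tested": int(len(de_mirna)),
        "n_genes_tested": int(len(de_gene)),
        "n_de_mirnas": len(de_mirna_ids),
        "n_de_genes": len(de_gene_ids),
        "n_pairs_computed": int(len(pairs)),
        "n_pairs_passing_cutoff": int(pairs["passes_cutoff"].sum()) if len(pairs) else 0,
        "n_pairs_kept": int(len(kept)),
        "n_query_genes": len(query),
        "universe_size": len(universe),
        "n_sets_tested": int(len(enrichment)),
    }
    return {
        "de_mirna": de_mirna,
        "de_gene": de_gene,
        "pairs": pairs,
        "pairs_kept": kept,
        "support_summary": summary_table,
        "enrichment": enrichment,
        "summary": summary,
    }


# ---------------------------------------------------------------------------
# function-driven workflow (in memory)
# ---------------------------------------------------------------------------

def function_driven_workflow(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    groups: SampleGroups,
    db: InteractionDB,
    collection: GeneSetCollection,
    config: PipelineConfig | None = None,
    aliases: AliasTable | None = None,
) -> dict:
    """Score all sets genome-wide, keep the top k, and mine in-set pairs."""
    config = config or PipelineConfig()
    if config.top_k < 1:
        raise ValueError("top_k must be >= 1")
    mirna_expr, gene_expr = _prepare(mirna_expr, gene_expr, config, aliases)

    scores = score_gene_sets(gene_expr, groups, collection, config.min_set_size)
    selected = top_sets(scores, config.top_k)

    de_mirna = differential_test(
        mirna_expr, groups, config.de_method, config.p_threshold, config.ratio_threshold
    )
    de_mirna_ids = passing_features(de_mirna)

    report_rows = []
    set_pair_tables = {}
    for _, row in selected.iterrows():
        gene_set = collection[row["set_name"]]
        report, set_pairs = in_set_pairs(
            gene_set.genes, mirna_expr, gene_expr, de_mirna_ids, db,
            cor_method=config.cor_method, pair_cutoff=config.pair_cutoff,
        )
        report_rows.append(
            {
                "set_name": row["set_name"],
                "category": row["category"],
                "direction": row["direction"],
                "p": row["p"],
                **report,
            }
        )
        set_pair_tables[row["set_name"]] = set_pairs
    report = pd.DataFrame(
        report_rows,
        columns=["set_name", "category", "direction", "p", "set_size_in_universe",
                 "n_targeted_genes", "n_pairs_below_cutoff"],
    )
    return {
        "scores": scores,
        "top_sets": selected,
        "report": report,
        "set_pairs": set_pair_tables,
        "de_mirna": de_mirna,
        "summary": {
            "n_sets_scored": int(scores["set_name"].nunique()) if len(scores) else 0,
            "n_de_mirnas": len(de_mirna_ids),
            "top_sets": report["set_name"].tolist(),
        },
    }


# ---------------------------------------------------------------------------
# file-level entry points
# ---------------------------------------------------------------------------

def _write_common(out: Path, config: PipelineConfig, tables: dict, summary: dict, workflow: str):
    out.mkdir(parents=True, exist_ok=True)
    for name, (table, sort_by) in tables.items():
        mio.write_table(table, out / f"{name}.tsv", sort_by=sort_by)
    with open(out / "run_summary.json", "w") as fh:
        json.dump({"workflow": workflow, "summary": summary,
                   "parameters": asdict(config)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"mirpair {workflow} workflow\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write("parameters (including defaults applied implicitly):\n")
        for key, value in sorted(asdict(config).items()):
            fh.write(f"  {key} = {value!r}\n")
        for key, value in sorted(summary.items()):
            fh.write(f"result {key}: {value}\n")


def run_general(config: PipelineConfig) -> Path:
    """File-level general workflow; returns the output directory."""
    mirna, gene, groups, db, collection, aliases = _load_inputs(config)
    results = general_workflow(mirna, gene, groups, db, collection, config, aliases)
    out = Path(config.out_dir)
    tables = {
        "de_mirna": (results["de_mirna"].reset_index(), "feature_id"),
        "de_gene": (results["de_gene"].reset_index(), "feature_id"),
        "pairs": (results["pairs"], ["mirna", "gene"]),
        "pairs_kept": (results["pairs_kept"], ["mirna", "gene"]),
        "support_summary": (results["support_summary"], None),
        "enrichment": (results["enrichment"], None),
    }
    _write_common(out, config, tables, results["summary"], "general")
    logger.info("general workflow finished: %s", results["summary"])
    return out


def run_function_driven(config: PipelineConfig) -> Path:
    """File-level function-driven workflow; returns the output directory."""
    mirna, gene, groups, db, collection, aliases = _load_inputs(config)
    results = function_driven_workflow(mirna, gene, groups, db, collection, config, aliases)
    out = Path(config.out_dir)
    tables = {
        "set_scores": (results["scores"], None),
        "fdriven_report": (results["report"], None),
        "de_mirna": (results["de_mirna"].reset_index(), "feature_id"),
    }
    for set_name, set_pairs in results["set_pairs"].items():
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in set_name)
        tables[f"pairs_{safe}"] = (set_pairs, ["mirna", "gene"])
    _write_common(out, config, tables, results["summary"], "function_driven")
    logger.info("function-driven workflow finished: %s", results["summary"])
    return out
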