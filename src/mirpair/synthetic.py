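"""Synthetic paired miRNA/gene expression with planted repressive interactions.

The generator emulates a two-phenotype microarray study with matched miRNA
and mRNA profiles on the log2 scale.  Its variance structure is
hierarchical, as in real array data: each feature draws a baseline level
from N(8, 1) (spread between features), and each measurement adds
independent per-sample noise (sd 0.3 by default, spread within a feature).

Planted structure:

* ``n_de_mirnas`` miRNAs gain ``mirna_group_effect`` log2 units in cases.
* ``n_planted_pairs`` repressive interactions are planted on the DE
  miRNAs (round-robin, one distinct target gene each):
  x_gene = 16 - beta * x_mirna + N(0, gene_noise_sd), the simplest
  mechanism producing the negative miRNA-target correlation the pipeline
  is built to detect.  Because their miRNAs shift, planted targets are
  themselves differentially expressed (by -beta * effect).
* ``n_de_genes`` further genes (disjoint from the planted targets) gain
  ``gene_group_effect`` log2 units in cases; they form the "shifted" gene
  set used to exercise the function-driven workflow.
* The interaction database holds every planted pair (prediction support
  drawn uniformly from 3..n_sources, 30% experimentally validated) plus an
  equal number of decoy pairs (support 1-2, never validated, never
  planted), so support-stratified summaries are enriched for true
  anti-correlation in the high-support strata by construction.
* The gene-set collection holds random sets, plus (optionally) one set
  packed with planted target genes and one set equal to the shifted genes.
* The alias table gives 10% of miRNAs a distinct old-version name.

Everything is drawn from a single seeded generator, so a config (including
its seed) reproduces the bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AliasTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionDB,
    SampleGroups,
)
from . import io as mio

SOURCE_NAMES = (
    "targetscan", "eimmo", "rna22", "miranda", "microcosm", "pita", "microt", "mirdb",
)

ENRICHED_SET = "SET_PLANTED_TARGETS"
SHIFTED_SET = "SET_SHIFTED_GENES"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle (all expression in log2 units)."""

    n_genes: int = 500
    n_mirnas: int = 60
    n_per_group: int = 15
    n_planted_pairs: int = 50
    repression_strength: float = 0.9   # beta in x_g = 16 - beta * x_m + eps
    gene_noise_sd: float = 0.3
    mirna_noise_sd: float = 0.3
    n_de_mirnas: int = 20
    mirna_group_effect: float = 1.0
    n_de_genes: int = 30
    gene_group_effect: float = 1.0
    n_gene_sets: int = 25
    genes_per_set: int = 30
    planted_enriched_set: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_de_mirnas > self.n_mirnas:
            raise ValueError("n_de_mirnas cannot exceed n_mirnas")
        if self.n_planted_pairs + self.n_de_genes > self.n_genes:
            raise ValueError("planted targets plus DE genes exceed n_genes")
        if self.n_planted_pairs > 0 and self.n_de_mirnas == 0:
            raise ValueError("planted pairs require at least one DE miRNA")
        if self.genes_per_set > self.n_genes:
            raise ValueError("genes_per_set cannot exceed n_genes")
        for name in ("n_genes", "n_mirnas", "n_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthTables:
    """Ground truth emitted alongside a simulated bundle."""

    planted_pairs: list          # [(mirna, gene), ...]
    de_mirnas: list
    de_genes: list               # planted targets (of DE miRNAs) + shifted genes
    enriched_set: str | None     # set packed with planted targets
    shifted_set: str | None      # set of genes with a +effect group shift


@dataclass
class SimulatedBundle:
    mirna_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    groups: SampleGroups
    db: InteractionDB
    collection: GeneSetCollection
    aliases: AliasTable
    truth: TruthTables
    config: SimulationConfig = field(repr=False)


def _mirna_name(i: int) -> str:
    return f"hsa-miR-{i + 1:03d}-5p"


def _gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Draw one fully reproducible bundle under ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = 2 * config.n_per_group
    sample_ids = [f"ctrl{i + 1:02d}" for i in range(config.n_per_group)] + [
        f"case{i + 1:02d}" for i in range(config.n_per_group)
    ]
    case_mask = np.array([0] * config.n_per_group + [1] * config.n_per_group, dtype=float)
    groups = SampleGroups(
        assignment={s: ("control" if s.startswith("ctrl") else "case") for s in sample_ids},
        control="control",
    )
    mirna_ids = [_mirna_name(i) for i in range(config.n_mirnas)]
    gene_ids = [_gene_name(i) for i in range(config.n_genes)]

    # --- miRNA matrix -----------------------------------------------------
    de_mirna_idx = rng.choice(config.n_mirnas, size=config.n_de_mirnas, replace=False)
    mirna_base = rng.normal(8.0, 1.0, size=config.n_mirnas)
    mirna_vals = (
        mirna_base[:, None]
        + rng.normal(0.0, config.mirna_noise_sd, size=(config.n_mirnas, n_samples))
    )
    mirna_vals[de_mirna_idx] += config.mirna_group_effect * case_mask[None, :]
    de_mirnas = [mirna_ids[i] for i in sorted(de_mirna_idx)]

    # --- planted pairs: targets of DE miRNAs, round-robin -----------------
    gene_perm = rng.permutation(config.n_genes)
    target_idx = gene_perm[: config.n_planted_pairs]
    shifted_idx = gene_perm[config.n_planted_pairs: config.n_planted_pairs + config.n_de_genes]
    hosts = [sorted(de_mirna_idx)[i % config.n_de_mirnas] for i in range(config.n_planted_pairs)]
    planted_pairs = [
        (mirna_ids[m], gene_ids[g]) for m, g in zip(hosts, target_idx)
    ]

    # --- gene matrix ------------------------------------------------------
    gene_base = rng.normal(8.0, 1.0, size=config.n_genes)
    gene_vals = (
        gene_base[:, None]
        + rng.normal(0.0, config.gene_noise_sd, size=(config.n_genes, n_samples))
    )
    gene_vals[shifted_idx] += config.gene_group_effect * case_mask[None, :]
    for m_idx, g_idx in zip(hosts, target_idx):
        gene_vals[g_idx] = (
            16.0
            - config.repression_strength * mirna_vals[m_idx]
            + rng.normal(0.0, config.gene_noise_sd, size=n_samples)
        )

    mirna_expr = ExpressionMatrix(pd.DataFrame(mirna_vals, index=mirna_ids, columns=sample_ids))
    gene_expr = ExpressionMatrix(pd.DataFrame(gene_vals, index=gene_ids, columns=sample_ids))

    # --- interaction database --------------------------------------------
    n_sources = len(SOURCE_NAMES)
    records = []
    for mirna, gene in planted_pairs:
        support = rng.integers(3, n_sources + 1)
        flags = np.zeros(n_sources, dtype=bool)
        flags[rng.choice(n_sources, size=support, replace=False)] = True
        records.append((mirna, gene, flags, bool(rng.random() < 0.3)))
    planted_set = set(planted_pairs)
    n_decoys = 0
    while n_decoys < config.n_planted_pairs:
        m = mirna_ids[rng.integers(config.n_mirnas)]
        g = gene_ids[rng.integers(config.n_genes)]
        if (m, g) in planted_set:
            continue
        planted_set.add((m, g))  # avoid duplicate decoys too
        support = rng.integers(1, 3)
        flags = np.zeros(n_sources, dtype=bool)
        flags[rng.choice(n_sources, size=support, replace=False)] = True
        records.append((m, g, flags, False))
        n_decoys += 1
    db_frame = pd.DataFrame(
        {
            "mirna": [r[0] for r in records],
            "gene": [r[1] for r in records],
            **{
                src: [bool(r[2][j]) for r in records]
                for j, src in enumerate(SOURCE_NAMES)
            },
            "validated": [r[3] for r in records],
        }
    )
    db = InteractionDB(db_frame, list(SOURCE_NAMES))

    # --- gene sets --------------------------------------------------------
    sets = []
    n_random = config.n_gene_sets - (2 if config.planted_enriched_set else 0)
    for s in range(max(n_random, 0)):
        members = rng.choice(config.n_genes, size=config.genes_per_set, replace=False)
        sets.append(
            GeneSet(
                name=f"SET_RANDOM_{s + 1:02d}",
                category="KEGG" if s % 2 == 0 else "Reactome",
                genes=frozenset(gene_ids[i] for i in members),
            )
        )
    truth_enriched = truth_shifted = None
    if config.planted_enriched_set:
        packed = [g for _, g in planted_pairs][: config.genes_per_set]
        if len(packed) < config.genes_per_set:  # pad with random non-target genes
            pool = [g for g in gene_ids if g not in set(packed)]
            extra = rng.choice(len(pool), size=config.genes_per_set - len(packed), replace=False)
            packed += [pool[i] for i in extra]
        sets.append(GeneSet(name=ENRICHED_SET, category="KEGG", genes=frozenset(packed)))
        truth_enriched = ENRICHED_SET
        if len(shifted_idx):
            sets.append(
                GeneSet(
                    name=SHIFTED_SET,
                    category="Reactome",
                    genes=frozenset(gene_ids[i] for i in shifted_idx),
                )
            )
            truth_shifted = SHIFTED_SET
    collection = GeneSetCollection(sets)

    # --- alias table ------------------------------------------------------
    n_renamed = max(1, config.n_mirnas // 10)
    renamed = set(rng.choice(config.n_mirnas, size=n_renamed, replace=False).tolist())
    alias_frame = pd.DataFrame(
        {
            "accession": [f"MIMAT{i + 1:07d}" for i in range(config.n_mirnas)],
            "v17": [
                mirna_ids[i].removesuffix("-5p") if i in renamed else mirna_ids[i]
                for i in range(config.n_mirnas)
            ],
            "v21": mirna_ids,
        }
    )
    aliases = AliasTable(alias_frame)

    planted_targets = [gene_ids[i] for i in target_idx]
    de_genes = sorted(planted_targets + [gene_ids[i] for i in shifted_idx])
    truth = TruthTables(
        planted_pairs=planted_pairs,
        de_mirnas=de_mirnas,
        de_genes=de_genes,
        enriched_set=truth_enriched,
        shifted_set=truth_shifted,
    )
    return SimulatedBundle(
        mirna_expr=mirna_expr,
        gene_expr=gene_expr,
        groups=groups,
        db=db,
        collection=collection,
        aliases=aliases,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture directories
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "mirna": "mirna_expression.tsv",
    "gene": "gene_expression.tsv",
    "groups": "sample_groups.tsv",
    "db": "interactions.tsv",
    "gmt": "gene_sets.gmt",
    "aliases": "mirna_aliases.tsv",
    "truth": "truth.yaml",
    "manifest": "manifest.yaml",
}


def write_fixture(bundle: SimulatedBundle, directory) -> Path:
    """Write all seven artifacts plus a manifest recording config and seed."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_expression(bundle.mirna_expr, out / FIXTURE_FILES["mirna"])
    mio.write_expression(bundle.gene_expr, out / FIXTURE_FILES["gene"])
    mio.write_sample_groups(bundle.groups, out / FIXTURE_FILES["groups"])
    mio.write_interaction_db(bundle.db, out / FIXTURE_FILES["db"])
    mio.write_gmt(bundle.collection, out / FIXTURE_FILES["gmt"])
    mio.write_alias_table(bundle.aliases, out / FIXTURE_FILES["aliases"])
    with open(out / FIXTURE_FILES["truth"], "w") as fh:
        yaml.safe_dump(
            {
                "planted_pairs": [list(p) for p in bundle.truth.planted_pairs],
                "de_mirnas": bundle.truth.de_mirnas,
                "de_genes": bundle.truth.de_genes,
                "enriched_set": bundle.truth.enriched_set,
                "shifted_set": bundle.truth.shifted_set,
            },
            fh,
            sort_keys=True,
        )
    with open(out / FIXTURE_FILES["manifest"], "w") as fh:
        yaml.safe_dump({"simulation_config": asdict(bundle.config)}, fh, sort_keys=True)
    return out


def load_manifest(path) -> SimulationConfig:
    """Reconstruct the simulation config from a fixture manifest."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return SimulationConfig(**payload["simulation_config"])


def read_fixture(directory) -> SimulatedBundle:
    """Load a fixture directory back into in-memory objects (via the manifest truth)."""
    d = Path(directory)
    config = load_manifest(d / FIXTURE_FILES["manifest"])
    with open(d / FIXTURE_FILES["truth"]) as fh:
        t = yaml.safe_load(fh)
    truth = TruthTables(
        planted_pairs=[tuple(p) for p in t["planted_pairs"]],
        de_mirnas=t["de_mirnas"],
        de_genes=t["de_genes"],
        enriched_set=t["enriched_set"],
        shifted_set=t["shifted_set"],
    )
    return SimulatedBundle(
        mirna_expr=mio.read_expression(d / FIXTURE_FILES["mirna"]),
        gene_expr=mio.read_expression(d / FIXTURE_FILES["gene"]),
        groups=mio.read_sample_groups(d / FIXTURE_FILES["groups"], control="control"),
        db=mio.read_interaction_db(d / FIXTURE_FILES["db"]),
        collection=mio.read_gmt(d / FIXTURE_FILES["gmt"]),
        aliases=mio.read_alias_table(d / FIXTURE_FILES["aliases"]),
        truth=truth,
        config=config,
    )
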