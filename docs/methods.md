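# Methods notes

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the design decisions taken where the design was
genuinely open, what the synthetic generator does and does not emulate,
and the package's known limitations.

## Data model and conventions

All expression values are assumed log2-scale (a `log2_input` flag applies
log2(x+1) to raw intensities). Identifiers are case-sensitive and
whitespace-stripped; gene symbols are never aliased, and only miRNAs pass
through the accession-keyed name-version conversion. Files are plain
delimited text (tab default, comma supported); the interaction database
declares its prediction sources in a `#sources=` manifest line and
duplicate (miRNA, gene) rows are merged by logical OR of every flag, which
makes reading idempotent and order-independent. Flat files were preferred
over a relational backend: at the scale of one study they are fully
reproducible, diffable, and need no installation.

## Normalization

Only quantile normalization is offered. It is the one array-level method
with a crisp definition — every sample's sorted values are replaced by the
across-sample mean of order statistics — and is therefore exactly
testable (idempotence, identical column distributions). Ties receive the
average of the reference values their ranks span, so equal inputs map to
equal outputs. Background correction, batch effects and probe
summarization are considered upstream concerns.

## Differential expression

Two-group tests per feature, each two-sided:

* **Welch t** (unequal variances). Welch is the default over the pooled
  t because it is safer under variance heterogeneity and loses almost
  nothing when variances are equal (it reduces to the pooled t for equal
  group sizes and equal sample variances, which the tests verify).
* **Wilcoxon rank-sum**: exact null distribution when both groups are
  tie-free and no larger than 25, otherwise the normal approximation with
  midranks, tie-corrected variance and continuity correction.
* **Moderated t**: empirical-Bayes variance shrinkage. Per-feature
  residual variances s²_g (d_g df) are assumed to follow a scaled
  inverse-chi-square prior (d₀, s₀²) fitted by moment-matching the
  distribution of log s²_g: with
  e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over its
  sampling component ψ′(d_g/2) identifies ψ′(d₀/2) (inverted by Newton
  iteration on the trigamma function), and the mean identifies s₀².
  The posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) enters a
  t statistic on d₀ + d_g df. When the observed spread of log-variances
  is no larger than its sampling noise the prior df is infinite and the
  prior variance is the mean sample variance, so the statistic collapses
  to the ordinary pooled t — the correct degenerate behaviour. The
  implementation agrees with Bioconductor limma's `eBayes` to ~1e-15 on a
  shared fixture (cross-checked via Rscript in the test suite).

A negative-binomial count model (the `deseq2` method name) is recognised
but refused with an explanatory error: these tests act on log-scale
continuous intensities, and a faithful count framework is out of scope.

A feature passes at raw p < 0.05 **and** |log2 ratio| ≥ 0.5 (case mean −
control mean). "Expression ratio 0.5" is interpreted as a log2-scale mean
difference — the only reading consistent with microarray conventions.
The threshold applies to both matrices; BH adjustment is applied within
each matrix (miRNAs and genes are different platforms and are corrected
separately), and q-values are reported alongside raw p. Features with
zero variance in both groups are flagged and given p = 1 rather than
raising, so one flat probe cannot abort a run.

## Pair correlation and database intersection

Correlations are computed over **all** samples, cases and controls pooled
(configurable). Pooling maximises n and captures the between-group
component of a repressive relationship; its cost is that any pair of
features responding to the phenotype in opposite directions correlates
negatively, which is exactly why the database intersection follows. All
|DE miRNAs| × |DE genes| combinations are scored; r ≤ −0.5 (moderate
anti-correlation) passes. Pearson and Spearman are computed by vectorised
matrix products (Spearman as Pearson on midranks); Kendall τ-b per pair.
Zero-variance vectors give an undefined correlation: the pair is reported
with r = NaN, flagged, and excluded from every downstream count.

Database annotation gives each pair its support count (number of
prediction sources) and validated flag; absent pairs get 0/False. The
default filter keeps pairs with support ≥ 1, and the pipeline by default
also keeps validated pairs unconditionally — experimental evidence is
treated as at least as strong as any prediction consensus. No correlation
p-values are computed: filtering is on the coefficient only, so the
support evidence, not a sample-size-driven p, carries the specificity.

The support-stratified summary reports, for each correlation threshold,
the count and proportion of anti-correlated pairs within the support = 0
stratum and within each support ≥ s stratum — the standard way to show
that prediction consensus enriches for genuine repression.

## Enrichment

The query is the set of target genes from pairs that survived both the
correlation cutoff and the database filter. The universe defaults to the
genes that are both measured and present in at least one collection set
("measured"); a pure-collection universe is available. The measured
universe is the defensible choice because unmeasured genes could never
have entered the query.

The hypergeometric upper tail P(X ≥ k) is summed exactly in log space
(log-gamma binomial coefficients + log-sum-exp), keeping p-values
accurate down to the smallest representable magnitudes; it matches
exhaustive subset enumeration to 1e-12 for all N ≤ 12 and
`scipy.stats.hypergeom.sf` to 1e-10 relative elsewhere. BH is applied to
the hypergeometric p-values across the tested sets of a run.

The permutation empirical p resamples the **query** at its observed size
(uniformly from the universe, without replacement) and recomputes each
pathway's hypergeometric p per draw; under exchangeability this is
algebraically the same null as resampling the pathway at fixed query, and
the query is the data-derived object, so it is the natural thing to
perturb. The add-one estimate p_emp = (b+1)/(B+1) avoids zero p-values
and gives resolution 1/5001 ≈ 0.0002 at the default B = 5000. One shared
stream of draws serves all pathways of a run (common random numbers), and
a dedicated per-pathway entry point exists for single sets. Note the
empirical p inherits the discreteness of the hypergeometric: it is valid
(never anti-conservative in expectation) at any size, but its
distribution under a null query only approaches uniform once the null
support is fine-grained (large set and query relative to the universe);
the calibration tests use such a configuration. Empirical p-values are
reported unadjusted, alongside the BH-adjusted hypergeometric ones.

## Function-driven gene-set scoring

For control samples c = 1..n₀ and test samples j = 1..m, define per-gene
fold changes f_gj = x_gj − mean_c(x_gc). For a set S and test sample j,
a two-sample Welch t compares {f_gj : g ∈ S} with {f_gj : all measured g},
and is mapped through its t CDF to a standard-normal score z_j (computed
from the tail to preserve accuracy at extreme values). The per-sample
scores are combined as

    Z = Σ z_j / sqrt(m · (1 + (m − 1)·ρ)),   ρ = 1/(n₀ + 1).

The correction term is deliberate: every test sample's fold changes share
the same estimated control mean per gene, which makes the z_j
equicorrelated with ρ = 1/(n₀+1); the plain Stouffer denominator sqrt(m)
would overstate the evidence by a factor ≈ sqrt(1 + (m−1)ρ) (≈ 1.37 at
15+15) and break null calibration. With the correction, one-sided p-values
from the normal tails are approximately uniform for random sets on null
data (verified by a KS test in the suite). Because every set shares m,
the correction is a monotone rescaling and never changes set rankings.
Both directions (up/down) are reported; `top_sets` keeps each set once,
under its better direction, with lexicographic tie-breaking for
determinism. Sets with fewer than 10 measured genes are skipped to avoid
degenerate t statistics.

This statistic is a deliberately simple, fully-specified, calibration-
tested set score; it is not intended to reproduce any external gene-set
package's p-values byte for byte. No per-gene DE filter enters the
scoring — genes contribute regardless of individual significance — which
is the point of the function-driven route: moderate coordinated shifts
count. The in-set pair step then uses DE miRNAs (the miRNA side *is*
filtered, mirroring the asymmetric design) against all measured set genes
present in the interaction database, at the looser cutoff r ≤ −0.3
appropriate for unfiltered genes.

## Synthetic data generator

The generator emulates a paired two-group microarray study:

* hierarchical variance structure — feature baselines ~ N(8, 1) (log2
  units, between-feature spread) plus i.i.d. per-sample measurement noise
  (sd 0.3 for both miRNAs and genes). This mirrors real arrays, where
  between-feature spread far exceeds within-feature noise; it is also what
  gives two-group effects of 1.0 log2 units essentially full power at
  15 + 15 samples, so recovery failures indicate real defects rather than
  designed-in underpower.
* 20 of 60 miRNAs gain +1.0 log2 in cases; 50 repressive pairs are
  planted on these DE miRNAs (round-robin, one distinct target gene
  each): x_g = 16 − 0.9·x_m + N(0, 0.3). Linear repression on the log2
  scale is the simplest mechanism consistent with the anti-correlation
  assumption being tested; planted targets are thereby also
  differentially expressed (−0.9 log2). Pairs are planted on DE miRNAs
  because the general workflow can only ever examine DE miRNAs — pairs
  hosted elsewhere would be undetectable by design, not by defect.
* 30 further genes gain +1.0 log2 in cases and form the "shifted" set the
  function-driven workflow should rank first; a second special set is
  packed with planted target genes for the enrichment check; the
  remaining 23 sets are random 30-gene draws.
* the interaction database holds all 50 planted pairs (support drawn
  uniformly from 3–8 of 8 sources, 30% validated) plus 50 uniform random
  decoy pairs (support 1–2, never validated), so support-stratified
  summaries show the true-pair enrichment trend by construction.
* an alias table gives 10% of miRNAs an old-version name (arm suffix
  stripped), exercising name conversion.

What it does **not** emulate: sequence features (no seed matches, no
3'UTRs), count noise (no RNA-seq dispersion), batch effects, correlated
gene modules beyond the planted structure, or miRNAs targeting multiple
genes with shared targets. Passing the recovery tests therefore shows the
pipeline's logic and statistics are sound under its stated model — not
that any particular biological dataset will yield comparable recall.

All draws come from a single `numpy` generator seeded by the config, so a
manifest (config + seed) regenerates a fixture directory byte for byte.

## Determinism and numerical choices

* One config seed governs all stochastic stages; the permutation test
  draws its stream from `SeedSequence(seed, spawn_key=(stage,))`, so
  stages are individually reproducible.
* Output tables are stably sorted on declared keys and floats rendered
  with a fixed 12-significant-digit format; identical config + seed
  reruns produce byte-identical output directories (asserted in the
  suite). Logs contain parameters and results, never timestamps.
* Ties: midranks everywhere (Wilcoxon, Spearman, quantile reference
  assignment); sorting ties break lexicographically by name.
* Degenerate inputs: constant features → p = 1 with a flag; zero-variance
  correlation vectors → NaN r, excluded from cutoff passing; sets without
  measured genes are skipped; an empty DE list yields empty-but-valid
  downstream tables and a successful exit.
* Test problem sizes (e.g. 2000 null features, 50 generator seeds,
  B = 500–5000 permutations) were chosen so each check has clear
  statistical resolution while the whole suite stays quick on one CPU.

## Limitations

* Two groups only; no paired designs, covariates, or multi-group layouts.
* No count-model differential test (log-transformed counts work
  acceptably through the continuous tests but lose count-specific power).
* Correlation filtering ignores indirect co-regulation; the database
  intersection mitigates but cannot eliminate it.
* Gene sets are flat lists; no ontology topology or overlap correction
  between sets.
* The function-driven score assumes approximately exchangeable genes
  within the background; strong inter-gene correlation inflates its
  evidence like any parametric set statistic.
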