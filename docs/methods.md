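# Methods

`microcore` derives a species "core microglia profile" from bulk RNA-seq of
sorted microglia and unsorted (total) CNS tissue, intersects such profiles
across species, and summarizes their functional annotation by collapsing
enriched GO terms onto a coarse reference layer. This note documents the
procedure, its assumptions, the defaults, and what the synthetic study does
and does not establish.

## The profile-derivation procedure

Cohorts profiled with different library protocols cannot be compared on raw
abundance. The pipeline therefore works on rank statistics:

1. **TPM.** Counts are normalized within sample to transcripts per million
   using exon-union gene lengths: `rate_g = count_g / length_kb_g`,
   `tpm_g = 1e6 · rate_g / Σ rate`. Columns sum to 1e6 over the genes that
   have a length annotation; genes without one are dropped with a warning
   rather than failing, because partial length annotations are the norm.
2. **Percentile ranks.** Per cohort, gene means are reduced to empirical
   percentiles `p = 100 · rank / (G − 1)` with rank 0 for the most abundant
   gene, so `p ∈ [0, 100]` and *smaller is more abundant*. Ties share the
   average of their descending ranks, which guarantees Δ = 0 for genes tied
   in both cohorts. Zero-expression genes stay in the ranking (they tie at
   the bottom); dropping them would shift every other percentile.
3. **Δ percentile.** For two cohorts, `Δ(g) = |p_A(g) − p_B(g)|` over the
   shared genes. Two unrelated rankings give E[Δ] → 100/3 and median
   Δ → 100(1 − 1/√2) ≈ 29.3, so medians well below that indicate rank
   concordance. The concordance filter keeps genes with Δ < 20.
4. **Top decile.** Genes with `p < 10` in a cohort are its "highest
   expressed" set. The strict `<` is configurable. Candidate marker genes
   are (top decile of microglia cohort 1 ∖ top decile of tissue) ∩ (same
   for cohort 2), plus the cohort-2-only remainder — i.e. highly expressed
   in sorted cells but not explained by overall tissue abundance.
5. **Specificity fraction.** Each gene's mean TPM across the three groups
   (tissue, microglia-1, microglia-2) is rescaled to percentages summing to
   100 (the ternary-plot coordinates). A gene is microglia-specific when
   the two microglia percentages together exceed 60 (strict). The two
   microglia axes are treated jointly against tissue.
6. **Profile assembly.** Candidates = DE-enriched ∪ shared-top ∪
   c2-only-top; retained = candidates with Δ < 20 **and** microglia
   fraction > 60. Union-then-filter: both filters re-apply to DE genes as
   well, since the thresholds define the profile as a whole. Per-gene
   provenance flags and per-filter attrition counts are kept so the
   reduction from candidates to profile is inspectable.

Species with a single sorted cohort cannot support the Δ/triangle
machinery; they contribute their DE-enriched gene list at the same
thresholds, which is how external comparison species enter the analysis.

## Differential enrichment

The thresholds — FDR < 0.001 and log2FC > 3, both strict — are the
interface; the estimator behind them is pluggable. The built-in stage:

- **Normalization** uses median-of-ratios size factors (per sample, the
  median over everywhere-positive genes of count / geometric-mean count).
  Total-count scaling is not an option here: when a sizeable tier of genes
  is strongly enriched in the sorted population, it inflates the sorted
  libraries and biases every fold change downward; the median over genes is
  robust to such a minority shift.
- **Test**: two-sample t on `log2(normalized count + 0.5)` with the pooled
  per-gene variance shrunk toward an empirical-Bayes prior. The prior
  (d₀, s₀²) is fitted by the moment method on log variances
  (digamma/trigamma matching); moderated variance
  `s²_mod = (d₀s₀² + df·s²)/(d₀ + df)` with d₀ + df degrees of freedom.
  At typical replicate numbers (n ≈ 5 per group) an unmoderated per-gene
  test is dominated by noise in the variance estimate; moderation restores
  power the way variance-shrinkage DE tools do. `moderate=False` gives a
  plain Welch test.
- **Multiplicity**: Benjamini–Hochberg over tested genes. Genes with zero
  counts in every sample of both groups are "not expressed": excluded
  before testing and reported as untested rather than given fabricated
  statistics.
- log2FC uses group means of normalized counts with pseudocount 0.5; this
  shrinks fold changes of very low-expressed genes toward zero, a known and
  accepted bias of pseudocount estimators.

An external DE table (any tool) can replace this stage via
`read_de_table`; column names are alias-matched case-insensitively.

## Cross-species intersection

Profiles are compared in shared-symbol space through an ortholog map
(per species a one-to-one gene↔symbol aliasing; exact, case-sensitive
matching). Genes without a map entry — ORF-like or species-private
identifiers — are excluded from the counts but reported per species, since
apparent non-conservation driven by annotation gaps should stay visible.
From the per-symbol species-membership sets the pipeline derives all
pairwise overlaps, the **lenient subset** (present in ≥ k species, default
3 of 4) and the **preserved core** (present in all). By construction
core ⊆ lenient ⊆ union and core ⊆ every pairwise overlap. Overlap with an
external tiered signature (high/intermediate/low) is reported as counts
and percentages per tier plus the unassigned remainder.

## GO enrichment and parent-collapse

Enrichment is the upper hypergeometric tail P(X ≥ k) for k hits among n
query genes, K annotated background genes, N background genes, with BH
adjustment across tested terms; terms pass at p < 0.05 and q < 0.1 (both
strict). Direct annotations propagate to all `is_a` ancestors for testing
(standard practice; the root is excluded as it annotates everything).

The collapse step re-annotates each enriched term to a **reference term**:
the terms within two `is_a` steps of the root. A term already in the
reference layer maps to itself; otherwise its ancestry is walked upward
breadth-first and the first level containing a reference term wins. Ties
within a level break by larger annotated-background size (the more general
term), then lexicographically smallest id — deterministic and documented,
since the procedure itself does not dictate a choice. Terms whose nearest
reference ancestor lies deeper than two steps are still collapsed but
flagged `deep`. Unique-gene counts per reference term are unions of the
contributing terms' *direct* hit lists (propagation off there, switchable),
so gene membership is conserved under collapse. The circos export lists
(species, reference term, unique genes, width), widths summing to 1 per
species.

## Synthetic study

The generator emulates the statistical shape of the emulated study design,
not its biology:

- **Counts**: negative binomial with Var = m + αm², dispersion α = 0.1,
  gene base means log-normal (ln-mean 4, ln-sd 1.5) — a realistic bulk
  RNA-seq mean–variance profile at desk scale. Four species
  (macaque, human, mouse, zebrafish), 2,000 genes, 5 samples per cohort.
  The focal species (macaque) has tissue + two sorted cohorts; the others
  tissue + one.
- **Planted markers**: multiplied by 16 in the microglia cohorts of the
  species they are planted in. Tiers: 54 symbols in all four species, 167
  in exactly three, 60 in two, 80 private — the 54/221 structure mirrors
  the size relationships a cross-species core/lenient split exhibits, as a
  recognizable default, not an assertion about real data.
- **Orthologs**: 5% of null genes per species receive no map entry,
  emulating unannotated/ORF transcripts.
- **Ontology/annotations**: a rooted 4-level DAG with six branches; levels
  1–2 are the reference layer. Planted symbols are annotated to leaves of
  the immune branch, nulls elsewhere, so enrichment of a recovered profile
  against the immune branch is guaranteed at large effect.
- **Signature**: planted core/lenient symbols enter the external tiered
  signature with probabilities 0.49/0.13/0.05 (high/intermediate/low) and
  are otherwise absent, yielding ≈67% overlap in expectation.

What the synthetic study does **not** model: batch effects, length bias,
cross-species differences in annotation depth beyond symbol dropout,
correlated genes, composition differences between brain regions, or
protocol-specific count distributions. Passing the planted-recovery test
shows the pipeline's logic is correct and powerful under clean NB noise;
it does not certify performance on real tissue data.

## Numerical choices and degenerate inputs

- All filter inequalities are strict (Δ < 20, fraction > 60, FDR < 0.001,
  log2FC > 3, p < 0.05, q < 0.1), matching their definitions.
- Percentiles need ≥ 2 genes; Δ needs a non-empty gene intersection; TPM
  refuses all-zero samples (undefined); DE needs ≥ 2 samples per group.
  Empty candidate sets yield an empty profile with a warning, not an error.
- Determinism: all randomness flows from a single integer seed; reports are
  JSON with sorted keys, so identical configurations produce byte-identical
  files.
- Problem sizes in the default run (2,000 genes × 4 species × ≤ 3 cohorts
  × 5 samples) keep a full pipeline execution in the low seconds on one
  CPU; the test-suite simulations (hundreds of replicates) are sized to
  estimate rates at the asserted bounds without excess runtime.

## Known limitations

- The built-in DE stage is a moderated t on log-normalized counts, not a
  count GLM; at very low counts its power and fold-change calibration lag
  purpose-built NB models (a cross-check against one is part of the test
  suite). Supplying an external DE table sidesteps this entirely.
- One ortholog symbol per gene per species: one-to-many orthology must be
  resolved before input.
- The GO stage handles a single namespace/root per run.
- `lenient_k` generalizes "3 of 4", but very small species counts make the
  lenient/core distinction degenerate (k = S collapses both).
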