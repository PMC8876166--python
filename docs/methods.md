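# Methods

## Statistical model and assumptions

The pipeline compares two groups of bulk expression profiles
(reference tissue vs test tissue, default labels `iWAT` and `PANC`) on
two omics layers measured on the same design: transcripts in FPKM and
mature miRNAs in TPM. Both layers are treated identically:

- **Filtering.** A feature enters testing only if its mean abundance over
  all non-excluded samples of both groups pooled is ≥ 1 (FPKM or TPM).
  The boundary is inclusive: only values strictly below the floor are
  removed. Filtering the pooled matrix once, before testing, keeps the
  tested universe identical for both groups and defines the "expressed"
  universe reused by the enrichment stage.
- **Per-feature test.** A two-sided Welch unequal-variance t-test on the
  raw abundance values, with Welch–Satterthwaite degrees of freedom.
  The test is applied to abundances rather than their logarithms to match
  the common practice for FPKM/TPM comparisons in this design; a
  `log_transform` switch applies the test to log2(x + pseudocount)
  instead. The modelling assumptions are therefore those of the Welch
  test: approximate normality of within-group means at n = 8, unequal
  variances allowed, no exchangeability assumption between groups. Under
  multiplicative (log-normal) noise with moderate coefficient of
  variation the two-sided test stays close to nominal level (the
  acceptance suite measures the type-I error at ~0.043–0.047 for CV 0.3);
  strong skew at very small n would make it conservative.
- **Significance** is an unadjusted p < α call with α = 0.05. No multiple
  testing correction is applied by default, since the integration and
  enrichment stages are designed around unadjusted per-feature calls;
  Benjamini–Hochberg is emitted as an extra `p_adj` column on request and
  never changes the `significant` flag.
- **Fold change** is `log2((mean_test + c)/(mean_ref + c))` on group
  means with pseudocount c = 0.01 — monotone, bounded near zero
  abundances, and equal to the plain log-ratio whenever means are well
  above c. It is deliberately computed on means of raw abundances (not
  means of logs) so that the sign always agrees with the direction of the
  difference in group means that the t-test evaluates.

**Transcript→gene collapsing.** A gene is differentially expressed when
at least one of its transcripts is significant. Its direction is the
common sign of its significant transcripts, or `discordant` when both
signs occur; `best_p` is the minimum transcript p and `max_abs_log2fc`
the signed fold change of largest magnitude. Discordant genes are
reported but excluded from every direction-dependent downstream rule.

**Outlier flagging.** Samples whose median Spearman correlation to all
other samples falls below 0.8 are flagged. The flag is advisory only:
exclusion happens exclusively through the sample sheet, so that the
analysis record states which samples were dropped and why.

## miRNA–target integration

Validated interaction tables are pooled by union, keeping per-edge
provenance; multi-database support is not required, because the source
databases themselves curate experimentally validated interactions.
miRNA identifiers are matched exactly (arm-specific); no family
expansion.

Every significant miRNA (p < α, regardless of fold-change magnitude) is
joined to its interaction partners among the DEGs; a pair is retained
only when `sign(miRNA log2FC) = −sign(gene log2FC)`. This encodes the
biological prior that miRNAs predominantly repress their targets, and is
a sign-level rule on group fold changes — no per-sample correlation is
computed. Pairs with |gene log2FC| > 1.5 are flagged `strong`.
"Exclusive" miRNAs (significant with |log2FC| ≥ 2, split by sign into
the two tissues) are a reporting overlay on the same results, not a
separate filter. The integration summary counts distinct miRNAs and
distinct target genes in retained pairs; `fraction_degs_explained` is
distinct regulated genes over all DEGs (up, down and discordant).

## Enrichment

Over-representation of a gene list against a GMT collection uses the
one-sided hypergeometric upper tail P[X ≥ k] for k overlap genes, query
size n, term size K and universe size N, with term members intersected
with the universe first. The universe is the expressed-gene set (genes
with ≥ 1 transcript surviving the floor), not the whole annotation — the
detected-background convention. A term *passes* only when all three
gates hold simultaneously: k ≥ min_count (10 for DEG enrichment, 3 for
the smaller miRNA-target queries), fold enrichment (k/n)/(K/N) strictly
greater than 2, and p < 0.05. A DAVID-style EASE variant (upper tail
evaluated at k − 1) is available behind a flag and is always at least as
conservative. Each term also carries the GO-circle direction score
z = (#up − #down)/√(#up + #down) over its overlapping genes, with
discordant genes ignored and z = 0 for an empty overlap. p-values are
reported at full computed precision; displays that floor at 2.2e-16 are
a printing convention, not a property of the statistic.

The marker-overlap test ranks expressed genes by mean abundance in the
chosen group (gene abundance = sum of its transcripts' FPKM; ties broken
lexicographically by gene id so ranking is total and reproducible),
takes the top N = 1000 and tests marker membership with a one-sided
Fisher exact test. The reported odds ratio is the sample odds ratio
(a·d)/(b·c); when b·c = 0 it is reported as infinite with a flag, or
Haldane-corrected (+0.5 per cell) on request.

## qPCR

Relative expression is 2^(−ΔCt) with ΔCt = Ct_gene − Ct_reference within
the same sample (reference gene `Eef2` by default). Group summaries are
geometric-mean based — the arithmetic mean of ΔCt back-transformed —
which is the natural summary for a log-scale quantity; the arithmetic
mean of per-sample values is emitted alongside for comparison. No
amplification-efficiency correction (Pfaffl-type models) is attempted.

## The synthetic-data generator

`mscompare.simulate` emulates the statistical structure of the two-tissue
design so the pipeline can be exercised against known truth:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 8 | samples per tissue |
| `n_transcripts` / `n_mirnas` | 3000 / 600 | features per layer |
| `transcripts_per_gene` | 1–2, drawn | gene scaffold (~2000 genes) |
| `frac_de_genes` / `frac_de_mirnas` | 0.20 / 0.10 | truly DE fractions |
| effect size | 1 + Exp(1) log2 units, signs balanced | multiplicative group effect 2^δ |
| `coupling_fraction` | 0.40 | share of DE genes driven by a DE miRNA |
| `repression_slope` | 0.75 | gene effect = −slope·miRNA effect + N(0, 0.1) |
| `decoy_edges_per_mirna` | 5 | validated-looking edges to non-DE genes |
| `noise_cv` | 0.30 | per-sample multiplicative log-normal noise |
| baseline | log2 ~ N(3, 2) | per-feature abundance scale |
| `frac_sub_floor` | 0.05 | non-DE features forced below 1 unit |
| `frac_secreted` | 0.12 | genes labelled secreted |
| `n_terms` / `n_enriched_terms` | 100 / 10 | GMT terms; enriched ones over-sample DE genes |

Choices worth noting:

- Baselines are resampled until non-flagged features sit comfortably
  above the abundance floor (log2 baseline ≥ 0.5), and a separate 5 %
  sub-floor tail is planted among non-DE features, so the filter always
  has work to do but never silently eats planted signal.
- Effects are assigned at the gene level and copied to all of a gene's
  transcripts, keeping the collapsing step exercised without artificial
  discordance; a `frac_discordant` knob flips one transcript of selected
  multi-transcript DE genes to exercise the discordant path.
- The coupling noise is resampled until the coupled gene's sign is
  exactly opposite its driving miRNA's, so the anti-correlation invariant
  is true by construction, not just in expectation.
- The marker list mixes a core drawn from the top-1000 expected-abundance
  genes (`frac_marker_top` = 0.5) with genes drawn uniformly from the
  whole universe. The uniform remainder is deliberately not restricted to
  the complement of the top set: with a synthetic universe of ~2000 genes
  the top-1000 is half of it, and excluding it from the remainder would
  pin the marker odds ratio to ~1 by construction.
- One integer seed drives a single `numpy.random.Generator` with a fixed
  draw order; a fixed seed yields byte-identical output files.

What the generator does **not** emulate: count-level sampling noise
(values are smooth log-normal abundances, not negative-binomial counts),
library-size or batch effects, correlated co-expression modules,
miRNA-family seed sharing, annotation errors, and the long-tailed
empirical abundance distributions of real tissues. Tests passing on this
generator therefore validate the statistical logic and its calibration
under the stated noise model — they do not certify performance on any
particular real dataset.

## Numerical and edge-case conventions

- Zero variance in both groups with equal means: t = 0, p = 1 (a valid
  null observation, not an error). With unequal means the squared
  standard error is floored at machine epsilon and the feature flagged in
  `zero_variance`.
- Expression tables must be complete; an NA or non-numeric cell is an
  error naming the row and column — never an imputation trigger.
  Negative or non-finite abundances are rejected at construction.
- Tables are written with `%.17g` so write→read round-trips are exact at
  double precision; the reader parses with round-trip float precision.
- All ranked outputs define total orders (p then term id; |log2FC| then
  gene symbol; abundance then gene id) so ties cannot make two runs
  differ.
- Manifests record SHA-256 checksums of every input and output and omit
  timestamps and absolute paths, so identical runs produce identical
  manifests.

## Calibration experiments and problem sizes

The test suite and `scripts/acceptance.py` use deliberately modest
problem sizes — a global-null matrix of 5000 features, effect-recovery
sets of 500 features, coupled datasets of 2000 transcripts / 400 miRNAs,
and the default 3000-transcript pipeline dataset — chosen so each
experiment is a sharp measurement of one property (level, bias, recall,
exactness, determinism) while the whole suite stays fast enough to run
habitually.

The coupling-recovery experiment uses single-transcript genes, a DE-gene
fraction of 0.4 and effect magnitudes of 2.5 + Exp(0.5) log2 units. The
reason is structural: `fraction_degs_explained` divides by *all*
recovered DEGs, and with unadjusted p < 0.05 the DEG list always carries
about α × (number of non-DE genes) false positives, which no increase in
effect size removes. The recovered fraction therefore converges not to
the planted coupling fraction f but to f × nDE/(nDE + α·nonDE); the
experiment's conditions make that dilution factor ≈ 0.93 so the
recovered value is a faithful readout of f, and the same arithmetic is
the reason the default-parameter pipeline (dilution ≈ 0.83, plus
two-transcript genes) reads ~0.34 for a planted 0.40.

## Known limitations

- Two groups only; no paired designs, covariates or batch correction.
- Abundance-scale Welch testing is not a count model; for raw counts a
  negative-binomial framework would be more powerful.
- The direction-consistency rule is sign-only; it cannot distinguish
  direct repression from shared upstream drivers, and carries the target
  databases' ascertainment biases.
- Enrichment ignores gene-set topology (no parent-term propagation) and
  tests over-representation only.
- The secretome partition is an annotation intersection, not a
  measurement of secretion.
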