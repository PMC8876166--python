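# mscompare

A tested, reusable pipeline for comparing the transcriptome and miRNome of
two cell populations from bulk expression tables — written around the
common design of sorting a stromal/progenitor cell type from two tissues
(by default pancreas-derived vs inguinal-white-adipose-derived mesenchymal
stromal cells, *n* = 8 per group) and asking which expression differences
between the tissues can be attributed to miRNA-mediated repression.

It is aimed at analysts who already have normalised abundance tables
(FPKM for transcripts, TPM for miRNAs) plus standard annotation exports —
a transcript→gene map, validated miRNA–target interaction tables
(DIANA-TarBase / miRecords / miRTarBase style), gene-set collections
(GMT), a predicted-secretome gene list (Human Protein Atlas style) and a
marker gene list — and want the downstream statistics to be scripted,
validated and reproducible rather than spread across a notebook.

## What it computes

Given feature × sample matrices `X` with groups *ref* and *test*:

1. **Expression filtering.** Features with pooled mean abundance < 1
   FPKM/TPM are removed (boundary values kept).
2. **Welch differential expression**, per feature:
   `t = (x̄_test − x̄_ref) / sqrt(s²_test/n_test + s²_ref/n_ref)` with
   Welch–Satterthwaite degrees of freedom and two-sided p; significance at
   unadjusted p < 0.05; `log2FC = log2((x̄_test + c)/(x̄_ref + c))` with
   pseudocount c = 0.01. Significant transcripts are collapsed to genes
   (direction `up`/`down`/`discordant`). Benjamini–Hochberg is optional.
3. **miRNA–target integration.** Significant miRNAs are joined to their
   validated target genes among the DEGs and a pair is kept only when the
   two fold changes are anti-correlated (miRNA up & gene down, or the
   reverse); |gene log2FC| > 1.5 marks strong repression, and miRNAs with
   p ≤ 0.05 and |log2FC| ≥ 2 are reported as tissue-exclusive. The
   headline is the fraction of DEGs attributable to miRNAs.
4. **Gated enrichment.** One-sided hypergeometric over-representation of
   a query against GMT terms within the expressed universe:
   `p = P[X ≥ k]`, fold enrichment `(k/n)/(K/N)`, with a term *passing*
   only when overlap ≥ min_count (10 for DEGs, 3 for miRNA targets), fold
   enrichment > 2 and p < 0.05; each term gets a direction z-score
   `(#up − #down)/√(#up + #down)` in the GO-circle convention.
5. **Secretome partition.** DEGs ∩ predicted-secreted genes, split by
   direction, with top-10 lists ranked by |log2FC|.
6. **Marker overlap.** One-sided Fisher exact test of a marker list
   against the top-1000 expressed genes of the test tissue, reporting the
   sample odds ratio (a·d)/(b·c).
7. **qPCR relative expression** by the 2^(−ΔCt) method against a
   reference gene (Eef2 by default).

A seeded simulator (`mscompare.simulate`) generates coupled two-layer
datasets — true differential genes and miRNAs, repressive miRNA→gene
edges among decoys, enriched gene-set terms, secretome labels, markers —
together with the ground truth, so every stage of the pipeline is
testable end to end without any external download. See
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Run the full pipeline on the default synthetic dataset (3000 transcripts
on ~2000 genes, 600 miRNAs, 8 samples per group, 20 % DE genes, 40 %
of them miRNA-driven):

```bash
mscompare run --config run.yaml --out results/demo
```

with `run.yaml`:

```yaml
outdir: results/demo
simulate:
  seed: 1
```

The summary printed at the end (also written to `summary.json`) includes:

```text
n_transcripts_tested      2844      # of 3000; sub-floor tail removed
n_de_transcripts          678
n_degs                    491       # 239 up / 250 down in the test tissue
n_mirnas_tested           570
n_de_mirnas               88        # 37 up / 51 down
n_exclusive_ref / test    11 / 5    # p<=0.05 and |log2FC|>=2
n_consistent_pairs        167
n_regulated_genes         166
fraction_degs_explained   0.338     # simulated coupling fraction: 0.4
n_enrichment_pass         10        # the 10 truly enriched terms
n_secreted_total          61        # 31 higher in test, 30 in reference
marker_odds_ratio         3.13      # p = 2.6e-07
```

Reading the numbers: of 491 differentially expressed genes, 166 are
targets of a differentially expressed miRNA with the opposite direction
of change, i.e. ~34 % of the expression differences are attributable to
miRNA regulation — close to the 40 % the generator planted, with the gap
driven mostly by false-positive DEGs diluting the denominator (the run
uses unadjusted p-values, as is common for this design). Exactly the ten
planted gene-set terms clear the three enrichment gates, and the marker
list built around top-expressed genes shows the expected Fisher
enrichment.

Every output directory contains per-stage TSVs (`de_transcripts.tsv`,
`degs.tsv`, `consistent_pairs.tsv`, `enrichment_degs.tsv`, …) and a
`manifest.json` with the effective configuration and SHA-256 checksums;
rerunning the same configuration reproduces the tree byte for byte.

The same stages are available as library functions
(`mscompare.diffexp.welch_de`, `mscompare.integration.map_and_filter_targets`,
`mscompare.enrichment.hypergeom_enrich`, …) and as individual
subcommands (`mscompare de`, `integrate`, `enrich`, `secretome`, `qpcr`,
`simulate`) for real exported tables.

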