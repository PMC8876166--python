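"""Low-expression filtering and per-feature Welch differential expression.

The test operates directly on abundance values (FPKM for transcripts, TPM
for miRNAs): features whose mean over all non-excluded samples falls below
an abundance floor are removed, then each remaining feature gets a
two-sided Welch unequal-variance t-test between the two groups with
Welch–Satterthwaite degrees of freedom.  Fold changes are log2 ratios of
group means with a small pseudocount; significance is an unadjusted
p < alpha call (Benjamini–Hochberg is available as an extra column, off by
default).  Significant transcripts are collapsed to genes, recording a
``discordant`` direction when significant transcripts of both signs map to
the same gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, FeatureAnnotation, SampleSheet


@dataclass(frozen=True)
class Thresholds:
    """Analysis cut-offs shared across pipeline stages.

    Attributes
    ----------
    expr_floor
        Minimum mean abundance (FPKM/TPM) a feature must reach to be tested.
    alpha
        Unadjusted significance level for both omics layers and enrichment.
    exclusive_lfc
        |log2FC| at or above which a significant miRNA counts as
        tissue-exclusive.
    highlight_lfc
        |log2FC| above which a repressed target gene is flagged as strong.
    min_count_deg, min_count_target
        Overlap-count gates for gene-set enrichment of DEGs and of miRNA
        target genes, respectively.
    min_fold_enrichment
        Fold-enrichment gate (strict >) for gene-set enrichment.
    top_n_expressed
        Size of the top-expressed gene list for the marker-overlap test.
    pseudocount
        Added to both group means before the log2 ratio.
    """

    expr_floor: float = 1.0
    alpha: float = 0.05
    exclusive_lfc: float = 2.0
    highlight_lfc: float = 1.5
    min_count_deg: int = 10
    min_count_target: int = 3
    min_fold_enrichment: float = 2.0
    top_n_expressed: int = 1000
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "expr_floor",
            "alpha",
            "exclusive_lfc",
            "highlight_lfc",
            "min_count_deg",
            "min_count_target",
            "min_fold_enrichment",
            "top_n_expressed",
            "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


DE_COLUMNS = [
    "feature_id",
    "mean_ref",
    "mean_test",
    "log2fc",
    "t_stat",
    "df",
    "p_value",
    "significant",
    "direction",
    "zero_variance",
]


def filter_low_expression(
    matrix: ExpressionMatrix,
    floor: float,
    sheet: SampleSheet | None = None,
) -> ExpressionMatrix:
    """Drop features whose mean abundance is below ``floor``.

    The mean is taken jointly over all non-excluded samples of both groups
    (the pooled matrix is filtered once, before testing).  Features with
    mean exactly equal to the floor are retained — only values *below* the
    floor are removed.
    """
    if floor <= 0:
        raise ValueError("expression floor must be > 0")
    if matrix.n_features == 0:
        raise ValueError("cannot filter an empty matrix")
    samples = None
    if sheet is not None:
        included = set(sheet.included()["sample_id"])
        samples = [s for s in matrix.sample_ids if s in included]
    means = matrix.feature_means(samples)
    keep = means[means >= floor].index
    if len(keep) == 0:
        warnings.warn(
            f"expression floor {floor} removed all {matrix.n_features} features",
            stacklevel=2,
        )
    return ExpressionMatrix(matrix.data.loc[keep], matrix.unit)


def welch_de(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    thresholds: Thresholds | None = None,
    log_transform: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided Welch t-test, test group vs reference.

    Returns a DataFrame with one row per feature: group means, log2 fold
    change (test over reference, pseudocount-stabilised), Welch t statistic,
    Welch–Satterthwaite df, two-sided p, significance at unadjusted
    p < alpha and the resulting direction (``up`` = higher in the test
    group).  ``log_transform`` runs the test on log2(x + pseudocount)
    instead of raw abundances; ``adjust`` appends a Benjamini–Hochberg
    ``p_adj`` column (significance still uses the unadjusted p).

    Features with zero variance in both groups get t = 0, p = 1 when the
    means agree; when the means differ the variance is floored at machine
    epsilon and the feature is flagged in ``zero_variance``.
    """
    thresholds = thresholds or Thresholds()
    if matrix.n_features == 0:
        raise ValueError("empty expression matrix; nothing to test")
    sheet.validate_against(matrix)
    ref_ids = [s for s in sheet.samples_for(sheet.reference) if s in set(matrix.sample_ids)]
    test_ids = [s for s in sheet.samples_for(sheet.test) if s in set(matrix.sample_ids)]
    if len(ref_ids) < 2 or len(test_ids) < 2:
        raise ValueError("each group needs >= 2 non-excluded samples")

    ref = matrix.data[ref_ids].to_numpy(float)
    tst = matrix.data[test_ids].to_numpy(float)
    mean_ref_raw = ref.mean(axis=1)
    mean_test_raw = tst.mean(axis=1)
    pc = thresholds.pseudocount
    log2fc = np.log2(mean_test_raw + pc) - np.log2(mean_ref_raw + pc)

    if log_transform:
        ref = np.log2(ref + pc)
        tst = np.log2(tst + pc)

    n1, n2 = ref.shape[1], tst.shape[1]
    m1, m2 = ref.mean(axis=1), tst.mean(axis=1)
    v1 = ref.var(axis=1, ddof=1)
    v2 = tst.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2

    both_flat = (v1 == 0) & (v2 == 0)
    zero_var_equal = both_flat & (m1 == m2)
    zero_var_diff = both_flat & (m1 != m2)
    eps = np.finfo(float).eps
    se2_safe = np.where(se2 == 0, eps, se2)

    t_stat = (m2 - m1) / np.sqrt(se2_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2_safe**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    df = np.where(both_flat, n1 + n2 - 2, df)
    t_stat = np.where(zero_var_equal, 0.0, t_stat)
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), df)
    p_value = np.where(zero_var_equal, 1.0, np.minimum(p_value, 1.0))

    significant = p_value < thresholds.alpha
    direction = np.where(
        significant & (log2fc > 0), "up", np.where(significant & (log2fc < 0), "down", "none")
    )

    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_ref": mean_ref_raw,
            "mean_test": mean_test_raw,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "df": df,
            "p_value": p_value,
            "significant": significant,
            "direction": direction,
            "zero_variance": zero_var_diff,
        }
    )
    if adjust:
        out["p_adj"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out.reset_index(drop=True)


def classify_de(results: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition significant features into (up, down) id sets by log2fc sign."""
    sig = results[results["significant"]]
    up = set(sig.loc[sig["log2fc"] > 0, "feature_id"])
    down = set(sig.loc[sig["log2fc"] < 0, "feature_id"])
    return up, down


def collapse_to_genes(results: pd.DataFrame, annotation: FeatureAnnotation) -> pd.DataFrame:
    """Collapse significant transcripts to differentially expressed genes.

    One row per gene with >= 1 significant transcript; ``direction`` is
    ``up``/``down`` when all its significant transcripts agree in sign and
    ``discordant`` otherwise.  ``best_p`` is the minimum transcript p and
    ``max_abs_log2fc`` the (signed) transcript log2fc of largest magnitude.
    """
    sig = results[results["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(
            columns=["gene_symbol", "direction", "best_p", "max_abs_log2fc", "n_transcripts"]
        )
    known = set(annotation.mapping.index)
    missing = [f for f in sig["feature_id"] if f not in known]
    if missing:
        raise ValueError(f"significant transcripts without annotation: {missing[:20]}")
    sig["gene_symbol"] = annotation.mapping.loc[sig["feature_id"]].to_numpy()

    rows = []
    for gene, grp in sig.groupby("gene_symbol", sort=True):
        signs = set(np.sign(grp["log2fc"]))
        if signs <= {1.0}:
            direction = "up"
        elif signs <= {-1.0}:
            direction = "down"
        else:
            direction = "discordant"
        best = grp.loc[grp["log2fc"].abs().idxmax(), "log2fc"]
        rows.append(
            {
                "gene_symbol": gene,
                "direction": direction,
                "best_p": float(grp["p_value"].min()),
                "max_abs_log2fc": float(best),
                "n_transcripts": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def flag_outlier_samples(matrix: ExpressionMatrix, min_median_corr: float = 0.8) -> list[str]:
    """Flag samples poorly correlated with the rest of the cohort.

    Computes pairwise Spearman correlations between samples and flags any
    sample whose median correlation to all others falls below the
    threshold.  Flags are advisory: exclusion happens only through the
    sample sheet.
    """
    if matrix.n_samples < 3:
        raise ValueError("outlier flagging needs >= 3 samples")
    corr, _ = stats.spearmanr(matrix.data.to_numpy())
    corr = np.atleast_2d(corr)
    flagged = []
    for i, sample in enumerate(matrix.sample_ids):
        others = np.delete(corr[i], i)
        if float(np.median(others)) < min_median_corr:
            flagged.append(sample)
    return flagged
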