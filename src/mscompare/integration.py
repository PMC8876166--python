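"""Direction-consistent integration of the miRNA and transcript layers.

Because miRNAs predominantly repress their targets, a differentially
expressed miRNA is linked to a differentially expressed target gene only
when the two move in opposite directions between the groups (miRNA up and
gene down, or miRNA down and gene up).  The join runs over experimentally
validated miRNA-target edges; genes whose transcript-level calls disagree
in sign ("discordant") are excluded because the rule is undefined for
them.  All significant miRNAs enter the filter; "exclusive" status
(significant with |log2FC| >= exclusive_lfc) is a reporting overlay for
the tissue-specific subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import Thresholds

PAIR_COLUMNS = ["mirna_id", "mirna_log2fc", "gene_symbol", "gene_log2fc", "strong", "sources"]


def select_exclusive_mirnas(
    results: pd.DataFrame, thresholds: Thresholds | None = None
) -> tuple[set[str], set[str]]:
    """Split significant miRNAs into tissue-exclusive sets by fold change.

    Returns ``(reference_exclusive, test_exclusive)``: significant miRNAs
    with log2fc <= -exclusive_lfc (higher in the reference tissue, iWAT by
    default) and log2fc >= +exclusive_lfc (higher in the test tissue,
    pancreas), respectively.
    """
    thresholds = thresholds or Thresholds()
    sig = results[results["significant"]]
    cut = thresholds.exclusive_lfc
    ref_side = set(sig.loc[sig["log2fc"] <= -cut, "feature_id"])
    test_side = set(sig.loc[sig["log2fc"] >= cut, "feature_id"])
    return ref_side, test_side


def map_and_filter_targets(
    mirna_results: pd.DataFrame,
    deg_sets: pd.DataFrame,
    interactions: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Join significant miRNAs to DEG targets, keeping anti-correlated pairs.

    For each significant miRNA, validated interaction partners that are
    DEGs (gene-level direction ``up`` or ``down``) are retained only when
    the signs of the miRNA and gene log2 fold changes are opposite.
    ``strong`` marks pairs whose gene |log2fc| exceeds ``highlight_lfc``.
    Database provenance is carried through in ``sources``.
    """
    thresholds = thresholds or Thresholds()
    if interactions.empty:
        warnings.warn("empty interaction table: no pairs can be formed", stacklevel=2)
        return pd.DataFrame(columns=PAIR_COLUMNS)

    sig_mirnas = mirna_results[mirna_results["significant"]][["feature_id", "log2fc"]]
    sig_mirnas = sig_mirnas.rename(
        columns={"feature_id": "mirna_id", "log2fc": "mirna_log2fc"}
    )
    genes = deg_sets[deg_sets["direction"].isin(["up", "down"])][
        ["gene_symbol", "max_abs_log2fc"]
    ].rename(columns={"max_abs_log2fc": "gene_log2fc"})

    joined = interactions.merge(sig_mirnas, on="mirna_id").merge(genes, on="gene_symbol")
    if joined.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    anti = np.sign(joined["mirna_log2fc"]) == -np.sign(joined["gene_log2fc"])
    nonzero = (joined["mirna_log2fc"] != 0) & (joined["gene_log2fc"] != 0)
    kept = joined[anti & nonzero].copy()
    kept["strong"] = kept["gene_log2fc"].abs() > thresholds.highlight_lfc
    if "sources" not in kept.columns:
        kept["sources"] = ""
    kept = kept[PAIR_COLUMNS].sort_values(["mirna_id", "gene_symbol"], kind="mergesort")
    return kept.reset_index(drop=True)


@dataclass(frozen=True)
class IntegrationSummary:
    """Headline counts of the miRNA-explained transcriptome differences."""

    n_de_mirnas_with_targets: int
    n_regulated_genes: int
    n_total_degs: int
    fraction_degs_explained: float


def summarize_integration(pairs: pd.DataFrame, deg_sets: pd.DataFrame) -> IntegrationSummary:
    """Count distinct regulated genes/miRNAs and the explained DEG fraction."""
    n_degs = len(deg_sets)
    if n_degs == 0:
        raise ValueError("no DEGs: fraction of explained DEGs is undefined")
    n_mirnas = int(pairs["mirna_id"].nunique()) if not pairs.empty else 0
    n_genes = int(pairs["gene_symbol"].nunique()) if not pairs.empty else 0
    return IntegrationSummary(
        n_de_mirnas_with_targets=n_mirnas,
        n_regulated_genes=n_genes,
        n_total_degs=n_degs,
        fraction_degs_explained=n_genes / n_degs,
    )
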