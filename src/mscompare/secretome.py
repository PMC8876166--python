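"""In-silico secretome partitioning of differentially expressed genes.

DEGs are intersected with a user-supplied list of genes predicted to
encode actively secreted proteins (a Human-Protein-Atlas-style export)
and split by direction: higher in the test tissue vs higher in the
reference tissue, with sign-discordant genes counted separately.  The
"top secreted" ranking orders each side by the magnitude of the gene's
largest-magnitude transcript log2 fold change — a documented convention,
since abundance-based and significance-based rankings are equally
defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class SecretomePartition:
    """Secreted DEGs split by direction of change (test vs reference)."""

    up_test: frozenset[str]
    up_ref: frozenset[str]
    discordant: frozenset[str]

    @property
    def n_secreted_total(self) -> int:
        return len(self.up_test) + len(self.up_ref) + len(self.discordant)


def annotate_secretome(deg_sets: pd.DataFrame, secreted: set[str]) -> SecretomePartition:
    """Intersect DEGs with the secreted-gene list and split by direction."""
    if not secreted:
        warnings.warn("empty secreted-gene list: partition is empty", stacklevel=2)
        return SecretomePartition(frozenset(), frozenset(), frozenset())
    hits = deg_sets[deg_sets["gene_symbol"].isin(secreted)]
    up = frozenset(hits.loc[hits["direction"] == "up", "gene_symbol"])
    down = frozenset(hits.loc[hits["direction"] == "down", "gene_symbol"])
    disc = frozenset(hits.loc[hits["direction"] == "discordant", "gene_symbol"])
    return SecretomePartition(up_test=up, up_ref=down, discordant=disc)


def top_secreted(
    partition: SecretomePartition, deg_sets: pd.DataFrame, k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank each side of the partition by |log2FC|, descending.

    Returns ``(test_side, ref_side)`` DataFrames with columns ``rank``,
    ``gene_symbol``, ``log2fc``, ``best_p``; at most ``k`` rows each,
    ties broken lexicographically by gene symbol.
    """
    indexed = deg_sets.set_index("gene_symbol")

    def _rank(genes: frozenset[str]) -> pd.DataFrame:
        if not genes:
            return pd.DataFrame(columns=["rank", "gene_symbol", "log2fc", "best_p"])
        sub = indexed.loc[sorted(genes)].reset_index()
        sub["abs_lfc"] = sub["max_abs_log2fc"].abs()
        sub = sub.sort_values(
            ["abs_lfc", "gene_symbol"], ascending=[False, True], kind="mergesort"
        ).head(k)
        return pd.DataFrame(
            {
                "rank": range(1, len(sub) + 1),
                "gene_symbol": sub["gene_symbol"].to_numpy(),
                "log2fc": sub["max_abs_log2fc"].to_numpy(),
                "best_p": sub["best_p"].to_numpy(),
            }
        )

    return _rank(partition.up_test), _rank(partition.up_ref)
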