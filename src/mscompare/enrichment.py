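"""Gated hypergeometric gene-set over-representation and marker overlap.

Enrichment of a query gene list against a GMT collection is scored with a
one-sided hypergeometric upper tail over an expressed-gene universe, plus
a fold enrichment (k/n)/(K/N).  A term "passes" only when it clears all
three gates simultaneously: overlap count >= min_count, fold enrichment
strictly > min_fold_enrichment, unadjusted p < alpha.  Each term also gets
a direction z-score in the GO-circle convention,
z = (#up - #down)/sqrt(#up + #down) over its overlapping genes, signing
the term as increased or decreased in the test group.

The marker-overlap test ranks genes by mean abundance, takes the top N and
tests marker membership against it with a one-sided Fisher exact test,
reporting the sample odds ratio (a*d)/(b*c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import Thresholds
from .io import ExpressionMatrix, GeneSetCollection


def hypergeom_pvalue(k: int, n: int, K: int, N: int, ease: bool = False) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``ease`` applies the DAVID-style EASE penalty, scoring the tail at
    k - 1 successes (more conservative for small overlaps).
    """
    if not 0 <= k <= min(n, K):
        raise ValueError(f"invalid overlap k={k} for n={n}, K={K}, N={N}")
    k_eff = max(k - 1, 0) if ease else k
    return float(stats.hypergeom.sf(k_eff - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Overlap rate of the query relative to the universe: (k/n)/(K/N)."""
    if n == 0 or K == 0 or N == 0:
        raise ValueError("fold enrichment undefined for empty query, term or universe")
    return (k / n) / (K / N)


def go_circle_zscore(
    overlap_genes: Iterable[str], directions: Mapping[str, str]
) -> float:
    """Direction score of a term's overlap: (#up - #down)/sqrt(#up + #down).

    Genes without an ``up``/``down`` direction (e.g. discordant at the
    gene level) are ignored; an empty overlap scores 0.
    """
    n_up = n_down = 0
    for gene in overlap_genes:
        d = directions.get(gene)
        if d == "up":
            n_up += 1
        elif d == "down":
            n_down += 1
    total = n_up + n_down
    if total == 0:
        return 0.0
    return (n_up - n_down) / np.sqrt(total)


def hypergeom_enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    directions: Mapping[str, str] | None = None,
    thresholds: Thresholds | None = None,
    min_count: int | None = None,
    ease: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Score every gene set against a query within a universe.

    One row per term with overlap k >= 1, sorted by p-value.  Term members
    are intersected with the universe before counting; the query must be a
    subset of the universe.  ``passes`` is the conjunction of the three
    gates (count, fold enrichment, alpha).
    """
    thresholds = thresholds or Thresholds()
    if min_count is None:
        min_count = thresholds.min_count_deg
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:20]}")
    directions = directions or {}
    N = len(universe)
    n = len(query)
    rows = []
    for term in collection:
        members = term.members & universe
        K = len(members)
        if K == 0:
            continue
        overlap = query & members
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeom_pvalue(k, n, K, N, ease=ease)
        fe = fold_enrichment(k, n, K, N)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fe,
                "p_value": p,
                "z_score": go_circle_zscore(overlap, directions),
                "passes": bool(
                    (k >= min_count)
                    and (fe > thresholds.min_fold_enrichment)
                    and (p < thresholds.alpha)
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "k",
            "n",
            "K",
            "N",
            "fold_enrichment",
            "p_value",
            "z_score",
            "passes",
        ],
    )
    if not out.empty:
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
        if adjust:
            out["p_adj"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out


@dataclass(frozen=True)
class MarkerOverlapResult:
    """2x2 contingency of marker membership against the top-N expressed set.

    Cells: a = markers in the top N, b = markers outside it, c = non-marker
    genes in the top N, d = the non-marker remainder.  ``odds_ratio`` is
    the sample odds ratio (a*d)/(b*c) (infinite when b*c = 0, see
    ``infinite_or``); ``p_value`` is the one-sided Fisher exact enrichment
    p.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    infinite_or: bool
    top_n: int
    n_markers: int

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def marker_overlap_fisher(
    matrix: ExpressionMatrix,
    markers: set[str],
    top_n: int = 1000,
    haldane: bool = False,
) -> MarkerOverlapResult:
    """Test marker enrichment among the top-N expressed genes.

    Genes are ranked by mean abundance over the matrix's samples (pass the
    test-group submatrix to rank within one tissue), ties broken
    lexicographically by gene id.  The marker set is intersected with the
    expressed universe first.  ``haldane`` adds 0.5 to every cell for the
    odds ratio when b*c = 0 instead of reporting infinity.
    """
    if top_n >= matrix.n_features:
        raise ValueError(
            f"top_n={top_n} must be smaller than the expressed universe ({matrix.n_features})"
        )
    means = matrix.feature_means()
    ranked = means.to_frame("mean").reset_index(names="gene")
    ranked = ranked.sort_values(["mean", "gene"], ascending=[False, True], kind="mergesort")
    top = set(ranked["gene"].head(top_n))
    universe = set(matrix.feature_ids)
    markers = markers & universe

    a = len(markers & top)
    b = len(markers - top)
    c = len(top - markers)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    infinite = b * c == 0
    if infinite and haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        infinite = False
    elif infinite:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return MarkerOverlapResult(a, b, c, d, odds, float(p), infinite, top_n, len(markers))
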