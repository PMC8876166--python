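"""Relative qPCR expression by the 2^(-dCt) method.

Each gene's cycle threshold (Ct) is normalised against a reference gene
measured in the same sample (Eef2 by default); relative expression is
2^-(Ct_gene - Ct_ref).  Group summaries are geometric-mean based
(arithmetic mean of dCt, then transform), matching the log-scale nature
of the method; the arithmetic mean of per-sample values is reported
alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENE = "Eef2"


def relative_expression(ct_gene, ct_ref):
    """2^-(ct_gene - ct_ref); accepts scalars or aligned arrays."""
    return 2.0 ** (-(np.asarray(ct_gene, dtype=float) - np.asarray(ct_ref, dtype=float)))


def read_ct_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a long-format Ct table with columns sample_id, gene, ct."""
    frame = pd.read_csv(path, sep=sep, comment="#", dtype={"sample_id": str, "gene": str})
    missing = {"sample_id", "gene", "ct"} - set(frame.columns)
    if missing:
        raise ValueError(f"Ct table {path} missing columns: {sorted(missing)}")
    ct = pd.to_numeric(frame["ct"], errors="coerce")
    bad = frame.loc[ct.isna() | ~np.isfinite(ct) | (ct <= 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"invalid Ct {row['ct']!r} for sample {row['sample_id']!r}, gene {row['gene']!r}"
        )
    frame = frame.copy()
    frame["ct"] = ct
    return frame


def relative_expression_table(
    ct_table: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Per-sample 2^(-dCt) for every non-reference gene.

    Every sample must carry a Ct for the reference gene; a sample without
    one raises ``ValueError`` naming it.
    """
    ref = ct_table[ct_table["gene"] == reference_gene].set_index("sample_id")["ct"]
    if ref.index.has_duplicates:
        raise ValueError("multiple reference-gene rows for one sample")
    target = ct_table[ct_table["gene"] != reference_gene].copy()
    missing = sorted(set(target["sample_id"]) - set(ref.index))
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for samples: {missing}"
        )
    target["ct_ref"] = ref.loc[target["sample_id"]].to_numpy()
    target["delta_ct"] = target["ct"] - target["ct_ref"]
    target["rel_expr"] = relative_expression(target["ct"], target["ct_ref"])
    return target[["sample_id", "gene", "ct", "ct_ref", "delta_ct", "rel_expr"]].reset_index(
        drop=True
    )


def summarize_by_group(
    rel_table: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Group summaries per gene: geometric and arithmetic means of 2^(-dCt).

    ``groups`` maps sample_id to group label.  The geometric mean is
    2^-(mean dCt); both summaries are emitted.
    """
    frame = rel_table.copy()
    unknown = sorted(set(frame["sample_id"]) - set(groups.index))
    if unknown:
        raise ValueError(f"samples without a group assignment: {unknown}")
    frame["group"] = groups.loc[frame["sample_id"]].to_numpy()
    out = (
        frame.groupby(["gene", "group"], sort=True)
        .agg(
            n=("rel_expr", "size"),
            mean_delta_ct=("delta_ct", "mean"),
            arithmetic_mean=("rel_expr", "mean"),
        )
        .reset_index()
    )
    out["geometric_mean"] = 2.0 ** (-out["mean_delta_ct"])
    return out[["gene", "group", "n", "mean_delta_ct", "geometric_mean", "arithmetic_mean"]]
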