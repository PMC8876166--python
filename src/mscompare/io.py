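"""Tabular input/output and the shared data model.

Everything downstream operates on a small set of validated containers:
an :class:`ExpressionMatrix` (feature x sample abundances with a unit tag),
a :class:`SampleSheet` (two-group design with optional exclusions), a
transcript-to-gene :class:`FeatureAnnotation`, a :class:`GeneSetCollection`
(GMT), and a table of validated miRNA-target interactions.

The canonical on-disk dialect is TSV (UTF-8, "." decimal); CSV is accepted
via ``sep=","``.  Lines starting with ``#`` are comments: writers emit one
recording the package version and parameters, readers skip them.
Expression tables must be complete — a missing or non-numeric cell is an
error, never silently coerced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__

VALID_UNITS = ("FPKM", "TPM")

#: default group labels: reference = iWAT stroma, test = pancreas stroma
DEFAULT_REFERENCE = "iWAT"
DEFAULT_TEST = "PANC"


def _comment_line(**params: object) -> str:
    fields = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# mscompare v{__version__} {fields}".rstrip()


@dataclass(frozen=True)
class ExpressionMatrix:
    """A feature x sample abundance matrix with a declared unit.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample id.
        All values must be finite and non-negative.
    unit
        Abundance unit, ``"FPKM"`` (transcripts) or ``"TPM"`` (miRNAs).
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size:
            bad = ~np.isfinite(values)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    "non-finite value at feature "
                    f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
                )
            neg = values < 0
            if neg.any():
                r, c = np.argwhere(neg)[0]
                raise ValueError(
                    "negative abundance at feature "
                    f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.unit)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.unit)

    def feature_means(self, sample_ids: Iterable[str] | None = None) -> pd.Series:
        """Per-feature mean abundance, optionally over a sample subset."""
        frame = self.data if sample_ids is None else self.data[list(sample_ids)]
        return frame.mean(axis=1)


def read_expression_table(path: str | Path, unit: str, sep: str = "\t") -> ExpressionMatrix:
    """Read a feature x sample abundance table.

    First column holds feature ids, header row holds sample ids.  Any
    non-numeric, missing, negative or non-finite cell raises ``ValueError``
    naming the offending row and column.
    """
    raw = pd.read_csv(
        path, sep=sep, index_col=0, comment="#", float_precision="round_trip"
    )
    raw.index = raw.index.astype(str)
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            row = raw.index[bad][0] if bad.any() else raw.index[raw[col].isna()][0]
            cell = raw[col].loc[row] if bad.any() else None
            kind = f"non-numeric cell {cell!r}" if bad.any() else "missing value"
            raise ValueError(f"{kind} at feature {row!r}, sample {col!r} in {path}")
    if raw.isna().to_numpy().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at feature {raw.index[r]!r}, sample {raw.columns[c]!r} in {path}"
        )
    return ExpressionMatrix(raw.astype(float), unit)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, sep: str = "\t"
) -> None:
    """Write a matrix as TSV with a comment line recording the unit."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_line(unit=matrix.unit) + "\n")
        # %.17g keeps write->read exact at double precision
        matrix.data.to_csv(
            fh, sep=sep, index_label="feature_id", lineterminator="\n", float_format="%.17g"
        )


@dataclass
class SampleSheet:
    """Assignment of samples to the two compared groups.

    ``frame`` has columns ``sample_id``, ``group``, ``excluded``.  Exactly
    two group labels are allowed; ``reference`` and ``test`` name them
    (fold changes are test over reference).  Exclusion is the only
    mechanism by which a sample leaves the analysis — outlier flags from
    :func:`mscompare.diffexp.flag_outlier_samples` are advisory.
    """

    frame: pd.DataFrame
    reference: str = DEFAULT_REFERENCE
    test: str = DEFAULT_TEST

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "excluded"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in sheet: {dups.tolist()}")
        groups = set(self.frame["group"])
        allowed = {self.reference, self.test}
        if not groups <= allowed:
            raise ValueError(f"unknown group labels {sorted(groups - allowed)}; expected {sorted(allowed)}")

    def included(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"].astype(bool)]

    def samples_for(self, group: str) -> list[str]:
        inc = self.included()
        return inc.loc[inc["group"] == group, "sample_id"].tolist()

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check the sheet covers the matrix and leaves >= 2 samples/group."""
        sheet_ids = set(self.frame["sample_id"])
        matrix_ids = set(matrix.sample_ids)
        if matrix_ids - sheet_ids:
            raise ValueError(f"samples absent from sheet: {sorted(matrix_ids - sheet_ids)}")
        for group in (self.reference, self.test):
            n = len([s for s in self.samples_for(group) if s in matrix_ids])
            if n < 2:
                raise ValueError(f"group {group!r} has {n} non-excluded samples; need >= 2")


def read_sample_sheet(
    path: str | Path,
    reference: str = DEFAULT_REFERENCE,
    test: str = DEFAULT_TEST,
    sep: str = "\t",
) -> SampleSheet:
    frame = pd.read_csv(path, sep=sep, comment="#", dtype={"sample_id": str, "group": str})
    if "excluded" not in frame.columns:
        frame["excluded"] = False
    frame["excluded"] = frame["excluded"].astype(bool)
    return SampleSheet(frame, reference=reference, test=test)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_line(reference=sheet.reference, test=sheet.test) + "\n")
        sheet.frame.to_csv(fh, sep=sep, index=False, lineterminator="\n")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Transcript-to-gene mapping (opaque, case-sensitive identifiers)."""

    mapping: pd.Series  # index: transcript_id, values: gene_symbol

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            dups = self.mapping.index[self.mapping.index.duplicated()].tolist()
            raise ValueError(f"duplicate transcript ids: {dups[:10]}")
        empty = self.mapping.isna() | (self.mapping.astype(str).str.len() == 0)
        if empty.any():
            raise ValueError(
                f"empty gene symbol for transcripts: {self.mapping.index[empty].tolist()[:10]}"
            )

    def gene_for(self, transcript_id: str) -> str:
        return str(self.mapping.loc[transcript_id])

    @property
    def genes(self) -> set[str]:
        return set(self.mapping.astype(str))


def read_annotation(path: str | Path, sep: str = "\t") -> FeatureAnnotation:
    frame = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    for col in ("transcript_id", "gene_symbol"):
        if col not in frame.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    return FeatureAnnotation(frame.set_index("transcript_id")["gene_symbol"])


def write_annotation(annotation: FeatureAnnotation, path: str | Path, sep: str = "\t") -> None:
    frame = annotation.mapping.rename("gene_symbol").rename_axis("transcript_id").reset_index()
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    terms: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = [i for i in ids if i in seen or seen.add(i)]
            raise ValueError(f"duplicate term ids: {dups[:10]}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __getitem__(self, term_id: str) -> GeneSet:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``term<TAB>description<TAB>member...``.

    Members are deduplicated preserving first occurrence; a line with
    fewer than three fields raises ``ValueError`` with its line number.
    """
    terms: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            term_id, name, *members = fields
            members = [m for m in members if m]
            terms.append(GeneSet(term_id, name, frozenset(members)))
    return GeneSetCollection(tuple(terms))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in collection:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


INTERACTION_COLUMNS = ("mirna_id", "gene_symbol", "source_db", "evidence_type")


def read_interaction_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a validated miRNA-target table and deduplicate edges.

    Expected columns: ``mirna_id``, ``gene_symbol``, ``source_db``,
    ``evidence_type``.  Records sharing (mirna_id, gene_symbol) are merged
    into one edge whose ``sources`` / ``evidence`` fields are the
    ``;``-joined sorted unions.
    """
    frame = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = set(INTERACTION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"interaction table {path} missing columns: {sorted(missing)}")
    return merge_interactions(frame)


def merge_interactions(*frames: pd.DataFrame) -> pd.DataFrame:
    """Union interaction records across tables, merging provenance.

    Returns columns ``mirna_id``, ``gene_symbol``, ``sources``,
    ``evidence`` with one row per unique (mirna_id, gene_symbol) edge.
    """
    if not frames:
        return pd.DataFrame(columns=["mirna_id", "gene_symbol", "sources", "evidence"])
    parts = []
    for frame in frames:
        part = frame.copy()
        if "sources" not in part.columns:
            part = part.rename(columns={"source_db": "sources", "evidence_type": "evidence"})
        parts.append(part[["mirna_id", "gene_symbol", "sources", "evidence"]])
    pooled = pd.concat(parts, ignore_index=True)
    if pooled.empty:
        return pd.DataFrame(columns=["mirna_id", "gene_symbol", "sources", "evidence"])

    def _union(values: pd.Series) -> str:
        items: set[str] = set()
        for v in values.dropna():
            items.update(x for x in str(v).split(";") if x)
        return ";".join(sorted(items))

    merged = (
        pooled.groupby(["mirna_id", "gene_symbol"], sort=True)
        .agg(sources=("sources", _union), evidence=("evidence", _union))
        .reset_index()
    )
    return merged


def write_interactions(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_gene_list(path: str | Path, column: str = "gene_symbol", sep: str = "\t") -> set[str]:
    """Read a one-column (or wider) gene table into a set of symbols."""
    frame = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if column not in frame.columns:
        raise ValueError(f"{path} has no column {column!r}")
    genes = set(frame[column].dropna())
    if not genes:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return genes


def write_gene_list(
    genes: Iterable[str], path: str | Path, column: str = "gene_symbol", sep: str = "\t"
) -> None:
    pd.DataFrame({column: sorted(genes)}).to_csv(path, sep=sep, index=False, lineterminator="\n")


def write_result_table(
    frame: pd.DataFrame, path: str | Path, sep: str = "\t", **params: object
) -> None:
    """Write an output table with a leading provenance comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_line(**params) + "\n")
        frame.to_csv(fh, sep=sep, index=False, lineterminator="\n")
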