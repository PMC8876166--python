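"""Seeded generator of coupled transcriptome/miRNome datasets with truth.

The generator emulates the statistical structure of a two-tissue stromal
cell comparison: eight samples per group, log-normal baseline abundances
with a deliberate sub-floor tail (to exercise expression filtering), a
configurable fraction of truly differentially expressed genes and miRNAs
with multiplicative effects, and a repression layer in which a subset of
the DE genes are driven by DE miRNAs with anti-correlated log2 fold
changes.  Validated-interaction tables (true edges plus decoys attached
to non-DE genes), gene-set collections whose enriched terms over-sample
the true DE genes, secretome labels and a marker list biased toward the
top-expressed genes are emitted alongside a :class:`GroundTruth` record,
so every pipeline stage can be scored against the truth.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` with a fixed draw order: a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSet,
    GeneSetCollection,
    SampleSheet,
    merge_interactions,
    write_annotation,
    write_expression_table,
    write_gene_list,
    write_gmt,
    write_interactions,
    write_sample_sheet,
)

_DATABASES = ("TarBase", "miRecords", "miRTarBase")
_EVIDENCE = ("luciferase", "HITS-CLIP", "in-vitro")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the coupled two-layer simulation.

    Effect magnitudes follow |delta| = ``effect_size_base`` +
    Exponential(``effect_size_scale``) in log2 units, signs balanced.
    ``coupling_fraction`` of the true DE genes are driven by a DE miRNA
    with gene effect = -``repression_slope`` x miRNA effect plus a small
    Gaussian wobble (resampled so the anti-correlated sign is exact).
    Per-sample noise is multiplicative log-normal with coefficient of
    variation ``noise_cv``.  ``frac_sub_floor`` of the non-DE features are
    given baselines below one abundance unit so the expression filter has
    something to remove.
    """

    n_per_group: int = 8
    n_transcripts: int = 3000
    n_mirnas: int = 600
    transcripts_per_gene: tuple[int, int] = (1, 2)
    frac_de_genes: float = 0.2
    frac_de_mirnas: float = 0.1
    effect_size_base: float = 1.0
    effect_size_scale: float = 1.0
    coupling_fraction: float = 0.4
    repression_slope: float = 0.75
    coupling_noise_sd: float = 0.1
    decoy_edges_per_mirna: int = 5
    max_targets_per_mirna: int = 20
    noise_cv: float = 0.3
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    frac_sub_floor: float = 0.05
    frac_secreted: float = 0.12
    n_terms: int = 100
    n_enriched_terms: int = 10
    term_size_range: tuple[int, int] = (10, 60)
    enriched_de_fraction: float = 0.6
    frac_discordant: float = 0.0
    n_markers: int = 100
    frac_marker_top: float = 0.5
    qpcr_log2fc: tuple[float, ...] = (0.0, 1.0, 2.0)
    ct_intercept: float = 30.0
    ct_slope: float = 1.0
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_de_genes",
            "frac_de_mirnas",
            "coupling_fraction",
            "frac_sub_floor",
            "frac_secreted",
            "enriched_de_fraction",
            "frac_discordant",
            "frac_marker_top",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.repression_slope <= 0:
            raise ValueError("repression_slope must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        lo, hi = self.transcripts_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("transcripts_per_gene must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class GroundTruth:
    """The simulator's record of what is actually true in a dataset."""

    true_de_genes: dict[str, float]
    true_de_mirnas: dict[str, float]
    true_edges: frozenset[tuple[str, str]]
    decoy_edges: frozenset[tuple[str, str]]
    enriched_terms: frozenset[str]
    secreted_genes: frozenset[str]


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything a pipeline run needs, plus the truth to score against."""

    transcripts: ExpressionMatrix
    mirnas: ExpressionMatrix
    annotation: FeatureAnnotation
    interactions: pd.DataFrame
    gene_sets: GeneSetCollection
    secreted_genes: frozenset[str]
    marker_genes: frozenset[str]
    sample_sheet: SampleSheet
    truth: GroundTruth
    config: SimulationConfig


def _effect_sizes(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    magnitudes = cfg.effect_size_base + rng.exponential(cfg.effect_size_scale, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return signs * magnitudes


def _baselines(
    rng: np.random.Generator, n: int, sub_floor_mask: np.ndarray, cfg: SimulationConfig
) -> np.ndarray:
    """Log-normal baselines; masked features are forced below one unit."""
    log2_b = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    # resample until comfortably above the abundance floor, so that group
    # effects and sampling noise rarely push a non-flagged feature under it
    for _ in range(100):
        low = (log2_b < 0.5) & ~sub_floor_mask
        if not low.any():
            break
        log2_b[low] = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=int(low.sum()))
    log2_b[sub_floor_mask] = rng.uniform(-3.0, -0.7, size=int(sub_floor_mask.sum()))
    return 2.0**log2_b


def simulate_two_group_matrix(
    baselines: np.ndarray,
    log2_effects: np.ndarray,
    n_per_group: int,
    noise_cv: float,
    rng: np.random.Generator,
    feature_ids: list[str],
    ref_samples: list[str],
    test_samples: list[str],
    unit: str,
) -> ExpressionMatrix:
    """Abundance matrix: baseline x 2^effect (test group) x log-normal noise.

    The multiplicative noise has unit mean and coefficient of variation
    ``noise_cv``.  This low-level generator is shared by the full dataset
    simulation and by calibration experiments on a bare matrix.
    """
    n_features = len(baselines)
    n_total = 2 * n_per_group
    expected = np.tile(baselines[:, None], (1, n_total)).astype(float)
    expected[:, n_per_group:] *= 2.0 ** log2_effects[:, None]
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=expected.shape)
    else:
        noise = 1.0
    values = expected * noise
    frame = pd.DataFrame(values, index=feature_ids, columns=ref_samples + test_samples)
    return ExpressionMatrix(frame, unit)


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate one coupled transcriptome/miRNome dataset with ground truth."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- gene / transcript scaffold -------------------------------------
    lo, hi = cfg.transcripts_per_gene
    counts: list[int] = []
    total = 0
    while total < cfg.n_transcripts:
        c = int(rng.integers(lo, hi + 1))
        c = min(c, cfg.n_transcripts - total)
        counts.append(c)
        total += c
    n_genes = len(counts)
    genes = [f"Gene{i:05d}" for i in range(n_genes)]
    transcripts: list[str] = []
    tx_gene: list[str] = []
    for gene, c in zip(genes, counts):
        for j in range(c):
            transcripts.append(f"{gene}.t{j + 1}")
            tx_gene.append(gene)
    annotation = FeatureAnnotation(pd.Series(tx_gene, index=transcripts, name="gene_symbol"))

    mirnas = [f"miR-{i + 100}-5p" for i in range(cfg.n_mirnas)]

    # --- true effects ----------------------------------------------------
    n_de_genes = math.floor(cfg.frac_de_genes * n_genes)
    n_de_mirnas = math.floor(cfg.frac_de_mirnas * cfg.n_mirnas)
    de_gene_idx = rng.choice(n_genes, size=n_de_genes, replace=False)
    de_mirna_idx = rng.choice(cfg.n_mirnas, size=n_de_mirnas, replace=False)
    gene_effects = dict(zip((genes[i] for i in de_gene_idx), _effect_sizes(rng, n_de_genes, cfg)))
    mirna_effects = dict(
        zip((mirnas[i] for i in de_mirna_idx), _effect_sizes(rng, n_de_mirnas, cfg))
    )

    # --- miRNA -> gene coupling ------------------------------------------
    n_coupled = math.floor(cfg.coupling_fraction * n_de_genes)
    if n_coupled > 0 and n_de_mirnas == 0:
        raise ValueError("coupling requested but no DE miRNAs are available")
    if n_coupled > n_de_mirnas * cfg.max_targets_per_mirna:
        raise ValueError(
            f"coupling_fraction needs {n_coupled} driven genes but capacity is "
            f"{n_de_mirnas} DE miRNAs x {cfg.max_targets_per_mirna} targets"
        )
    coupled_genes = [genes[i] for i in de_gene_idx[:n_coupled]]
    de_mirna_ids = [mirnas[i] for i in de_mirna_idx]
    true_edges: set[tuple[str, str]] = set()
    for j, gene in enumerate(coupled_genes):
        mirna = de_mirna_ids[j % n_de_mirnas]
        delta_m = mirna_effects[mirna]
        while True:
            delta_g = -cfg.repression_slope * delta_m + rng.normal(0.0, cfg.coupling_noise_sd)
            if np.sign(delta_g) == -np.sign(delta_m) and delta_g != 0:
                break
        gene_effects[gene] = float(delta_g)
        true_edges.add((mirna, gene))

    # --- decoy edges: DE miRNAs pointing at non-DE genes ------------------
    non_de_genes = [g for g in genes if g not in gene_effects]
    decoy_edges: set[tuple[str, str]] = set()
    for mirna in de_mirna_ids:
        k = min(cfg.decoy_edges_per_mirna, len(non_de_genes))
        for gi in rng.choice(len(non_de_genes), size=k, replace=False):
            decoy_edges.add((mirna, non_de_genes[int(gi)]))
    decoy_edges -= true_edges

    # --- transcript-level effects (copied from genes) ---------------------
    tx_effects = np.array([gene_effects.get(g, 0.0) for g in tx_gene])
    if cfg.frac_discordant > 0:
        multi = [
            g for g, c in zip(genes, counts) if c >= 2 and g in gene_effects and c > 0
        ]
        n_flip = math.floor(cfg.frac_discordant * len(multi))
        for g in (multi[int(i)] for i in rng.choice(len(multi), size=n_flip, replace=False)):
            tx_ids = [i for i, gg in enumerate(tx_gene) if gg == g]
            tx_effects[tx_ids[-1]] *= -1.0

    # --- baselines and matrices -------------------------------------------
    non_de_tx = np.array([g not in gene_effects for g in tx_gene])
    sub_tx = np.zeros(cfg.n_transcripts, dtype=bool)
    candidates = np.flatnonzero(non_de_tx)
    n_sub = min(math.floor(cfg.frac_sub_floor * cfg.n_transcripts), len(candidates))
    sub_tx[rng.choice(candidates, size=n_sub, replace=False)] = True
    tx_base = _baselines(rng, cfg.n_transcripts, sub_tx, cfg)

    mirna_is_de = np.array([m in mirna_effects for m in mirnas])
    sub_mi = np.zeros(cfg.n_mirnas, dtype=bool)
    candidates = np.flatnonzero(~mirna_is_de)
    n_sub = min(math.floor(cfg.frac_sub_floor * cfg.n_mirnas), len(candidates))
    sub_mi[rng.choice(candidates, size=n_sub, replace=False)] = True
    mi_base = _baselines(rng, cfg.n_mirnas, sub_mi, cfg)
    mi_effects = np.array([mirna_effects.get(m, 0.0) for m in mirnas])

    ref_samples = [f"iWAT_{i + 1}" for i in range(cfg.n_per_group)]
    test_samples = [f"PANC_{i + 1}" for i in range(cfg.n_per_group)]
    tx_matrix = simulate_two_group_matrix(
        tx_base, tx_effects, cfg.n_per_group, cfg.noise_cv, rng,
        transcripts, ref_samples, test_samples, "FPKM",
    )
    mi_matrix = simulate_two_group_matrix(
        mi_base, mi_effects, cfg.n_per_group, cfg.noise_cv, rng,
        mirnas, ref_samples, test_samples, "TPM",
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ref_samples + test_samples,
                "group": ["iWAT"] * cfg.n_per_group + ["PANC"] * cfg.n_per_group,
                "excluded": False,
            }
        )
    )

    # --- interaction table -------------------------------------------------
    edge_rows = []
    for mirna, gene in sorted(true_edges | decoy_edges):
        n_src = int(rng.integers(1, 3))
        src_idx = rng.choice(len(_DATABASES), size=n_src, replace=False)
        for si in src_idx:
            edge_rows.append(
                {
                    "mirna_id": mirna,
                    "gene_symbol": gene,
                    "source_db": _DATABASES[int(si)],
                    "evidence_type": _EVIDENCE[int(rng.integers(0, len(_EVIDENCE)))],
                }
            )
    interactions = merge_interactions(pd.DataFrame(edge_rows, columns=[
        "mirna_id", "gene_symbol", "source_db", "evidence_type"
    ]))

    # --- gene sets ----------------------------------------------------------
    de_gene_list = sorted(gene_effects)
    non_de_list = sorted(non_de_genes)
    terms = []
    enriched_ids = set()
    for t in range(cfg.n_terms):
        term_id = f"TERM{t:04d}"
        size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
        if t < cfg.n_enriched_terms and de_gene_list:
            n_de_members = min(round(cfg.enriched_de_fraction * size), len(de_gene_list))
            members = {
                de_gene_list[int(i)]
                for i in rng.choice(len(de_gene_list), size=n_de_members, replace=False)
            }
            n_rest = min(size - n_de_members, len(non_de_list))
            members |= {
                non_de_list[int(i)]
                for i in rng.choice(len(non_de_list), size=n_rest, replace=False)
            }
            enriched_ids.add(term_id)
            name = f"enriched process {t}"
        else:
            members = {genes[int(i)] for i in rng.choice(n_genes, size=min(size, n_genes), replace=False)}
            name = f"background process {t}"
        terms.append(GeneSet(term_id, name, frozenset(members)))
    gene_sets = GeneSetCollection(tuple(terms))

    # --- secretome labels and markers ---------------------------------------
    n_secreted = math.floor(cfg.frac_secreted * n_genes)
    secreted = frozenset(genes[int(i)] for i in rng.choice(n_genes, size=n_secreted, replace=False))

    gene_test_mean = pd.Series(0.0, index=genes)
    tx_test_mean = tx_base * 2.0**tx_effects
    for tx, g, v in zip(transcripts, tx_gene, tx_test_mean):
        gene_test_mean[g] += v
    top_pool = gene_test_mean.sort_values(ascending=False, kind="mergesort").index[:1000].tolist()
    n_top = min(math.floor(cfg.frac_marker_top * cfg.n_markers), len(top_pool))
    markers = {top_pool[int(i)] for i in rng.choice(len(top_pool), size=n_top, replace=False)}
    # the remainder is drawn uniformly from the whole gene universe, so the
    # marker list mixes a top-expressed core with background genes
    rest_pool = [g for g in genes if g not in markers]
    n_rest = min(cfg.n_markers - n_top, len(rest_pool))
    markers |= {rest_pool[int(i)] for i in rng.choice(len(rest_pool), size=n_rest, replace=False)}

    truth = GroundTruth(
        true_de_genes={g: float(v) for g, v in sorted(gene_effects.items())},
        true_de_mirnas={m: float(v) for m, v in sorted(mirna_effects.items())},
        true_edges=frozenset(true_edges),
        decoy_edges=frozenset(decoy_edges),
        enriched_terms=frozenset(enriched_ids),
        secreted_genes=secreted,
    )
    return SimulatedDataset(
        transcripts=tx_matrix,
        mirnas=mi_matrix,
        annotation=annotation,
        interactions=interactions,
        gene_sets=gene_sets,
        secreted_genes=secreted,
        marker_genes=frozenset(markers),
        sample_sheet=sheet,
        truth=truth,
        config=cfg,
    )


def simulate_ct_table(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a long-format qPCR Ct table with a non-DE reference gene.

    Ct = intercept - slope x log2(expression) + Gaussian noise.  Target
    genes carry the group log2 fold changes from ``config.qpcr_log2fc``;
    the reference gene (Eef2) is flat.  Returns the table and a truth dict
    recording the fold changes and the Ct model parameters.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    ref_samples = [f"iWAT_{i + 1}" for i in range(cfg.n_per_group)]
    test_samples = [f"PANC_{i + 1}" for i in range(cfg.n_per_group)]
    genes = {"Eef2": (2.0**10, 0.0)}
    for i, lfc in enumerate(cfg.qpcr_log2fc):
        genes[f"Target{i + 1}"] = (2.0**8, float(lfc))
    rows = []
    for gene, (base, lfc) in genes.items():
        for sample in ref_samples + test_samples:
            expr = base * (2.0**lfc if sample in test_samples else 1.0)
            ct = cfg.ct_intercept - cfg.ct_slope * math.log2(expr)
            if cfg.ct_noise_sd > 0:
                ct += rng.normal(0.0, cfg.ct_noise_sd)
            rows.append({"sample_id": sample, "gene": gene, "ct": ct})
    truth = {
        "log2fc": {f"Target{i + 1}": float(l) for i, l in enumerate(cfg.qpcr_log2fc)},
        "intercept": cfg.ct_intercept,
        "slope": cfg.ct_slope,
        "reference_gene": "Eef2",
    }
    return pd.DataFrame(rows), truth


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write every simulated table in the pipeline's canonical formats.

    Returns a name -> relative path map of everything written; rerunning
    with the same dataset produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": "transcripts.tsv",
        "mirnas": "mirnas.tsv",
        "samples": "samples.tsv",
        "annotation": "annotation.tsv",
        "interactions": "interactions.tsv",
        "gene_sets": "gene_sets.gmt",
        "secreted": "secreted.tsv",
        "markers": "markers.tsv",
        "truth_genes": "truth_genes.tsv",
        "truth_mirnas": "truth_mirnas.tsv",
        "truth_edges": "truth_edges.tsv",
        "truth_terms": "truth_terms.tsv",
    }
    write_expression_table(dataset.transcripts, outdir / paths["transcripts"])
    write_expression_table(dataset.mirnas, outdir / paths["mirnas"])
    write_sample_sheet(dataset.sample_sheet, outdir / paths["samples"])
    write_annotation(dataset.annotation, outdir / paths["annotation"])
    write_interactions(dataset.interactions, outdir / paths["interactions"])
    write_gmt(dataset.gene_sets, outdir / paths["gene_sets"])
    write_gene_list(dataset.secreted_genes, outdir / paths["secreted"])
    write_gene_list(dataset.marker_genes, outdir / paths["markers"])

    truth = dataset.truth
    pd.DataFrame(
        sorted(truth.true_de_genes.items()), columns=["gene_symbol", "log2_effect"]
    ).to_csv(outdir / paths["truth_genes"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        sorted(truth.true_de_mirnas.items()), columns=["mirna_id", "log2_effect"]
    ).to_csv(outdir / paths["truth_mirnas"], sep="\t", index=False, lineterminator="\n")
    edges = [(m, g, "true") for m, g in sorted(truth.true_edges)] + [
        (m, g, "decoy") for m, g in sorted(truth.decoy_edges)
    ]
    pd.DataFrame(edges, columns=["mirna_id", "gene_symbol", "kind"]).to_csv(
        outdir / paths["truth_edges"], sep="\t", index=False, lineterminator="\n"
    )
    pd.DataFrame({"term_id": sorted(truth.enriched_terms)}).to_csv(
        outdir / paths["truth_terms"], sep="\t", index=False, lineterminator="\n"
    )
    return paths
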