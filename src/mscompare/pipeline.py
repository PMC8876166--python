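"""End-to-end orchestration: ingest/simulate -> filter -> DE -> integrate
-> enrich -> secretome -> marker overlap, with a machine-readable manifest.

Every stage writes its intermediate table into the output directory; the
run ends with ``summary.json`` (headline counts) and ``manifest.json``
(package version, effective configuration, SHA-256 checksums of every
input and output).  Stage outputs are pure functions of the inputs and
configuration: rerunning the same configuration produces byte-identical
files, which the manifest checksums make easy to verify.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexp import (
    Thresholds,
    classify_de,
    collapse_to_genes,
    filter_low_expression,
    flag_outlier_samples,
    welch_de,
)
from .enrichment import hypergeom_enrich, marker_overlap_fisher
from .integration import (
    map_and_filter_targets,
    select_exclusive_mirnas,
    summarize_integration,
)
from .io import (
    ExpressionMatrix,
    read_annotation,
    read_expression_table,
    read_gene_list,
    read_gmt,
    read_interaction_table,
    read_sample_sheet,
    write_result_table,
)
from .qpcr import relative_expression_table, summarize_by_group
from .secretome import annotate_secretome, top_secreted
from .simulate import SimulationConfig, simulate_ct_table, simulate_dataset, write_dataset

logger = logging.getLogger("mscompare")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Either ``simulate`` is set (a :class:`SimulationConfig`, inputs are
    generated into ``outdir/inputs``) or the explicit input paths are.
    """

    outdir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference: str = "iWAT"
    test: str = "PANC"
    transcripts: str | None = None
    mirnas: str | None = None
    samples: str | None = None
    annotation: str | None = None
    interactions: str | None = None
    gene_sets: str | None = None
    secreted: str | None = None
    markers: str | None = None
    simulate: SimulationConfig | None = None
    min_median_corr: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        sim = raw.pop("simulate", None)
        sim_cfg = None
        if sim is not None:
            for key in ("transcripts_per_gene", "term_size_range", "qpcr_log2fc"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim_cfg = SimulationConfig(**sim)
        return cls(thresholds=thresholds, simulate=sim_cfg, **raw)

    def to_dict(self) -> dict:
        # outdir is deliberately omitted so manifests of identical runs
        # into different directories stay byte-identical
        out = dataclasses.asdict(self)
        out.pop("outdir", None)
        return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _require(path: str | None, name: str, stage: str) -> str:
    if path is None:
        raise PipelineError(stage, f"missing required input: {name}")
    if not Path(path).exists():
        raise PipelineError(stage, f"{name} table not found: {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    outputs: dict[str, Path] = {}
    inputs: dict[str, Path] = {}
    summary: dict[str, object] = {}

    def emit(name: str, frame: pd.DataFrame, **params: object) -> None:
        path = outdir / f"{name}.tsv"
        write_result_table(frame, path, **params)
        outputs[name] = path

    # --- stage: inputs ----------------------------------------------------
    stage = "inputs"
    logger.info("stage %s", stage)
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.simulate.seed or config.seed)
            dataset = simulate_dataset(sim)
            in_dir = outdir / "inputs"
            rel = write_dataset(dataset, in_dir)
            inputs = {k: in_dir / v for k, v in rel.items()}
            tx, mi = dataset.transcripts, dataset.mirnas
            sheet = dataset.sample_sheet
            sheet.reference, sheet.test = config.reference, config.test
            annotation = dataset.annotation
            interactions = dataset.interactions
            gene_sets = dataset.gene_sets
            secreted = set(dataset.secreted_genes)
            markers = set(dataset.marker_genes)
            ct_table, _ = simulate_ct_table(sim)
            ct_path = in_dir / "ct_values.tsv"
            ct_table.to_csv(ct_path, sep="\t", index=False, lineterminator="\n")
            inputs["ct_values"] = ct_path
        else:
            tx = read_expression_table(_require(config.transcripts, "transcripts", stage), "FPKM")
            mi = read_expression_table(_require(config.mirnas, "mirnas", stage), "TPM")
            sheet = read_sample_sheet(
                _require(config.samples, "samples", stage),
                reference=config.reference,
                test=config.test,
            )
            annotation = read_annotation(_require(config.annotation, "annotation", stage))
            interactions = read_interaction_table(
                _require(config.interactions, "interactions", stage)
            )
            gene_sets = read_gmt(_require(config.gene_sets, "gene_sets", stage))
            secreted = read_gene_list(_require(config.secreted, "secreted", stage))
            markers = (
                read_gene_list(config.markers) if config.markers else set()
            )
            ct_table = None
            inputs = {
                k: Path(getattr(config, k))
                for k in (
                    "transcripts", "mirnas", "samples", "annotation",
                    "interactions", "gene_sets", "secreted",
                )
            }
            if config.markers:
                inputs["markers"] = Path(config.markers)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: filter ------------------------------------------------------
    stage = "filter"
    logger.info("stage %s", stage)
    try:
        tx_f = filter_low_expression(tx, th.expr_floor, sheet)
        mi_f = filter_low_expression(mi, th.expr_floor, sheet)
        summary["n_transcripts_tested"] = tx_f.n_features
        summary["n_mirnas_tested"] = mi_f.n_features
        summary["outlier_flags_transcripts"] = flag_outlier_samples(
            tx_f, config.min_median_corr
        )
        summary["outlier_flags_mirnas"] = flag_outlier_samples(mi_f, config.min_median_corr)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: differential expression -------------------------------------
    stage = "diffexp"
    logger.info("stage %s", stage)
    try:
        de_tx = welch_de(tx_f, sheet, th)
        de_mi = welch_de(mi_f, sheet, th)
        up_tx, down_tx = classify_de(de_tx)
        up_mi, down_mi = classify_de(de_mi)
        degs = collapse_to_genes(de_tx, annotation)
        emit("de_transcripts", de_tx, layer="transcripts", alpha=th.alpha)
        emit("de_mirnas", de_mi, layer="mirnas", alpha=th.alpha)
        emit("degs", degs, layer="genes", alpha=th.alpha)
        summary.update(
            n_de_transcripts=len(up_tx) + len(down_tx),
            n_transcripts_up=len(up_tx),
            n_transcripts_down=len(down_tx),
            n_degs=len(degs),
            n_degs_up=int((degs["direction"] == "up").sum()),
            n_degs_down=int((degs["direction"] == "down").sum()),
            n_degs_discordant=int((degs["direction"] == "discordant").sum()),
            n_de_mirnas=len(up_mi) + len(down_mi),
            n_mirnas_up=len(up_mi),
            n_mirnas_down=len(down_mi),
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: integration ---------------------------------------------------
    stage = "integration"
    logger.info("stage %s", stage)
    try:
        if interactions is None or interactions.empty:
            raise ValueError("interaction table is missing or empty")
        ref_excl, test_excl = select_exclusive_mirnas(de_mi, th)
        pairs = map_and_filter_targets(de_mi, degs, interactions, th)
        integ = summarize_integration(pairs, degs) if len(degs) else None
        emit("consistent_pairs", pairs, highlight_lfc=th.highlight_lfc)
        emit(
            "exclusive_mirnas",
            pd.DataFrame(
                [(m, config.reference) for m in sorted(ref_excl)]
                + [(m, config.test) for m in sorted(test_excl)],
                columns=["mirna_id", "side"],
            ),
            exclusive_lfc=th.exclusive_lfc,
        )
        summary.update(
            n_exclusive_ref=len(ref_excl),
            n_exclusive_test=len(test_excl),
            n_consistent_pairs=len(pairs),
            n_de_mirnas_with_targets=integ.n_de_mirnas_with_targets if integ else 0,
            n_regulated_genes=integ.n_regulated_genes if integ else 0,
            fraction_degs_explained=integ.fraction_degs_explained if integ else None,
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: enrichment -----------------------------------------------------
    stage = "enrichment"
    logger.info("stage %s", stage)
    try:
        expressed_genes = {
            annotation.gene_for(t) for t in tx_f.feature_ids if t in annotation.mapping.index
        }
        deg_query = set(degs["gene_symbol"]) & expressed_genes
        directions = dict(
            zip(degs["gene_symbol"], degs["direction"])
        )
        enr = hypergeom_enrich(
            deg_query, gene_sets, expressed_genes, directions, th, min_count=th.min_count_deg
        )
        emit("enrichment_degs", enr, gates=f"k>={th.min_count_deg},fe>{th.min_fold_enrichment}")
        summary["n_enrichment_terms"] = len(enr)
        summary["n_enrichment_pass"] = int(enr["passes"].sum()) if len(enr) else 0

        for side, label in (("down", "test"), ("up", "ref")):
            # targets repressed by miRNAs high in `label` tissue move opposite
            side_genes = set(
                pairs.loc[
                    (pairs["gene_log2fc"] < 0) if side == "down" else (pairs["gene_log2fc"] > 0),
                    "gene_symbol",
                ]
            ) & expressed_genes
            enr_t = hypergeom_enrich(
                side_genes, gene_sets, expressed_genes, directions, th,
                min_count=th.min_count_target,
            )
            emit(f"enrichment_targets_{label}", enr_t, side=label)
            summary[f"n_target_terms_pass_{label}"] = (
                int(enr_t["passes"].sum()) if len(enr_t) else 0
            )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: secretome -------------------------------------------------------
    stage = "secretome"
    logger.info("stage %s", stage)
    try:
        partition = annotate_secretome(degs, secreted)
        top_test, top_ref = top_secreted(partition, degs, k=10)
        part_frame = pd.DataFrame(
            [(g, "up_test") for g in sorted(partition.up_test)]
            + [(g, "up_ref") for g in sorted(partition.up_ref)]
            + [(g, "discordant") for g in sorted(partition.discordant)],
            columns=["gene_symbol", "side"],
        )
        emit("secretome_partition", part_frame)
        emit("top_secreted_test", top_test)
        emit("top_secreted_ref", top_ref)
        summary.update(
            n_secreted_up_test=len(partition.up_test),
            n_secreted_up_ref=len(partition.up_ref),
            n_secreted_discordant=len(partition.discordant),
            n_secreted_total=partition.n_secreted_total,
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: marker overlap ----------------------------------------------------
    stage = "marker_overlap"
    logger.info("stage %s", stage)
    try:
        if markers:
            gene_expr = tx_f.data.copy()
            gene_expr["gene"] = [annotation.gene_for(t) for t in tx_f.feature_ids]
            gene_matrix = ExpressionMatrix(
                gene_expr.groupby("gene").sum().sort_index(), tx_f.unit
            )
            test_matrix = gene_matrix.subset_samples(sheet.samples_for(sheet.test))
            top_n = min(th.top_n_expressed, test_matrix.n_features - 1)
            overlap = marker_overlap_fisher(test_matrix, markers, top_n=top_n)
            emit(
                "marker_overlap",
                pd.DataFrame([dataclasses.asdict(overlap)]),
            )
            summary.update(
                marker_odds_ratio=overlap.odds_ratio,
                marker_p_value=overlap.p_value,
            )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: qpcr ----------------------------------------------------------------
    stage = "qpcr"
    logger.info("stage %s", stage)
    try:
        if config.simulate is not None and ct_table is not None:
            rel = relative_expression_table(ct_table)
            groups = sheet.frame.set_index("sample_id")["group"]
            emit("qpcr_relative", rel, reference="Eef2")
            emit("qpcr_groups", summarize_by_group(rel, groups))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- manifest ---------------------------------------------------------------------
    summary_path = outdir / "summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    outputs["summary"] = summary_path

    manifest = {
        "version": __version__,
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "inputs": {
            k: {"path": str(p.relative_to(outdir)) if p.is_relative_to(outdir) else str(p.name),
                "sha256": _sha256(p)}
            for k, p in sorted(inputs.items())
        },
        "outputs": {
            k: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for k, p in sorted(outputs.items())
        },
        "summary": json.loads(json.dumps(summary, default=str)),
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return manifest
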