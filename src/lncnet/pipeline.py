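"""End-to-end orchestration of the analysis stages.

``run_pipeline`` wires the stages together as pure functions of the inputs
plus configuration: differential expression for both biotypes, top-lncRNA
selection and CNC network construction, genomic-context classification and
cis/antisense pairing, gene-set enrichment with lncRNA projection, and
optional Ct-table validation.  A manifest records versions, seed,
thresholds and per-stage counts; identical inputs and config reproduce
byte-identical result tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import lncnet
from lncnet import cnc, diffexp, enrichment, genomic_context, validation
from lncnet.io import (
    AnnotationTable,
    ExpressionMatrix,
    GeneSets,
    read_annotation,
    read_gmt,
    read_series_matrix,
    read_table,
    write_edge_list,
    write_table,
)

logger = logging.getLogger("lncnet.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for actionable CLI messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input locations, group patterns and every analysis threshold."""

    matrix_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    ct_path: str | None = None
    outdir: str | None = None
    group_patterns: dict = field(
        default_factory=lambda: {"control": "group: control", "treated": "group: treated"}
    )
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    t_variant: str = "student"
    top_k: int = 50
    top_p: float = 0.01
    pcc_threshold: float = 0.9
    pair_p: float = 0.05
    pair_fdr: float = 1.0
    fdr_family: str = "global"
    cis_distance: int = 300_000
    bidir_window: int = 1000
    enrich_score: float = 1.3
    seed: int = 0

    def validate(self) -> None:
        positive = ["fc_threshold", "p_threshold", "top_k", "top_p", "pcc_threshold",
                    "pair_p", "pair_fdr", "cis_distance", "bidir_window", "enrich_score"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    network: cnc.CncNetwork
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    annotation: AnnotationTable | None = None,
    gene_sets: GeneSets | None = None,
    ct_table: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every stage; in-memory inputs take precedence over paths.

    Writes all result tables plus ``manifest.json`` under
    ``config.outdir`` when set.  Any stage failure raises
    :class:`PipelineStageError` labeled with the stage name.
    """
    config.validate()

    @_stage("inputs")
    def load_inputs():
        m = matrix
        if m is None:
            if config.matrix_path is None:
                raise ValueError("no expression matrix (path or object) provided")
            m = read_series_matrix(config.matrix_path, config.group_patterns)
        a = annotation
        if a is None:
            if config.annotation_path is None:
                raise ValueError("no annotation provided; classification and "
                                 "pairing require coordinates")
            a = read_annotation(config.annotation_path)
        gs = gene_sets
        if gs is None and config.gmt_path is not None:
            gs = read_gmt(config.gmt_path)
        ct = ct_table
        if ct is None and config.ct_path is not None:
            ct = read_table(config.ct_path)
        return m, a, gs, ct

    mat, annot, gsets, ct = load_inputs()
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int | float] = {}

    @_stage("diffexp")
    def stage_de():
        in_matrix = set(mat.feature_ids)
        by_bio = {}
        for biotype in ("mRNA", "lncRNA"):
            ids = [f for f in annot.of_biotype(biotype).feature_ids if f in in_matrix]
            if not ids:
                raise ValueError(f"no {biotype} features shared by matrix and annotation")
            res = diffexp.call_dysregulated(
                mat, ids, config.fc_threshold, config.p_threshold, config.t_variant
            )
            by_bio[biotype] = res
            key = "mrna" if biotype == "mRNA" else "lnc"
            tables[f"de_{key}_full"] = res.table
            tables[f"de_{key}"] = res.dysregulated
            counts[f"{key}_tested"] = res.n_tested
            counts[f"{key}_up"] = res.n_up
            counts[f"{key}_down"] = res.n_down
            counts[f"{key}_profile_correlation"] = diffexp.group_profile_correlation(
                mat, ids
            )
        return by_bio

    de = stage_de()

    @_stage("cnc")
    def stage_cnc():
        top = cnc.select_top_lncrnas(de["lncRNA"].dysregulated, config.top_k, config.top_p)
        net = cnc.build_cnc(
            mat,
            top,
            list(de["mRNA"].dysregulated["feature_id"]),
            config.pcc_threshold,
            config.pair_p,
            config.pair_fdr,
            config.fdr_family,
        )
        tables["cnc_edges"] = net.edges
        counts["top_lncs"] = len(top)
        counts["cnc_edges"] = net.n_edges
        counts["cnc_lnc_nodes"] = len(net.lnc_nodes)
        counts["cnc_mrna_nodes"] = len(net.mrna_nodes)
        return net

    network = stage_cnc()

    @_stage("classify")
    def stage_classify():
        de_lnc_ids = list(de["lncRNA"].dysregulated["feature_id"])
        classes = genomic_context.classify_all(
            annot, config.bidir_window, lnc_ids=de_lnc_ids
        )
        tables["lnc_classes"] = classes
        tables["class_composition"] = genomic_context.class_composition(classes)
        counts["classified_lncs"] = len(classes)

    stage_classify()

    @_stage("pairs")
    def stage_pairs():
        anti = genomic_context.antisense_dysregulated_pairs(
            de["lncRNA"].dysregulated, de["mRNA"].dysregulated, annot
        )
        near = genomic_context.nearby_dysregulated_pairs(
            de["lncRNA"].dysregulated, de["mRNA"].dysregulated, annot,
            config.cis_distance,
        )
        tables["antisense_pairs"] = anti
        tables["cis_pairs"] = near
        counts["antisense_pairs"] = len(anti)
        counts["cis_pairs"] = len(near)

    stage_pairs()

    @_stage("enrichment")
    def stage_enrich():
        if gsets is None:
            logger.info("no gene sets provided; enrichment skipped")
            return
        symbol_of = dict(zip(annot.table["feature_id"], annot.table["symbol"]))
        mrna_all = annot.of_biotype("mRNA").table
        background = list(mrna_all["symbol"])
        query = [
            symbol_of.get(f, f) for f in de["mRNA"].dysregulated["feature_id"]
        ]
        enr = enrichment.fisher_enrich(query, gsets, background)
        proj = enrichment.lncrna_pathway_projection(
            network, enr, config.enrich_score, symbol_of
        )
        tables["enrichment"] = enr
        tables["lnc_pathway_projection"] = proj
        counts["enriched_sets"] = int((enr["score"] >= config.enrich_score).sum())

    stage_enrich()

    @_stage("validation")
    def stage_validate():
        if ct is None:
            return
        tables["qpcr_relative_expression"] = validation.relative_expression_table(ct)

    stage_validate()

    manifest = {
        "versions": {
            "lncnet": lncnet.__version__,
            "numpy": __import__("numpy").__version__,
            "scipy": __import__("scipy").__version__,
            "pandas": pd.__version__,
        },
        # outdir is where results land, not part of the analysis definition
        "config": {k: v for k, v in asdict(config).items() if k != "outdir"},
        "counts": counts,
        "network": network.summary(),
    }

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            if name == "cnc_edges":
                write_edge_list(df, out / "cnc_edges.tsv")
            else:
                write_table(df, out / f"{name}.tsv")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    return PipelineResult(tables=tables, network=network, manifest=manifest)
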