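"""End-to-end orchestration of the analysis as composable stages.

Stages: ``simulate`` (synthetic cohort with ground truth), ``deg``
(responder vs non-responder screen), ``genes`` (six-classifier benchmark +
concordance gene selection), ``pathway`` (gene-pathway encodings, CNNs,
Grad-CAM, spots), ``signature`` (bulk signature scoring + survival). Each
stage reads its inputs from the run directory when an earlier stage
produced them, or from ``config.paths`` otherwise, and writes plain-text
artifacts plus a manifest with per-file checksums.

A single global seed fans out to per-stage derived seeds (seed + stage
index) so stages can be rerun in isolation reproducibly; the manifest
carries no timestamps, so identical configs give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, deg as deg_mod, io, models, pathway as pw, simulate as sim, survival as surv
from .config import PipelineConfig, validate_config
from .containers import ExpressionMatrix
from .errors import PipelineStageError, ScResponseError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "deg", "genes", "pathway", "signature")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    doc = config.to_dict()
    doc.pop("outdir", None)
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _sim_config(config: PipelineConfig) -> sim.SimConfig:
    s = config.simulate
    return sim.SimConfig(
        seed=config.seed,
        n_samples_responder=s["n_samples_responder"],
        n_samples_nonresponder=s["n_samples_nonresponder"],
        cells_per_sample=s["cells_per_sample"],
        n_genes=s["n_genes"],
        n_deg_up_responder=s["n_deg_up_responder"],
        n_deg_up_nonresponder=s["n_deg_up_nonresponder"],
        deg_log2fc=s["deg_log2fc"],
        dropout_rate=s["dropout_rate"],
        bimodal_gene=s["bimodal_gene"],
        bimodal_separation=s["bimodal_separation"],
        noise_sd=s["noise_sd"],
        sample_effect_sd=s["sample_effect_sd"],
        pathway_spec=sim.PathwaySpec(
            n_pathways=s["n_pathways"],
            genes_per_pathway=s["genes_per_pathway"],
            spot_genes=s["spot_genes"],
            spot_pathways=s["spot_pathways"],
        ),
        bulk_spec=sim.BulkSpec(
            n_samples=s["bulk_n_samples"],
            hazard_log_ratio=s["bulk_hazard_log_ratio"],
            censoring_rate=s["bulk_censoring_rate"],
        ),
    )


def _input_path(outdir: Path, name: str, config: PipelineConfig, key: str) -> Path:
    candidate = outdir / name
    if candidate.exists():
        return candidate
    configured = config.paths.get(key)
    if configured:
        return Path(configured)
    raise ScResponseError(
        f"stage input {name!r} not found in run directory and paths.{key} not configured"
    )


def validate_inputs(config: PipelineConfig) -> None:
    """Fail before any compute if a configured input path is missing."""
    for key, value in config.paths.items():
        if value is not None and not Path(value).exists():
            raise PipelineStageError("validate", "missing-input", f"paths.{key} does not exist: {value}")


def run_pipeline(config: PipelineConfig | dict | str | Path | None) -> Path:
    """Run the configured stages; returns the run directory.

    The manifest (``manifest.json``) records the normalized config, its
    hash, per-stage derived seeds and output checksums; stage failures halt
    the run with the stage name and a machine-readable code while partial
    outputs are retained.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("scresponse")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    validate_inputs(config)
    for key, prov in sorted(config.provenance.items()):
        logger.info("config %s provenance=%s", key, prov)

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "stages": {},
    }
    runners = {
        "simulate": _stage_simulate,
        "deg": _stage_deg,
        "genes": _stage_genes,
        "pathway": _stage_pathway,
        "signature": _stage_signature,
    }
    try:
        for index, stage in enumerate(STAGE_ORDER):
            if stage not in config.stages:
                manifest["stages"][stage] = {"status": "skipped"}
                continue
            stage_seed = config.seed + index
            logger.info("stage %s starting (seed %d)", stage, stage_seed)
            try:
                outputs = runners[stage](config, outdir, stage_seed)
            except ScResponseError as exc:
                raise PipelineStageError(stage, "stage-error", str(exc)) from exc
            manifest["stages"][stage] = {
                "status": "completed",
                "seed": stage_seed,
                "outputs": {name: _sha256(outdir / name) for name in sorted(outputs)},
            }
            logger.info("stage %s completed: %s", stage, sorted(outputs))
    finally:
        io.write_json(manifest, outdir / "manifest.json")
        root.removeHandler(handler)
        handler.close()
    return outdir


# ------------------------------------------------------------------ stages
def _stage_simulate(config: PipelineConfig, outdir: Path, seed: int) -> list[str]:
    sc = _sim_config(config)
    X, meta, truth = sim.simulate_single_cell_cohort(sc)
    sets = sim.simulate_gene_sets(sc)
    io.write_expression_matrix(X, outdir / "matrix.tsv")
    io.write_metadata(meta, outdir / "metadata.tsv")
    io.write_gmt(sets, outdir / "gene_sets.gmt")
    io.write_json(truth.to_dict(), outdir / "truth.json")
    return ["matrix.tsv", "metadata.tsv", "gene_sets.gmt", "truth.json"]


def _load_matrix_meta(config: PipelineConfig, outdir: Path):
    X = io.read_expression_matrix(_input_path(outdir, "matrix.tsv", config, "matrix"))
    meta = io.read_metadata(_input_path(outdir, "metadata.tsv", config, "metadata"))
    from .containers import align_metadata

    meta = align_metadata(X, meta)
    return X, meta


def _stage_deg(config: PipelineConfig, outdir: Path, seed: int) -> list[str]:
    X, meta = _load_matrix_meta(config, outdir)
    d = config.deg
    table = deg_mod.deg_screen(
        X,
        meta["response"],
        mode=d["mode"],
        alpha=d["alpha"],
        fc_threshold=d["fc_threshold"],
        fc_method=d["fc_method"],
        min_pct=d["min_pct"],
    )
    table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
    flagged = table.loc[table["passes"], "gene"].tolist()
    (outdir / "deg_genes.txt").write_text("\n".join(flagged) + ("\n" if flagged else ""))
    logger.info("deg: %d/%d genes flagged", len(flagged), len(table))
    return ["deg_table.tsv", "deg_genes.txt"]


def _stage_genes(config: PipelineConfig, outdir: Path, seed: int) -> list[str]:
    X, meta = _load_matrix_meta(config, outdir)
    deg_path = outdir / "deg_genes.txt"
    if not deg_path.exists():
        raise ScResponseError("genes stage requires the deg stage output (deg_genes.txt)")
    deg_genes = [g for g in deg_path.read_text().splitlines() if g]
    if not deg_genes:
        raise ScResponseError("no DEGs available as model features")
    g = config.genes
    sub = X.subset(genes=deg_genes)
    result = models.benchmark_gene_models(
        sub.values,
        meta["response"].to_numpy(),
        meta=meta,
        feature_names=deg_genes,
        models=tuple(g["models"]),
        split_spec=models.SplitSpec(unit=g["split_unit"], test_fraction=g["test_fraction"], seed=seed),
        cv_folds=g["cv_folds"],
        n_iter=g["n_iter"],
        seed=seed,
        pooled_scaling=g["scaling"] == "pooled",
    )
    if g["scaling"] == "pooled":
        logger.warning("genes: pooled scaling requested (protocol-faithful, leakage-prone)")
    report_doc = {name: rep.to_dict() for name, rep in result["reports"].items()}
    report_doc["_split"] = {
        "train_idx": result["train_idx"].tolist(),
        "test_idx": result["test_idx"].tolist(),
    }
    io.write_json(report_doc, outdir / "gene_models.json")
    outputs = ["gene_models.json"]

    tree_present = [m for m in ("xgboost", "random_forest") if m in result["models"]]
    if len(tree_present) == 2:
        ra = models.tree_importances(result["models"]["xgboost"], deg_genes)
        rb = models.tree_importances(result["models"]["random_forest"], deg_genes)
        selected, rho, pval = models.concordant_gene_selection(ra, rb, top_n=g["top_n"])
        imp = pd.DataFrame(
            {
                "gene": deg_genes,
                "xgboost_importance": ra.importances.loc[deg_genes].to_numpy(),
                "xgboost_rank": ra.ranks.loc[deg_genes].to_numpy(),
                "random_forest_importance": rb.importances.loc[deg_genes].to_numpy(),
                "random_forest_rank": rb.ranks.loc[deg_genes].to_numpy(),
            }
        )
        imp.to_csv(outdir / "importances.tsv", sep="\t", index=False)
        io.write_json(
            {"selected_genes": selected, "spearman_r": rho, "spearman_p": pval, "top_n": g["top_n"]},
            outdir / "concordant_genes.json",
        )
        outputs += ["importances.tsv", "concordant_genes.json"]

    if g["resampling_splits"] >= 2:
        fast = {
            name: est
            for name, est in result["models"].items()
            if name in ("xgboost", "random_forest", "logistic_regression", "svm", "fnn")
        }
        stability = models.resampling_stability(
            sub.values,
            result["labels"],
            fast,
            n_splits=g["resampling_splits"],
            test_fraction=g["test_fraction"],
            base_seed=seed,
            original_aucs={n: r.auc for n, r in result["reports"].items() if n in fast},
        )
        doc = {
            "mean": stability["mean"],
            "ci95": stability["ci95"],
            "n_splits": g["resampling_splits"],
        }
        if "correlation_with_original" in stability:
            doc["correlation_with_original"] = list(stability["correlation_with_original"])
        io.write_json(doc, outdir / "resampling.json")
        outputs.append("resampling.json")
    return outputs


def _stage_pathway(config: PipelineConfig, outdir: Path, seed: int) -> list[str]:
    X, meta = _load_matrix_meta(config, outdir)
    sets = io.read_gmt(_input_path(outdir, "gene_sets.gmt", config, "gene_sets"))
    p = config.pathway
    labels = meta["response"].to_numpy()
    split = models.stratified_split(meta, models.SplitSpec(seed=seed))

    outputs: list[str] = []
    reports: dict[str, dict] = {}
    if "cnn1d" in p["arch"] or p["baselines"]:
        pairs = pw.expand_gene_pathway_pairs(X, sets)
        pairs_cols = pd.Series(pairs.columns)
        pairs_cols.to_csv(outdir / "pair_columns.txt", sep="\t", index=False, header=False)
        outputs.append("pair_columns.txt")
        if "cnn1d" in p["arch"]:
            _, rep = pw.train_pathway_cnn1d(
                pairs,
                labels,
                split=split,
                seed=seed,
                epochs=p["epochs"],
                batch_size=p["batch_size"],
                lr=p["lr"],
                patience=p["patience"],
                filters=tuple(p["filters_1d"]),
            )
            reports["pathway_cnn1d"] = rep.to_dict()
        if p["baselines"]:
            base = pw.baseline_suite_on_pairs(
                pairs, labels, split=split, models=tuple(p["baselines"]), seed=seed
            )
            for name, rep in base.items():
                reports[f"baseline_{name}"] = rep.to_dict()

    if "cnn2d" in p["arch"]:
        images, legend = pw.build_gene_pathway_images(X, sets)
        net, rep = pw.train_pathway_cnn2d(
            images,
            labels,
            split=split,
            seed=seed,
            epochs=p["epochs"],
            batch_size=p["batch_size"],
            lr=p["lr"],
            patience=p["patience"],
            filters=tuple(p["filters_2d"]),
        )
        reports["pathway_cnn2d"] = rep.to_dict()
        att = pw.class_mean_maps(net, images, labels, legend)
        for name, grid in (
            ("attribution_responder.tsv", att.responder),
            ("attribution_nonresponder.tsv", att.nonresponder),
            ("attribution_difference.tsv", att.difference),
        ):
            pd.DataFrame(grid, index=legend.genes, columns=legend.pathways).to_csv(
                outdir / name, sep="\t"
            )
            outputs.append(name)
        io.write_json(legend.to_dict(), outdir / "image_legend.json")
        spots = pw.extract_spots(att.difference, legend, q=p["gradcam_quantile"])
        io.write_json([s.to_dict() for s in spots], outdir / "spots.json")
        outputs += ["image_legend.json", "spots.json"]

    io.write_json(reports, outdir / "pathway_models.json")
    outputs.append("pathway_models.json")
    return outputs


def _stage_signature(config: PipelineConfig, outdir: Path, seed: int) -> list[str]:
    sig = config.signature.get("signature_genes")
    if not sig:
        spots_path = outdir / "spots.json"
        if not spots_path.exists():
            raise ScResponseError(
                "signature stage needs signature_genes or the pathway stage's spots.json"
            )
        spots = io.read_json(spots_path)
        responder_spots = [s for s in spots if s["sign"] == "responder"]
        if not responder_spots:
            raise ScResponseError("no responder spot found to derive a signature from")
        sig = responder_spots[0]["genes"]
    sc = _sim_config(config)
    bulk, response, survival = sim.simulate_bulk_validation_cohort(sc, sig)
    io.write_expression_matrix(bulk, outdir / "bulk_matrix.tsv")
    io.write_survival(survival, outdir / "bulk_survival.tsv")
    result = surv.survival_validation(
        bulk, survival, sig, quantile=config.signature["dichotomize_quantile"]
    )
    result["scores"].table.to_csv(outdir / "signature_scores.tsv", sep="\t", index=False)
    io.write_json(
        {
            "signature_genes": list(sig),
            "logrank": result["logrank"],
            "cox": result["cox"],
            "group_sizes": result["groups"].value_counts().to_dict(),
        },
        outdir / "signature_survival.json",
    )
    return ["bulk_matrix.tsv", "bulk_survival.tsv", "signature_scores.tsv", "signature_survival.json"]
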