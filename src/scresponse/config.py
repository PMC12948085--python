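"""Pipeline configuration: defaults, validation, provenance tagging.

A config document (YAML/JSON or a plain dict) is validated against the
schema below; unknown keys are rejected with a close-match suggestion,
every omitted value is filled from the defaults, and each default carries a
provenance class — ``stated`` (fixed by the analysis protocol this package
implements, e.g. the global seed 42, the 80/20 split, the DEG thresholds)
or ``choice`` (a package decision where the protocol is silent) — which the
pipeline echoes into its run log.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

# (default, provenance) per key, grouped by section
_SCHEMA: dict[str, dict[str, tuple[Any, str]]] = {
    "": {
        "seed": (42, "stated"),
        "stages": (["simulate", "deg", "genes", "pathway", "signature"], "choice"),
        "outdir": ("runs/run", "choice"),
    },
    "paths": {
        "matrix": (None, "choice"),
        "metadata": (None, "choice"),
        "gene_sets": (None, "choice"),
        "survival": (None, "choice"),
    },
    "simulate": {
        "n_samples_responder": (17, "stated"),
        "n_samples_nonresponder": (31, "stated"),
        "cells_per_sample": (40, "choice"),
        "n_genes": (2000, "choice"),
        "n_deg_up_responder": (86, "stated"),
        "n_deg_up_nonresponder": (124, "stated"),
        "deg_log2fc": (1.5, "choice"),
        "dropout_rate": (0.3, "choice"),
        "bimodal_gene": (True, "stated"),
        "bimodal_separation": (4.0, "choice"),
        "noise_sd": (0.9, "choice"),
        "sample_effect_sd": (0.2, "choice"),
        "n_pathways": (12, "choice"),
        "genes_per_pathway": (20, "choice"),
        "spot_genes": (16, "choice"),
        "spot_pathways": (4, "choice"),
        "bulk_n_samples": (120, "choice"),
        "bulk_hazard_log_ratio": (-0.8, "choice"),
        "bulk_censoring_rate": (0.2, "choice"),
    },
    "deg": {
        "mode": ("global", "stated"),
        "alpha": (0.05, "stated"),
        "fc_threshold": (1.0, "stated"),
        "fc_method": ("ratio", "choice"),
        "min_pct": (0.0, "choice"),
    },
    "genes": {
        "models": (["xgboost", "random_forest", "logistic_regression"], "choice"),
        "split_unit": ("cell", "stated"),
        "test_fraction": (0.2, "stated"),
        "scaling": ("train_only", "choice"),
        "cv_folds": (5, "stated"),
        "n_iter": (5, "choice"),
        "top_n": (50, "choice"),
        "resampling_splits": (0, "choice"),
    },
    "pathway": {
        "arch": (["cnn2d"], "choice"),
        "epochs": (30, "stated"),
        "batch_size": (64, "stated"),
        "lr": (1e-4, "stated"),
        "patience": (3, "stated"),
        "filters_2d": ([128, 64], "stated"),
        "filters_1d": ([128, 64, 32], "stated"),
        "gradcam_quantile": (0.8, "choice"),
        "baselines": ([], "choice"),
    },
    "signature": {
        "dichotomize_quantile": (0.5, "choice"),
        "signature_genes": (None, "choice"),
    },
}


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration (see module docstring)."""

    seed: int
    stages: list[str]
    outdir: str
    paths: dict[str, Any]
    simulate: dict[str, Any]
    deg: dict[str, Any]
    genes: dict[str, Any]
    pathway: dict[str, Any]
    signature: dict[str, Any]
    provenance: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "outdir": self.outdir,
            "paths": dict(self.paths),
            "simulate": dict(self.simulate),
            "deg": dict(self.deg),
            "genes": dict(self.genes),
            "pathway": dict(self.pathway),
            "signature": dict(self.signature),
        }


_ALL_STAGES = ("simulate", "deg", "genes", "pathway", "signature")


def _suggest(key: str, candidates) -> str:
    match = difflib.get_close_matches(key, list(candidates), n=1)
    return f"; did you mean {match[0]!r}?" if match else ""


def validate_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Validate a YAML/JSON document (or dict) and fill defaults.

    An empty document yields the full default configuration (seed 42).
    Unknown keys raise with a suggestion; basic range checks are applied.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        doc = {} if loaded is None else loaded
        if not isinstance(doc, dict):
            raise ConfigurationError("config document must be a mapping")

    sections: dict[str, dict[str, Any]] = {}
    provenance: dict[str, str] = {}
    top_known = set(_SCHEMA[""].keys()) | {s for s in _SCHEMA if s}
    for key in doc:
        if key not in top_known:
            raise ConfigurationError(f"unknown config key {key!r}{_suggest(key, top_known)}")

    for section, schema in _SCHEMA.items():
        given = doc if section == "" else doc.get(section, {})
        if section != "" and not isinstance(given, dict):
            raise ConfigurationError(f"config section {section!r} must be a mapping")
        out: dict[str, Any] = {}
        known = set(schema)
        source_items = {k: v for k, v in given.items() if section != "" or k in known}
        for key in source_items:
            if key not in known:
                raise ConfigurationError(
                    f"unknown config key {section + '.' if section else ''}{key!r}"
                    f"{_suggest(key, known)}"
                )
        for key, (default, prov) in schema.items():
            if key in source_items and source_items[key] is not None:
                out[key] = source_items[key]
                provenance[f"{section + '.' if section else ''}{key}"] = "user"
            else:
                out[key] = default
                provenance[f"{section + '.' if section else ''}{key}"] = f"default:{prov}"
        sections[section] = out

    top = sections[""]
    _check_types(top, sections)
    return PipelineConfig(
        seed=int(top["seed"]),
        stages=list(top["stages"]),
        outdir=str(top["outdir"]),
        paths=sections["paths"],
        simulate=sections["simulate"],
        deg=sections["deg"],
        genes=sections["genes"],
        pathway=sections["pathway"],
        signature=sections["signature"],
        provenance=provenance,
    )


def _check_types(top: dict, sections: dict) -> None:
    if not isinstance(top["seed"], int):
        raise ConfigurationError(f"seed must be an integer, got {top['seed']!r}")
    for stage in top["stages"]:
        if stage not in _ALL_STAGES:
            raise ConfigurationError(f"unknown stage {stage!r}{_suggest(stage, _ALL_STAGES)}")
    tf = sections["genes"]["test_fraction"]
    if not (0.0 < float(tf) < 1.0):
        raise ConfigurationError(f"genes.test_fraction must be in (0, 1), got {tf!r}")
    alpha = sections["deg"]["alpha"]
    if not (0.0 < float(alpha) < 1.0):
        raise ConfigurationError(f"deg.alpha must be in (0, 1), got {alpha!r}")
    q = sections["pathway"]["gradcam_quantile"]
    if not (0.0 <= float(q) <= 1.0):
        raise ConfigurationError(f"pathway.gradcam_quantile must be in [0, 1], got {q!r}")
    dq = sections["signature"]["dichotomize_quantile"]
    if not (0.0 < float(dq) < 1.0):
        raise ConfigurationError(f"signature.dichotomize_quantile must be in (0, 1), got {dq!r}")
    dr = sections["simulate"]["dropout_rate"]
    if not (0.0 <= float(dr) < 1.0):
        raise ConfigurationError(f"simulate.dropout_rate must be in [0, 1), got {dr!r}")
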