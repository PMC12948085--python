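"""Synthetic single-cell and bulk cohorts with planted ground truth.

The generator emulates a Smart-seq2-style checkpoint-inhibitor cohort: 48
tumour samples (17 responder, 31 non-responder), zero-inflated log2(TPM+1)
expression, planted differentially expressed genes (86 up in responders,
124 up in non-responders by default), one bimodal marker gene whose high
mode is enriched in non-responders, pathway gene sets with one planted
responder block and one planted non-responder block, and bulk validation
cohorts whose survival hazard is linked to a planted signature burden.

Generation model (per cell, log2 scale):

    x_gc = max(0, base_g + class_effect_gc + sample_effect_s + eps_gc)

with ``base_g`` drawn from a right-skewed Gamma, Gaussian noise ``eps``,
a scalar per-sample intercept (the pseudoreplication a cell-level split
leaks), and Bernoulli dropout zeroing entries with probability
``dropout_rate``. Planted DEGs receive a +``deg_log2fc`` shift in their
class. The default reduced scale (40 cells/sample) keeps the full pipeline
desk-sized; the full-scale profile is reachable through the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    NON_RESPONDER,
    RESPONDER,
    validate_cell_metadata,
    validate_survival,
)
from .errors import ConfigurationError


@dataclass
class PathwaySpec:
    """Gene-set layout: how many pathways, their size, and the planted spots.

    Spot genes are taken from the planted DEG lists and belong only to the
    spot pathways; spot pathways are adjacent in collection order, so the
    planted signal forms a contiguous genes-x-pathways block in the canonical
    image layout. The full-scale spot is 64 genes x 8 pathways; the reduced
    default is 16 x 4.
    """

    n_pathways: int = 12
    genes_per_pathway: int = 20
    spot_genes: int = 16
    spot_pathways: int = 4

    def validate(self) -> None:
        for name in ("n_pathways", "genes_per_pathway", "spot_genes", "spot_pathways"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"pathway_spec.{name} must be a non-negative integer, got {v!r}")
        if self.n_pathways > 0:
            if self.spot_genes > self.genes_per_pathway:
                raise ConfigurationError(
                    "pathway_spec.spot_genes exceeds genes_per_pathway: "
                    f"spot of {self.spot_genes} genes cannot fit in pathways of "
                    f"{self.genes_per_pathway} genes"
                )
            if 2 * self.spot_pathways > self.n_pathways:
                raise ConfigurationError(
                    "pathway_spec.spot_pathways: the two planted spots need "
                    f"2x{self.spot_pathways} pathways but only {self.n_pathways} requested"
                )


@dataclass
class BulkSpec:
    """Bulk validation cohort: size, signature-linked hazard, censoring."""

    n_samples: int = 120
    hazard_log_ratio: float = -0.8  # log hazard per unit standardized signature burden
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.1
    signature_effect: float = 1.0  # log2 shift of signature genes per unit burden

    def validate(self) -> None:
        if not isinstance(self.n_samples, (int, np.integer)) or self.n_samples < 4:
            raise ConfigurationError(f"bulk_spec.n_samples must be an integer >= 4, got {self.n_samples!r}")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ConfigurationError(f"bulk_spec.censoring_rate must be in [0, 1], got {self.censoring_rate!r}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError(f"bulk_spec.baseline_hazard must be > 0, got {self.baseline_hazard!r}")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort (defaults = reduced profile)."""

    seed: int = 42
    n_samples_responder: int = 17
    n_samples_nonresponder: int = 31
    cells_per_sample: int | tuple[int, int] = 40
    n_genes: int = 2000
    n_deg_up_responder: int = 86
    n_deg_up_nonresponder: int = 124
    deg_log2fc: float = 1.5
    dropout_rate: float = 0.3
    bimodal_gene: bool = True
    bimodal_separation: float = 4.0
    baseline_shape: float = 2.0  # Gamma shape of per-gene baseline log-mean
    baseline_scale: float = 0.7  # Gamma scale (mean baseline ~ 1.4 log2 units)
    noise_sd: float = 0.9
    sample_effect_sd: float = 0.2
    pathway_spec: PathwaySpec = field(default_factory=PathwaySpec)
    bulk_spec: BulkSpec = field(default_factory=BulkSpec)

    def validate(self) -> None:
        for name in (
            "n_samples_responder",
            "n_samples_nonresponder",
            "n_genes",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_deg_up_responder", "n_deg_up_nonresponder"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        cps = self.cells_per_sample
        if isinstance(cps, (tuple, list)):
            if len(cps) != 2 or cps[0] < 1 or cps[1] < cps[0]:
                raise ConfigurationError(f"cells_per_sample range invalid: {cps!r}")
        elif not isinstance(cps, (int, np.integer)) or cps < 1:
            raise ConfigurationError(f"cells_per_sample must be a positive count or range, got {cps!r}")
        reserved = self.n_deg_up_responder + self.n_deg_up_nonresponder + int(self.bimodal_gene)
        if reserved > self.n_genes:
            raise ConfigurationError(
                f"n_deg_up_responder + n_deg_up_nonresponder (+ bimodal gene) = {reserved} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate!r}")
        if self.deg_log2fc < 0:
            raise ConfigurationError(f"deg_log2fc must be >= 0, got {self.deg_log2fc!r}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd!r}")
        if self.sample_effect_sd < 0:
            raise ConfigurationError(f"sample_effect_sd must be >= 0, got {self.sample_effect_sd!r}")
        if self.pathway_spec is not None:
            self.pathway_spec.validate()
        if self.bulk_spec is not None:
            self.bulk_spec.validate()
        if self.pathway_spec is not None and self.pathway_spec.n_pathways > 0:
            # spots are carved out of the planted DEG lists
            for name in ("n_deg_up_responder", "n_deg_up_nonresponder"):
                if self.pathway_spec.spot_genes > getattr(self, name):
                    raise ConfigurationError(
                        f"pathway_spec.spot_genes exceeds {name} "
                        f"({self.pathway_spec.spot_genes} > {getattr(self, name)})"
                    )


@dataclass
class PlantedSpot:
    genes: list[str]
    pathways: list[str]


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream scoring against truth."""

    planted_deg_up_responder: list[str]
    planted_deg_up_nonresponder: list[str]
    deg_log2fc: float
    bimodal_gene_id: str | None
    bimodal_modes: tuple[float, float] | None
    responder_spot: PlantedSpot | None
    nonresponder_spot: PlantedSpot | None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _plan(config: SimConfig) -> dict:
    """Deterministic structural plan shared by the cohort and gene-set simulators."""
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 0])
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)
    n_up_r = config.n_deg_up_responder
    n_up_nr = config.n_deg_up_nonresponder
    up_r = sorted(order[:n_up_r])
    up_nr = sorted(order[n_up_r : n_up_r + n_up_nr])
    bimodal_idx = None
    if config.bimodal_gene:
        bimodal_idx = int(order[n_up_r + n_up_nr])
    plan = {
        "genes": genes,
        "up_r_idx": np.asarray(up_r, dtype=int),
        "up_nr_idx": np.asarray(up_nr, dtype=int),
        "bimodal_idx": bimodal_idx,
    }
    spec = config.pathway_spec
    if spec is not None and spec.n_pathways > 0:
        deg_idx = set(plan["up_r_idx"]) | set(plan["up_nr_idx"])
        if bimodal_idx is not None:
            deg_idx.add(bimodal_idx)
        background_pool = np.array([i for i in range(config.n_genes) if i not in deg_idx])
        spot_r_genes = [genes[i] for i in plan["up_r_idx"][: spec.spot_genes]]
        spot_nr_genes = [genes[i] for i in plan["up_nr_idx"][: spec.spot_genes]]
        names = [f"P{i:03d}" for i in range(spec.n_pathways)]
        membership: list[tuple[str, list[str]]] = []
        for p in range(spec.n_pathways):
            if p < spec.spot_pathways:
                core = list(spot_r_genes)
            elif p < 2 * spec.spot_pathways:
                core = list(spot_nr_genes)
            else:
                core = []
            n_extra = spec.genes_per_pathway - len(core)
            if len(background_pool) == 0:
                extra = []
            else:
                extra = [
                    genes[i]
                    for i in rng.choice(background_pool, size=min(n_extra, len(background_pool)), replace=False)
                ]
            membership.append((names[p], core + extra))
        plan["pathways"] = membership
        plan["responder_spot"] = PlantedSpot(genes=spot_r_genes, pathways=names[: spec.spot_pathways])
        plan["nonresponder_spot"] = PlantedSpot(
            genes=spot_nr_genes, pathways=names[spec.spot_pathways : 2 * spec.spot_pathways]
        )
    else:
        plan["pathways"] = None
        plan["responder_spot"] = None
        plan["nonresponder_spot"] = None
    return plan


def simulate_single_cell_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate the single-cell cohort; returns (matrix, metadata, truth).

    The matrix is cells x genes on a non-negative log2 scale; metadata rows
    align 1:1 with matrix rows. Identical configs (same seed) give
    byte-identical outputs.
    """
    plan = _plan(config)
    rng = np.random.default_rng([int(config.seed) % (2**31), 1])
    genes = plan["genes"]
    n_genes = config.n_genes

    n_r, n_nr = config.n_samples_responder, config.n_samples_nonresponder
    n_samples = n_r + n_nr
    cps = config.cells_per_sample
    if isinstance(cps, (tuple, list)):
        cells_per_sample = rng.integers(cps[0], cps[1] + 1, size=n_samples)
    else:
        cells_per_sample = np.full(n_samples, int(cps))
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    responses = [RESPONDER] * n_r + [NON_RESPONDER] * n_nr
    timepoints = rng.choice(["baseline", "post-treatment"], size=n_samples)

    base = rng.gamma(config.baseline_shape, config.baseline_scale, size=n_genes)
    sample_effects = rng.normal(0.0, config.sample_effect_sd, size=n_samples) if config.sample_effect_sd > 0 else np.zeros(n_samples)

    total_cells = int(cells_per_sample.sum())
    X = np.empty((total_cells, n_genes))
    cell_sample = np.repeat(np.arange(n_samples), cells_per_sample)
    is_responder_cell = np.repeat(np.array([r == RESPONDER for r in responses]), cells_per_sample)

    mean = np.tile(base, (total_cells, 1))
    if config.deg_log2fc > 0:
        mean[np.ix_(is_responder_cell, plan["up_r_idx"])] += config.deg_log2fc
        mean[np.ix_(~is_responder_cell, plan["up_nr_idx"])] += config.deg_log2fc
    mean += sample_effects[cell_sample][:, None]
    X = mean + rng.normal(0.0, config.noise_sd, size=(total_cells, n_genes))

    bimodal_modes = None
    bi = plan["bimodal_idx"]
    if bi is not None:
        low, high = 0.5, 0.5 + config.bimodal_separation
        p_high = np.where(is_responder_cell, 0.25, 0.7)
        comp = rng.random(total_cells) < p_high
        X[:, bi] = np.where(comp, high, low) + rng.normal(0.0, 0.5, size=total_cells)
        bimodal_modes = (low, high)

    np.maximum(X, 0.0, out=X)
    if config.dropout_rate > 0:
        drop = rng.random(X.shape) < config.dropout_rate
        if bi is not None:
            drop[:, bi] = False  # keep the marker's clean two-mode shape
        X[drop] = 0.0

    cell_ids = [f"C{i:06d}" for i in range(total_cells)]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=cell_ids, columns=genes))
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": [sample_ids[s] for s in cell_sample],
            "patient_id": [sample_ids[s] for s in cell_sample],
            "response": [responses[s] for s in cell_sample],
            "timepoint": [timepoints[s] for s in cell_sample],
        }
    )
    meta = validate_cell_metadata(meta)
    truth = SyntheticTruth(
        planted_deg_up_responder=[genes[i] for i in plan["up_r_idx"]],
        planted_deg_up_nonresponder=[genes[i] for i in plan["up_nr_idx"]],
        deg_log2fc=config.deg_log2fc,
        bimodal_gene_id=genes[bi] if bi is not None else None,
        bimodal_modes=bimodal_modes,
        responder_spot=plan["responder_spot"],
        nonresponder_spot=plan["nonresponder_spot"],
    )
    return matrix, meta, truth


def simulate_gene_sets(config: SimConfig) -> GeneSetCollection:
    """Simulate pathway gene sets with the planted spots embedded.

    Consistent with :func:`simulate_single_cell_cohort` for the same config:
    spot genes are leading subsets of the planted DEG lists and appear in
    exactly the spot pathways; background pathways draw from non-DEG genes.
    """
    plan = _plan(config)
    if plan["pathways"] is None:
        raise ConfigurationError("pathway_spec requests zero pathways; no gene sets to simulate")
    return GeneSetCollection(plan["pathways"])


def simulate_bulk_validation_cohort(
    config: SimConfig, signature: Sequence[str]
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Simulate a bulk cohort with signature-linked response and hazard.

    Each sample carries a latent standardized signature burden ``z``; the
    signature genes are shifted by ``signature_effect * z`` on the log2
    scale, response odds increase with ``z``, and survival is exponential
    with log-hazard ``hazard_log_ratio * z`` (negative values mean high
    burden protects). Censoring is independent exponential tuned to the
    requested rate; ``censoring_rate = 1`` censors everything.

    Returns (expression, response labels, survival table with the true
    burden as a ``truth_burden`` column).
    """
    plan = _plan(config)
    spec = config.bulk_spec
    signature = [str(g) for g in signature]
    if len(signature) == 0:
        raise ConfigurationError("signature must contain at least one gene")
    genes = plan["genes"]
    missing = sorted(set(signature) - set(genes))
    if missing:
        raise ConfigurationError(f"signature genes absent from the simulated gene universe: {missing[:5]}")

    rng = np.random.default_rng([int(config.seed) % (2**31), 2])
    n = spec.n_samples
    z = rng.normal(0.0, 1.0, size=n)
    response = np.where(
        rng.random(n) < 1.0 / (1.0 + np.exp(-z)), RESPONDER, NON_RESPONDER
    )

    base = rng.gamma(config.baseline_shape, config.baseline_scale, size=len(genes))
    X = base[None, :] + rng.normal(0.0, config.noise_sd, size=(n, len(genes)))
    sig_idx = [genes.index(g) for g in signature]
    X[:, sig_idx] += spec.signature_effect * z[:, None]
    np.maximum(X, 0.0, out=X)

    hazard = spec.baseline_hazard * np.exp(spec.hazard_log_ratio * z)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate >= 1.0:
        time = rng.exponential(1.0 / spec.baseline_hazard, size=n)
        event = np.zeros(n, dtype=int)
    elif spec.censoring_rate <= 0.0:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        cens_rate = hazard * spec.censoring_rate / (1.0 - spec.censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate)
        time = np.minimum(event_time, cens_time)
        event = (event_time <= cens_time).astype(int)
    time = np.maximum(time, 1e-9)

    sample_ids = [f"B{i:03d}" for i in range(n)]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=sample_ids, columns=genes))
    labels = pd.Series(response, index=sample_ids, name="response")
    survival = validate_survival(
        pd.DataFrame(
            {"sample_id": sample_ids, "time": time, "event": event, "truth_burden": z}
        )
    )
    return matrix, labels, survival
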