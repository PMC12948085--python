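"""Pathway-level feature construction, convolutional models and attribution.

Two encodings of the same information are built from an expression matrix
and a gene-set collection:

* a **pair matrix** — one column per unique (gene, pathway) membership,
  named ``gene.pathway``, valued at the gene's expression in each cell
  (input to the 1-D CNN and the flattened-vector baselines); and
* a **gene x pathway image** per cell — rows are genes belonging to at
  least one pathway, columns are pathways, entry (g, p) is the gene's
  expression if g is a member of p and 0 otherwise (input to the 2-D CNN).

Grad-CAM attribution over the image, per-class mean maps, their
responder-minus-non-responder difference, and connected-component spot
extraction turn the 2-D classifier into gene/pathway signatures.

Image ordering is deterministic and recorded in the legend: pathways in
collection (GMT) order, genes sorted by first-containing pathway then
symbol. Convolutional locality depends on this ordering, so it is surfaced
rather than hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
from skimage.transform import resize as _resize

from .containers import ExpressionMatrix, GeneSetCollection, NON_RESPONDER, RESPONDER
from .errors import ValidationError
from .models import (
    MODEL_NAMES,
    ModelReport,
    SplitSpec,
    model_scores,
    response_to_binary,
    roc_auc,
    standardize,
    stratified_split,
    tune_and_train,
)
from . import nn

logger = logging.getLogger(__name__)

PAIR_SEP = "."


def expand_gene_pathway_pairs(X: ExpressionMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Cells x unique (gene, pathway) pair matrix, columns ``gene.pathway``.

    Column order is deterministic: pathways in collection order, genes in
    within-pathway order, restricted to genes present in the matrix.
    """
    matrix_genes = set(X.gene_ids)
    columns: list[str] = []
    source_genes: list[str] = []
    for pathway, genes in sets.items():
        for g in genes:
            if g in matrix_genes:
                columns.append(f"{g}{PAIR_SEP}{pathway}")
                source_genes.append(g)
    if not columns:
        raise ValidationError("no overlap between matrix genes and gene-set members")
    data = X.data[source_genes].to_numpy()
    return pd.DataFrame(data, index=X.row_ids, columns=columns)


@dataclass
class ImageLegend:
    """Maps image coordinates back to identifiers: row -> gene, col -> pathway."""

    genes: list[str]
    pathways: list[str]
    membership: np.ndarray = field(repr=False)  # bool (n_genes, n_pathways)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genes), len(self.pathways))

    def to_dict(self) -> dict:
        return {"genes": self.genes, "pathways": self.pathways}


def build_gene_pathway_images(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    genes: list[str] | None = None,
) -> tuple[np.ndarray, ImageLegend]:
    """Per-cell gene x pathway image stack plus its coordinate legend.

    ``genes`` optionally fixes the row universe explicitly; by default it is
    every matrix gene belonging to at least one pathway, ordered by
    first-containing pathway then symbol.
    """
    matrix_genes = set(X.gene_ids)
    pathways = sets.names
    first_pathway: dict[str, int] = {}
    for pi, (_, members) in enumerate(sets.items()):
        for g in members:
            if g in matrix_genes and g not in first_pathway:
                first_pathway[g] = pi
    if genes is None:
        genes = sorted(first_pathway, key=lambda g: (first_pathway[g], g))
    else:
        missing = [g for g in genes if g not in matrix_genes]
        if missing:
            raise ValidationError(f"requested image genes absent from matrix: {missing[:5]}")
        genes = list(genes)
    if not genes:
        raise ValidationError("no overlap between matrix genes and gene-set members")

    gene_pos = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((len(genes), len(pathways)), dtype=bool)
    for pi, (_, members) in enumerate(sets.items()):
        for g in members:
            if g in gene_pos:
                membership[gene_pos[g], pi] = True

    expr = X.data[genes].to_numpy()  # (n_cells, n_genes)
    stack = expr[:, :, None] * membership[None, :, :]
    legend = ImageLegend(genes=genes, pathways=pathways, membership=membership)
    return stack.astype(np.float32), legend


def _prepare_split(labels, split, n, seed):
    if split is not None:
        return np.asarray(split[0]), np.asarray(split[1])
    meta = pd.DataFrame({"response": np.asarray(labels)})
    return stratified_split(meta, SplitSpec(seed=seed))


def train_pathway_cnn1d(
    pairs: pd.DataFrame,
    labels,
    *,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 42,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 1e-4,
    patience: int = 3,
    **arch_kwargs,
) -> tuple[nn.NeuralNet, ModelReport]:
    """Train the three-block pathway 1-D CNN on standardized pair vectors."""
    y = response_to_binary(labels)
    tr, te = _prepare_split(labels, split, len(y), seed)
    X = pairs.to_numpy(dtype=float)
    Xtr, Xte, _ = standardize(X[tr], X[te])
    net = nn.build_pathway_cnn1d(X.shape[1], seed=seed, **arch_kwargs)
    net.fit(
        Xtr[:, :, None],
        y[tr].astype(float),
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        patience=patience,
        seed=seed,
        restore_best="val_accuracy",
    )
    scores = net.predict_proba(Xte[:, :, None])
    roc, a = roc_auc(scores, y[te])
    report = ModelReport(name="pathway_cnn1d", params={"epochs": epochs, "lr": lr}, roc=roc, auc=a)
    return net, report


def train_pathway_cnn2d(
    images: np.ndarray,
    labels,
    *,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 42,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 1e-4,
    patience: int = 3,
    **arch_kwargs,
) -> tuple[nn.NeuralNet, ModelReport]:
    """Train the two-block + global-max-pool pathway 2-D CNN.

    Images stay on their log2 expression scale: standardizing per pixel
    would destroy the structural zeros that carry the membership pattern.
    """
    y = response_to_binary(labels)
    tr, te = _prepare_split(labels, split, len(y), seed)
    X = np.asarray(images, dtype=float)[:, :, :, None]
    net = nn.build_pathway_cnn2d(X.shape[1], X.shape[2], seed=seed, **arch_kwargs)
    net.fit(
        X[tr],
        y[tr].astype(float),
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        patience=patience,
        seed=seed,
        restore_best="val_accuracy",
    )
    scores = _predict_images(net, X[te])
    roc, a = roc_auc(scores, y[te])
    report = ModelReport(name="pathway_cnn2d", params={"epochs": epochs, "lr": lr}, roc=roc, auc=a)
    return net, report


def _predict_images(net: nn.NeuralNet, X4: np.ndarray, batch_size: int = 128) -> np.ndarray:
    return net.predict_proba(X4, batch_size=batch_size)


def baseline_suite_on_pairs(
    pairs: pd.DataFrame,
    labels,
    *,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    models: tuple[str, ...] = ("xgboost", "random_forest", "logistic_regression", "svm", "fnn"),
    seed: int = 42,
    cv_folds: int = 5,
    n_iter: int = 5,
) -> dict[str, ModelReport]:
    """Conventional classifiers on the same flattened pair vectors and the
    same split as the 1-D CNN; the shared-split fingerprint is recorded in
    every report so a fair comparison is checkable."""
    y = response_to_binary(labels)
    tr, te = _prepare_split(labels, split, len(y), seed)
    X = pairs.to_numpy(dtype=float)
    Xtr, Xte, _ = standardize(X[tr], X[te])
    fingerprint = _split_fingerprint(tr, te)
    reports: dict[str, ModelReport] = {}
    for name in models:
        if name not in MODEL_NAMES:
            raise ValidationError(f"unknown baseline model {name!r}")
        model, params = tune_and_train(name, Xtr, y[tr], cv_folds=cv_folds, n_iter=n_iter, seed=seed)
        roc, a = roc_auc(model_scores(model, Xte), y[te])
        params = dict(params)
        params["split_fingerprint"] = fingerprint
        reports[name] = ModelReport(name=name, params=params, roc=roc, auc=a)
    return reports


def _split_fingerprint(tr: np.ndarray, te: np.ndarray) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.asarray(tr, dtype=np.int64).tobytes())
    h.update(b"|")
    h.update(np.asarray(te, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


# ------------------------------------------------------------- attribution
def gradcam_heatmap(
    net: nn.NeuralNet,
    images: np.ndarray,
    class_index: int,
    *,
    upsample: str = "bilinear",
    batch_size: int = 64,
) -> np.ndarray:
    """Grad-CAM maps for a batch of images, upsampled to image resolution.

    ``class_index`` 1 targets the responder (positive-logit) class, 0 the
    non-responder class (negated logit). Maps are rectified (ReLU) and
    non-negative.
    """
    if class_index not in (0, 1):
        raise ValidationError("class_index must be 0 (non-responder) or 1 (responder)")
    X4 = np.asarray(images, dtype=float)
    if X4.ndim == 3:
        X4 = X4[:, :, :, None]
    sign = 1.0 if class_index == 1 else -1.0
    cams = net.gradcam(X4, class_sign=sign, batch_size=batch_size)
    h, w = X4.shape[1], X4.shape[2]
    order = 1 if upsample == "bilinear" else 0
    out = np.empty((cams.shape[0], h, w))
    for i in range(cams.shape[0]):
        out[i] = _resize(cams[i], (h, w), order=order, mode="edge", anti_aliasing=False)
    return np.maximum(out, 0.0)


@dataclass
class AttributionMap:
    """Per-class mean Grad-CAM grids and their signed difference."""

    responder: np.ndarray
    nonresponder: np.ndarray
    difference: np.ndarray  # responder - nonresponder
    legend: ImageLegend


def class_mean_maps(
    net: nn.NeuralNet,
    images: np.ndarray,
    labels,
    legend: ImageLegend,
    *,
    restrict_to_correct: bool = False,
    batch_size: int = 64,
) -> AttributionMap:
    """Average each class's own-class Grad-CAM maps over its cells.

    By default all cells of a class contribute; ``restrict_to_correct``
    limits the averages to correctly classified cells.
    """
    y = response_to_binary(labels)
    X4 = np.asarray(images, dtype=float)
    if X4.ndim == 3:
        X4 = X4[:, :, :, None]
    if restrict_to_correct:
        pred = (_predict_images(net, X4) >= 0.5).astype(int)
        keep = pred == y
    else:
        keep = np.ones(len(y), dtype=bool)
    maps = {}
    for cls, name in ((1, RESPONDER), (0, NON_RESPONDER)):
        mask = (y == cls) & keep
        if not mask.any():
            raise ValidationError(f"no cells available for class {name!r}")
        cams = gradcam_heatmap(net, X4[mask], class_index=cls, batch_size=batch_size)
        maps[name] = cams.mean(axis=0)
    return AttributionMap(
        responder=maps[RESPONDER],
        nonresponder=maps[NON_RESPONDER],
        difference=maps[RESPONDER] - maps[NON_RESPONDER],
        legend=legend,
    )


@dataclass
class SpotReport:
    sign: str  # 'responder' (positive difference) or 'non-responder'
    coordinates: list[tuple[int, int]]
    genes: list[str]
    pathways: list[str]
    mass: float

    def to_dict(self) -> dict:
        return {
            "sign": self.sign,
            "coordinates": [list(c) for c in self.coordinates],
            "genes": self.genes,
            "pathways": self.pathways,
            "mass": self.mass,
        }


def extract_spots(
    difference: np.ndarray,
    legend: ImageLegend,
    q: float = 0.99,
) -> list[SpotReport]:
    """Top positive and top negative spots of a class-difference grid.

    Thresholds at the ``q``-quantile of the positive entries (respectively
    of |negative| entries), labels 4-connected components above threshold,
    ranks them by summed |mass| and returns the top spot of each sign with
    its spanned gene and pathway lists. ``q = 1.0`` keeps at most the argmax
    cell per sign; an all-zero grid yields no spots.
    """
    diff = np.asarray(difference, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValidationError("difference grid contains non-finite values")
    if not (0.0 <= q <= 1.0):
        raise ValidationError(f"quantile q must be in [0, 1], got {q}")
    reports: list[SpotReport] = []
    for sign_name, grid in ((RESPONDER, diff), (NON_RESPONDER, -diff)):
        positive = grid[grid > 0]
        if positive.size == 0:
            continue
        threshold = np.quantile(positive, q)
        mask = grid >= threshold
        mask &= grid > 0
        labelled, n_comp = scipy.ndimage.label(mask)  # default structure = 4-connectivity
        if n_comp == 0:
            continue
        masses = scipy.ndimage.sum_labels(np.abs(grid), labelled, index=np.arange(1, n_comp + 1))
        best = int(np.argmax(masses)) + 1
        coords = [tuple(map(int, rc)) for rc in np.argwhere(labelled == best)]
        rows = sorted({r for r, _ in coords})
        cols = sorted({c for _, c in coords})
        reports.append(
            SpotReport(
                sign=sign_name,
                coordinates=coords,
                genes=[legend.genes[r] for r in rows],
                pathways=[legend.pathways[c] for c in cols],
                mass=float(masses[best - 1]),
            )
        )
    return reports
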