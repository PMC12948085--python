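"""Gene-level statistics for the responder / non-responder screen.

Implements the differential-expression screen used throughout the pipeline:
per-gene two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg
correction and fold-change thresholds (global mode: |log2FC| > 1 and
adjusted p < 0.05; marker mode: prevalence >= 0.1 in at least one group and
|log2FC| >= 0.25 before testing), plus the surrounding utilities: the
high-variance gene filter (variance > 6), expression-bin-matched module
scoring, and a two-component Gaussian-mixture split for bimodal markers.

Fold change is computed on de-logged group means with a pseudocount of 1,

    log2FC = log2[(mean(2^x - 1 over A) + 1) / (mean(2^x - 1 over B) + 1)],

the convention of the standard single-cell toolkits; a plain
difference-of-log-means variant is available via ``fc_method='logdiff'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import ValidationError

UP_IN_GROUP1 = "up_in_group1"
UP_IN_GROUP2 = "up_in_group2"


def select_high_variance_genes(X: ExpressionMatrix, threshold: float = 6.0) -> list[str]:
    """Genes whose per-gene variance (n-1 denominator) strictly exceeds ``threshold``.

    Returned in input column order. Requires at least two rows.
    """
    if X.shape[0] < 2:
        raise ValidationError("variance is undefined for a single-cell matrix (need >= 2 rows)")
    var = X.values.var(axis=0, ddof=1)
    return [g for g, v in zip(X.gene_ids, var) if v > threshold]


def wilcoxon_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both group sizes are <= 10 and there are no ties,
    otherwise the normal approximation with tie-corrected variance and
    continuity correction. Identical groups (zero rank variance) return 1.0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("wilcoxon_test requires two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must all lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(values_a, values_b, method: str = "ratio") -> float:
    """Signed log2 fold change of group A over group B (inputs on log2(x+1) scale)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("log2_fold_change requires two non-empty groups")
    if method == "ratio":
        return float(np.log2((np.mean(2.0**a - 1.0) + 1.0) / (np.mean(2.0**b - 1.0) + 1.0)))
    if method == "logdiff":
        return float(a.mean() - b.mean())
    raise ValidationError(f"unknown fold-change method {method!r}")


def _fold_changes(A: np.ndarray, B: np.ndarray, method: str) -> np.ndarray:
    if method == "ratio":
        return np.log2((np.mean(2.0**A - 1.0, axis=0) + 1.0) / (np.mean(2.0**B - 1.0, axis=0) + 1.0))
    if method == "logdiff":
        return A.mean(axis=0) - B.mean(axis=0)
    raise ValidationError(f"unknown fold-change method {method!r}")


def _rank_sum_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values with the wilcoxon_test rules."""
    na, nb = A.shape[0], B.shape[0]
    if min(na, nb) <= 10:
        return np.array([wilcoxon_test(A[:, j], B[:, j]) for j in range(A.shape[1])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(
            A, B, axis=0, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))


def deg_screen(
    X: ExpressionMatrix,
    labels: pd.Series,
    mode: str = "global",
    *,
    group1: str | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 1.0,
    marker_min_pct: float = 0.1,
    marker_fc_threshold: float = 0.25,
    min_pct: float = 0.0,
    fc_method: str = "ratio",
) -> pd.DataFrame:
    """Screen every gene for differential expression between two groups.

    ``labels`` aligns with matrix rows (positionally or by index). ``group1``
    is the reference direction (defaults to ``responder`` when present).
    Global mode tests all genes and flags ``|log2FC| > fc_threshold`` with
    BH-adjusted p < ``alpha``; marker mode first restricts to genes with
    prevalence >= ``marker_min_pct`` in at least one group and
    ``|log2FC| >= marker_fc_threshold``, then tests and BH-adjusts. An
    optional ``min_pct`` prevalence filter is available in global mode
    (off by default).

    Returns a DEG table with one row per tested gene: log2fc, p_value,
    adj_p, pct_group1, pct_group2, direction, passes.
    """
    if mode not in ("global", "marker"):
        raise ValidationError(f"mode must be 'global' or 'marker', got {mode!r}")
    labels = pd.Series(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("labels length does not match the number of matrix rows")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValidationError(f"deg_screen requires exactly two groups, got {list(groups)!r}")
    if group1 is None:
        group1 = "responder" if "responder" in set(groups) else sorted(map(str, groups))[0]
    if group1 not in set(groups):
        raise ValidationError(f"group1 {group1!r} not among labels {list(groups)!r}")
    mask1 = (labels == group1).to_numpy()
    A = X.values[mask1]
    B = X.values[~mask1]
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValidationError("each group needs at least 3 cells")

    if not X.values.any():
        warnings.warn("all-zero expression matrix; returning empty DEG table")
        return pd.DataFrame(
            columns=["gene", "log2fc", "p_value", "adj_p", "pct_group1", "pct_group2", "direction", "passes"]
        )

    genes = np.asarray(X.gene_ids)
    lfc = _fold_changes(A, B, fc_method)
    pct1 = (A > 0).mean(axis=0)
    pct2 = (B > 0).mean(axis=0)

    if mode == "marker":
        tested = ((pct1 >= marker_min_pct) | (pct2 >= marker_min_pct)) & (
            np.abs(lfc) >= marker_fc_threshold
        )
    else:
        tested = np.ones(len(genes), dtype=bool)
        if min_pct > 0:
            tested &= (pct1 >= min_pct) | (pct2 >= min_pct)

    idx = np.flatnonzero(tested)
    p = _rank_sum_pvalues(A[:, idx], B[:, idx]) if idx.size else np.array([])
    adj = benjamini_hochberg(p) if idx.size else np.array([])

    table = pd.DataFrame(
        {
            "gene": genes[idx],
            "log2fc": lfc[idx],
            "p_value": p,
            "adj_p": adj,
            "pct_group1": pct1[idx],
            "pct_group2": pct2[idx],
            "direction": np.where(lfc[idx] >= 0, UP_IN_GROUP1, UP_IN_GROUP2),
        }
    )
    if mode == "marker":
        table["passes"] = table["adj_p"] < alpha
    else:
        table["passes"] = (np.abs(table["log2fc"]) > fc_threshold) & (table["adj_p"] < alpha)
    return table.reset_index(drop=True)


def module_score(
    X: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score: mean(set genes) - mean(bin-matched controls).

    Genes are binned into ``n_bins`` equal-frequency bins by dataset-average
    expression; for each set gene, ``n_ctrl`` control genes are drawn from
    its bin (without replacement when the bin allows) and pooled. A random
    gene set scores 0 in expectation.
    """
    gene_set = [str(g) for g in gene_set]
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    missing = sorted(set(gene_set) - set(X.gene_ids))
    if missing:
        raise ValidationError(f"module_score: genes absent from matrix: {missing}")
    data = X.data
    avg = data.mean(axis=0)
    n_bins_eff = min(n_bins, avg.nunique())
    if n_bins_eff < 1:
        n_bins_eff = 1
    # equal-frequency binning on average expression; rank first to break ties
    ranks = avg.rank(method="first")
    bins = pd.qcut(ranks, q=n_bins_eff, labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    control_genes: dict[str, None] = {}
    for g in gene_set:
        pool = bins.index[bins == bins[g]]
        pool = pool[pool != g]
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        chosen = rng.choice(pool, size=take, replace=False)
        for c in chosen:
            control_genes.setdefault(c)
    set_mean = data[gene_set].mean(axis=1)
    if control_genes:
        ctrl_mean = data[list(control_genes)].mean(axis=1)
    else:
        ctrl_mean = pd.Series(0.0, index=data.index)
    score = set_mean - ctrl_mean
    score.name = "module_score"
    return score


@dataclass
class BimodalSplit:
    threshold: float
    labels: pd.Series  # 'high' / 'low'
    separation: float  # mode separation / pooled SD
    low_confidence: bool
    modes: tuple[float, float]


def bimodal_split(values, seed: int = 0) -> BimodalSplit:
    """Split values at the equal-posterior point of a 2-component Gaussian mixture.

    The separability diagnostic is (mu_high - mu_low) / pooled SD; fits with
    diagnostic < 1 are flagged low-confidence rather than rejected.
    """
    values = pd.Series(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 20:
        raise ValidationError("bimodal_split requires at least 20 finite values")
    if finite.nunique() == 1:
        raise ValidationError("bimodal_split: constant input has no modes")
    x = finite.to_numpy().reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=seed, reg_covar=1e-6)
    gm.fit(x)
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    order = np.argsort(means)
    mu_lo, mu_hi = means[order]
    var_lo, var_hi = variances[order]
    pooled_sd = float(np.sqrt((var_lo + var_hi) / 2.0))
    separation = float((mu_hi - mu_lo) / pooled_sd) if pooled_sd > 0 else np.inf

    grid = np.linspace(mu_lo, mu_hi, 2001).reshape(-1, 1)
    post = gm.predict_proba(grid)[:, order[1]] - gm.predict_proba(grid)[:, order[0]]
    crossings = np.flatnonzero(np.diff(np.sign(post)) != 0)
    threshold = float(grid[crossings[0] + 1, 0]) if crossings.size else float((mu_lo + mu_hi) / 2.0)

    labels = pd.Series(np.where(values > threshold, "high", "low"), index=values.index)
    labels[~np.isfinite(values)] = "low"
    return BimodalSplit(
        threshold=threshold,
        labels=labels,
        separation=separation,
        low_confidence=separation < 1.0,
        modes=(float(mu_lo), float(mu_hi)),
    )
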