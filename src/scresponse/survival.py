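"""Rank-based signature scoring and survival validation for bulk cohorts.

A spot-derived gene list is scored per bulk sample by the mean rank of its
genes within that sample's expression profile (up-set-only, invariant to
any strictly increasing transform of the sample's values), normalized to
[0, 1] against its theoretical bounds. Scores are dichotomized (median by
default), compared with Kaplan-Meier curves and the log-rank test, and
related to outcome with univariate Cox proportional-hazards regression
(Breslow tie handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from statsmodels.duration.hazard_regression import PHReg

from .containers import ExpressionMatrix, validate_survival
from .errors import ConvergenceError, ValidationError


@dataclass
class SignatureScores:
    """Per-sample rank signature scores."""

    table: pd.DataFrame  # sample_id, raw_rank, score, n_set, n_genes
    missing_genes: list[str]

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("sample_id")["score"]


def rank_signature_score(bulk: ExpressionMatrix, gene_set) -> SignatureScores:
    """Up-set mean-rank score per sample, normalized to [0, 1].

    Within each sample, all n genes are ranked ascending (average ranks for
    ties); the raw score is the mean rank of the k set genes and the
    normalized score is ``(raw - (k+1)/2) / (n - (k-1)/2 - (k+1)/2)``, i.e.
    0 when the set genes are the lowest-ranked and 1 when they are the
    highest. Set genes absent from the matrix are dropped with a warning
    and recorded; fewer than 2 present genes is an error.
    """
    gene_set = [str(g) for g in gene_set]
    present = [g for g in gene_set if g in set(bulk.gene_ids)]
    missing = sorted(set(gene_set) - set(present))
    if len(present) < 2:
        raise ValidationError(
            f"rank_signature_score needs >= 2 set genes present in the matrix; "
            f"found {len(present)} (missing: {missing[:5]})"
        )
    if missing:
        import warnings

        warnings.warn(f"rank_signature_score: {len(missing)} set genes absent and dropped")
    values = bulk.values
    n = values.shape[1]
    k = len(present)
    ranks = scipy.stats.rankdata(values, axis=1, method="average")
    set_cols = [bulk.gene_ids.get_loc(g) for g in present]
    raw = ranks[:, set_cols].mean(axis=1)
    low = (k + 1) / 2.0
    high = n - (k - 1) / 2.0
    score = (raw - low) / (high - low)
    table = pd.DataFrame(
        {
            "sample_id": bulk.row_ids,
            "raw_rank": raw,
            "score": score,
            "n_set": k,
            "n_genes": n,
        }
    ).reset_index(drop=True)
    return SignatureScores(table=table, missing_genes=missing)


def dichotomize(scores: pd.Series, quantile: float = 0.5) -> pd.Series:
    """Split samples into 'high' (score > cut) and 'low' (score <= cut).

    The cut is the ``quantile`` of the scores (median by default). Requires
    at least 4 samples and a non-constant score vector.
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 4:
        raise ValidationError("dichotomize requires at least 4 samples")
    if scores.nunique() == 1:
        raise ValidationError("all scores are equal; no high/low split exists")
    if not (0.0 < quantile < 1.0):
        raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
    cut = float(scores.quantile(quantile))
    groups = pd.Series(np.where(scores > cut, "high", "low"), index=scores.index, name="group")
    if groups.nunique() == 1:
        raise ValidationError("chosen quantile puts every sample on one side of the cut")
    return groups


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as (time, survival) step points.

    Starts at (0, 1); survival is non-increasing. All-censored input gives
    survival 1 everywhere.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("km_estimate requires at least one record")
    if (times <= 0).any():
        raise ValidationError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValidationError("logrank_test requires two non-empty groups")
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("logrank_test: no events in either group")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(times, events, covariate) -> tuple[float, float, float]:
    """Univariate Cox PH fit; returns (log hazard ratio, SE, Wald p).

    Partial likelihood is maximized with Breslow tie handling. Monotone
    separation (no finite maximizer) raises a convergence error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if events.sum() < 2:
        raise ValidationError("cox_univariate requires at least 2 events")
    if np.unique(x).size < 2:
        raise ValidationError("covariate does not vary")
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = PHReg(times, x[:, None], status=events, ties="breslow")
    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = model.fit(disp=False)
    except Exception as exc:  # numerical blow-up inside the optimizer
        raise ConvergenceError(f"Cox partial-likelihood maximization failed: {exc}") from exc
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise ConvergenceError(
            "Cox partial-likelihood maximization did not converge; the covariate "
            "may order the event times monotonically (no finite maximizer)"
        )
    coef = float(res.params[0])
    se = float(res.bse[0])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 50:
        raise ConvergenceError(
            f"Cox fit diverged (log HR {coef!r}); covariate likely separates event order monotonically"
        )
    p = float(res.pvalues[0])
    return coef, se, p


def survival_validation(
    bulk: ExpressionMatrix,
    survival: pd.DataFrame,
    signature,
    *,
    quantile: float = 0.5,
) -> dict:
    """Score -> dichotomize -> KM + log-rank + Cox, as one validation report."""
    survival = validate_survival(survival)
    scores = rank_signature_score(bulk, signature)
    s = scores.scores
    surv = survival.set_index("sample_id").loc[s.index]
    groups = dichotomize(s, quantile=quantile)
    hi = groups == "high"
    stat, p = logrank_test(
        surv.loc[hi, "time"], surv.loc[hi, "event"], surv.loc[~hi, "time"], surv.loc[~hi, "event"]
    )
    z = (s - s.mean()) / s.std(ddof=0)
    coef, se, cox_p = cox_univariate(surv["time"], surv["event"], z)
    return {
        "scores": scores,
        "groups": groups,
        "km_high": km_estimate(surv.loc[hi, "time"], surv.loc[hi, "event"]),
        "km_low": km_estimate(surv.loc[~hi, "time"], surv.loc[~hi, "event"]),
        "logrank": {"statistic": stat, "p_value": p},
        "cox": {"log_hr": coef, "se": se, "p_value": cox_p},
    }
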