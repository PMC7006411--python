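"""Personalized therapy ranking and adherence-outcome comparison.

From the six counterfactual predictions per cycle, the best-ranked therapy
DMT* minimizes the predicted mean relapse count (relapse model) or the
predicted CDP probability (CDP model).  To judge whether receiving DMT*
matters in practice, patients assigned the same DMT* are split into
receivers and non-receivers, the two groups are reweighted to the pooled
population with propensity-score average-treatment-effect (ATE) weights,
and the observed outcomes are compared in a weighted GLM with a log-duration
offset and robust (sandwich) standard errors:

    relapse:  NB GLM    observed relapses ~ took_dmt_star + offset(log T)
    CDP:      quasi-binomial GLM  observed CDP ~ took_dmt_star + offset(log T)

A negative slope on the receiver indicator means lower disease activity
among patients who received their top-ranked therapy.  Propensity scores
use age, relapses count in the prior year, categorized EDSS and diagnosis
distance; the propensity model is gradient-boosted trees with the boosting
stage chosen to minimize the mean absolute standardized mean difference
(a logistic-regression fallback is available), and groups with fewer than
10 observations on either side are excluded from the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import INDEX_DMTS

log = logging.getLogger(__name__)

#: default EDSS categories used for propensity covariates (configurable)
DEFAULT_EDSS_BREAKS = (1.5, 3.5)
#: covariates entering the propensity model
PROPENSITY_COVARIATES = ("age", "relapses_count", "edss_baseline", "diagnosis_distance")
#: minimum observations per condition for the weighted comparison
MIN_PER_CONDITION = 10
#: summaries closer than this are flagged as ties in the ranking
TIE_TOLERANCE = 1e-6


def rank_therapies(
    summaries: pd.DataFrame, response: str, tie_tolerance: float = TIE_TOLERANCE
) -> pd.DataFrame:
    """Rank the six DMTs per cycle by predicted outcome (ascending).

    ``summaries`` holds one column per DMT with the predicted mean relapse
    count or CDP probability.  DMT* is the argmin; exact or near ties (gap
    below ``tie_tolerance``) break alphabetically, which is the column order,
    and are flagged.  ``second_margin`` is the gap between the best and
    second-best prediction, used to flag rankings that small perturbations
    could flip.
    """
    missing = [d for d in INDEX_DMTS if d not in summaries.columns]
    if missing:
        raise ValueError(f"missing predictions for DMT(s): {missing}")
    vals = summaries[list(INDEX_DMTS)].to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("missing prediction values in ranking input")
    order = np.argsort(vals, axis=1, kind="stable")  # stable = alphabetical ties
    best = order[:, 0]
    sorted_vals = np.take_along_axis(vals, order, axis=1)
    margin = sorted_vals[:, 1] - sorted_vals[:, 0]
    return pd.DataFrame(
        {
            "dmt_star": np.array(INDEX_DMTS)[best],
            "predicted_best": sorted_vals[:, 0],
            "second_margin": margin,
            "tie": margin < tie_tolerance,
            "ranking": ["<".join(np.array(INDEX_DMTS)[o]) for o in order],
        },
        index=summaries.index,
    )


# ---------------------------------------------------------------------------
# Propensity weighting


@dataclass
class PropensityResult:
    weights: np.ndarray  # normalized ATE weights, mean 1 within each group
    propensity: np.ndarray
    method: str
    smd_before: pd.Series
    smd_after: pd.Series
    ess_received: float
    ess_not_received: float


def _propensity_design(cycles: pd.DataFrame, edss_breaks=DEFAULT_EDSS_BREAKS) -> pd.DataFrame:
    x = pd.DataFrame(
        {
            "age": cycles["age"].to_numpy(float),
            "relapses_count": cycles["relapses_count"].to_numpy(float),
            "diagnosis_distance": cycles["diagnosis_distance"].to_numpy(float),
        }
    )
    edss = cycles["edss_baseline"].to_numpy(float)
    lo, hi = edss_breaks
    x["edss_cat_mid"] = ((edss > lo) & (edss <= hi)).astype(float)
    x["edss_cat_high"] = (edss > hi).astype(float)
    return x


def _standardized_mean_differences(
    x: pd.DataFrame, received: np.ndarray, weights: np.ndarray | None = None
) -> pd.Series:
    """Absolute SMD per covariate, pooled-SD denominator (unweighted)."""
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    out = {}
    for col in x.columns:
        v = x[col].to_numpy(float)
        sd = np.std(v)
        if sd == 0:
            out[col] = 0.0
            continue
        m1 = np.average(v[received], weights=w[received])
        m0 = np.average(v[~received], weights=w[~received])
        out[col] = abs(m1 - m0) / sd
    return pd.Series(out)


def estimate_weights(
    cycles: pd.DataFrame,
    received: np.ndarray,
    method: str = "gbm",
    edss_breaks=DEFAULT_EDSS_BREAKS,
    seed: int = 0,
    max_stages: int = 300,
) -> PropensityResult:
    """ATE propensity weights balancing receivers and non-receivers.

    Fits a propensity model for receiving DMT* on age, relapses count,
    categorized EDSS and diagnosis distance, and returns normalized ATE
    weights ``1/e(x)`` for receivers and ``1/(1 - e(x))`` for the others,
    which reweight both groups to the pooled population.  The gradient-
    boosting variant evaluates every boosting stage and keeps the one with
    the smallest mean absolute standardized mean difference; ``method=
    "logistic"`` uses a plain logistic regression instead.
    """
    received = np.asarray(received).astype(bool)
    if not received.any() or received.all():
        raise ValueError("both receiver and non-receiver groups must be nonempty")
    x = _propensity_design(cycles, edss_breaks)
    smd_before = _standardized_mean_differences(x, received)

    if method == "gbm" and min(received.sum(), (~received).sum()) < 40:
        log.info("group too small for boosting; using logistic propensity model")
        method = "logistic"
    if method == "gbm":
        # cross-fitted boosting: each half is scored by a model trained on
        # the other half, so overfit propensities cannot fake balance, and
        # the boosting stage is the one minimizing the mean absolute SMD
        from sklearn.ensemble import GradientBoostingClassifier

        rng = np.random.default_rng(seed)
        fold = rng.integers(0, 2, len(x))
        xa = x.to_numpy()
        staged = [np.full(len(x), 0.5) for _ in range(max_stages)]
        for f in (0, 1):
            model = GradientBoostingClassifier(
                n_estimators=max_stages,
                learning_rate=0.05,
                max_depth=3,
                subsample=0.8,
                random_state=seed + f,
            )
            model.fit(xa[fold == f], received[fold == f].astype(int))
            for stage, proba in enumerate(model.staged_predict_proba(xa[fold != f])):
                staged[stage][fold != f] = proba[:, 1]
        best = None
        for stage in range(max_stages):
            e = np.clip(staged[stage], 1e-6, 1 - 1e-6)
            w = np.where(received, 1.0 / e, 1.0 / (1.0 - e))
            score = _standardized_mean_differences(x, received, w).mean()
            if best is None or score < best[0]:
                best = (score, stage, e)
        _, _, e = best
    elif method == "logistic":
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(max_iter=1000)
        lr.fit(x.to_numpy(), received.astype(int))
        e = np.clip(lr.predict_proba(x.to_numpy())[:, 1], 1e-6, 1 - 1e-6)
    else:
        raise ValueError(f"unknown propensity method {method!r}")

    if np.any(e <= 1e-6) or np.any(e >= 1 - 1e-6):
        raise ValueError(
            "propensity scores at the boundary (near-perfect separation); "
            "weights would be unstable"
        )
    weights = np.where(received, 1.0 / e, 1.0 / (1.0 - e))
    # normalize to mean 1 within each group (stabilization only)
    weights = weights.astype(float)
    weights[received] /= weights[received].mean()
    weights[~received] /= weights[~received].mean()
    smd_after = _standardized_mean_differences(x, received, weights)

    def ess(w):
        return float(w.sum() ** 2 / np.sum(w**2))

    return PropensityResult(
        weights=weights,
        propensity=e,
        method=method,
        smd_before=smd_before,
        smd_after=smd_after,
        ess_received=ess(weights[received]),
        ess_not_received=ess(weights[~received]),
    )


# ---------------------------------------------------------------------------
# Weighted outcome GLMs


@dataclass
class WeightedComparison:
    dmt_star: str
    response: str
    slope: float | None
    p_value: float | None
    n_received: int
    n_not_received: int
    smd_max_after: float | None = None
    excluded_reason: str | None = None


def _estimate_nb_alpha(y, X, offset, weights, n_iter: int = 3) -> float:
    """Cameron-Trivedi auxiliary OLS estimate of the NB2 overdispersion."""
    alpha = 0.5
    for _ in range(n_iter):
        fam = sm.families.NegativeBinomial(alpha=alpha)
        res = sm.GLM(y, X, family=fam, offset=offset, var_weights=weights).fit()
        mu = res.mu
        aux = ((y - mu) ** 2 - y) / mu
        num = float(np.sum(weights * aux * mu))
        den = float(np.sum(weights * mu**2))
        alpha = max(num / den, 1e-3)
    return alpha


def weighted_outcome_glm(
    cycles: pd.DataFrame,
    weights: np.ndarray,
    received: np.ndarray,
    response: str,
    dmt_star: str = "",
) -> WeightedComparison:
    """Weighted GLM of the observed outcome on the receiver indicator.

    Relapse: negative binomial GLM (overdispersion estimated by iterated
    auxiliary regression) of ``n_relapses``; CDP: quasi-binomial GLM of the
    CDP flag; both with offset ``log(index_duration)``, propensity weights
    as variance weights, and HC1 sandwich covariance for the Wald p-value.
    """
    received = np.asarray(received).astype(bool)
    n1, n0 = int(received.sum()), int((~received).sum())
    if min(n1, n0) < MIN_PER_CONDITION:
        return WeightedComparison(
            dmt_star=dmt_star,
            response=response,
            slope=None,
            p_value=None,
            n_received=n1,
            n_not_received=n0,
            excluded_reason=f"fewer than {MIN_PER_CONDITION} observations in a condition",
        )
    durations = cycles["index_duration"].to_numpy(float)
    if np.any(durations <= 0):
        raise ValueError("index_duration must be positive (log offset)")
    offset = np.log(durations)
    X = sm.add_constant(received.astype(float))
    w = np.asarray(weights, float)
    if response == "relapse":
        y = cycles["n_relapses"].to_numpy(float)
        alpha = _estimate_nb_alpha(y, X, offset, w)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        res = sm.GLM(y, X, family=fam, offset=offset, var_weights=w).fit(
            cov_type="HC1"
        )
    elif response == "cdp":
        y = cycles["cdp"].to_numpy(bool).astype(float)
        res = sm.GLM(
            y, X, family=sm.families.Binomial(), offset=offset, var_weights=w
        ).fit(cov_type="HC1", scale="X2")  # quasi-binomial scale
    else:
        raise ValueError(f"unknown response {response!r}")
    return WeightedComparison(
        dmt_star=dmt_star,
        response=response,
        slope=float(res.params[1]),
        p_value=float(res.pvalues[1]),
        n_received=n1,
        n_not_received=n0,
    )


def run_adherence_comparison(
    cohort: pd.DataFrame,
    rankings: pd.DataFrame,
    response: str,
    method: str = "gbm",
    seed: int = 0,
) -> pd.DataFrame:
    """Receivers-vs-non-receivers comparison per DMT* level.

    For each therapy appearing as someone's top rank, patients with that
    DMT* are split by whether their observed index therapy is the top rank;
    levels with both groups present and at least 10 observations each are
    propensity-weighted and compared in the weighted GLM.  Returns one row
    per DMT* level (at most six) with slope, p-value, group sizes, balance
    diagnostics and the exclusion reason where applicable.
    """
    rows = []
    for dmt in INDEX_DMTS:
        mask = (rankings["dmt_star"] == dmt).to_numpy()
        if not mask.any():
            rows.append(
                WeightedComparison(
                    dmt_star=dmt, response=response, slope=None, p_value=None,
                    n_received=0, n_not_received=0,
                    excluded_reason="no patient ranked this DMT first",
                )
            )
            continue
        sub = cohort[mask]
        received = (sub["index_dmt"] == dmt).to_numpy()
        n1, n0 = int(received.sum()), int((~received).sum())
        if min(n1, n0) < MIN_PER_CONDITION:
            rows.append(
                WeightedComparison(
                    dmt_star=dmt, response=response, slope=None, p_value=None,
                    n_received=n1, n_not_received=n0,
                    excluded_reason=f"fewer than {MIN_PER_CONDITION} observations in a condition",
                )
            )
            log.info("DMT* level %s excluded (%d received / %d not)", dmt, n1, n0)
            continue
        prop = estimate_weights(sub, received, method=method, seed=seed)
        result = weighted_outcome_glm(
            sub, prop.weights, received, response, dmt_star=dmt
        )
        result.smd_max_after = float(prop.smd_after.max())
        rows.append(result)
    return pd.DataFrame([r.__dict__ for r in rows])
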