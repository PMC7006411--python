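"""Performance measures and out-of-sample validation schemes.

Measures
--------
* binned calibration with equally populated bins,
* mean squared error (posterior-mean count vs observed count for the relapse
  model; predicted event probability vs 0/1 outcome for the CDP model),
* total negative log-likelihood (negative log pointwise predictive density),
* Harrell's concordance index over duration-matched cycle pairs: two cycles
  are comparable when their index durations differ by at most half a year if
  the shorter is under half a year, and by at most one year otherwise.

Schemes
-------
* repeated k-fold cross-validation with patient-level folds (out-of-sample
  prediction from the held-out fold's model; in-sample prediction from one
  randomly chosen other fold's model, so each cycle gets exactly one of
  each), with standard errors over repeats;
* leave-one-site-out cross-validation;
* a held-out test set (via :func:`dmtrank.cohort.split_test` upstream).

All predictions zero the site random intercepts, the prediction path used
for new patients and sites, and measures use only the prediction for the
cycle's observed index therapy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import glm
from .glm import MCMCConfig, ModelSpec, PosteriorFit

log = logging.getLogger(__name__)

#: duration-matching thresholds, years
MATCH_SHORT_CUTOFF = 0.5
MATCH_TOL_SHORT = 0.5
MATCH_TOL_LONG = 1.0

#: right-closed forecast windows (years) for duration-stratified evaluation
DEFAULT_WINDOWS = ((0.0, 0.5), (0.5, 1.5), (1.5, 2.5), (2.5, 3.5), (3.5, 4.5), (4.5, 5.5))


# ---------------------------------------------------------------------------
# Measures


def calibration(
    predictions: np.ndarray,
    observations: np.ndarray,
    n_bins: int = 20,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Equally-populated calibration bins over the predicted-outcome range.

    Sorts cycles by predicted outcome (stable sort, so tied predictions stay
    in input order) and splits them into ``n_bins`` bins whose populations
    differ by at most one, the remainder going to the leading bins.  Returns
    per-bin population, mean predicted and mean observed outcome, and the
    prediction range covered.  With ``groups`` (e.g. the index DMT per
    cycle) the binning is repeated within each group and the tables are
    stacked with a ``group`` column.
    """
    if groups is not None:
        groups = np.asarray(groups)
        parts = []
        for g in pd.unique(groups):
            m = groups == g
            parts.append(
                calibration(predictions[m], observations[m], n_bins).assign(group=g)
            )
        return pd.concat(parts, ignore_index=True)
    predictions = np.asarray(predictions, float)
    observations = np.asarray(observations, float)
    if predictions.shape != observations.shape:
        raise ValueError("predictions and observations must be aligned")
    n = predictions.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} observations, got {n}")
    order = np.argsort(predictions, kind="mergesort")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    rows = []
    start = 0
    for b, size in enumerate(sizes):
        idx = order[start : start + size]
        rows.append(
            {
                "bin": b,
                "n": int(size),
                "pred_mean": predictions[idx].mean(),
                "obs_mean": observations[idx].mean(),
                "pred_min": predictions[idx].min(),
                "pred_max": predictions[idx].max(),
            }
        )
        start += size
    return pd.DataFrame(rows)


def match_pairs(durations: np.ndarray) -> np.ndarray:
    """Unordered unique index pairs with roughly the same exposure duration.

    Pair (i, j) qualifies iff |T_i - T_j| <= 0.5 y when min(T_i, T_j) < 0.5 y
    and |T_i - T_j| <= 1.0 y otherwise.  Returns an (m, 2) integer array with
    i < j.
    """
    t = np.asarray(durations, float)
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    diff = np.abs(t[:, None] - t[None, :])
    shorter = np.minimum(t[:, None], t[None, :])
    tol = np.where(shorter < MATCH_SHORT_CUTOFF, MATCH_TOL_SHORT, MATCH_TOL_LONG)
    ok = diff <= tol
    i, j = np.triu_indices(t.size, k=1)
    keep = ok[i, j]
    return np.column_stack([i[keep], j[keep]])


def c_index(
    pairs: np.ndarray, scores: np.ndarray, events: np.ndarray
) -> tuple[float, int]:
    """Concordance over outcome-discordant matched pairs (Harrell convention).

    A pair counts when exactly one member has the event; it is concordant
    when the event-bearing cycle has the higher predicted score, and tied
    predictions credit 0.5.  Returns (c-index, number of usable pairs).
    """
    scores = np.asarray(scores, float)
    events = np.asarray(events).astype(bool)
    if len(pairs) == 0:
        raise ValueError("no matched pairs available")
    i, j = pairs[:, 0], pairs[:, 1]
    usable = events[i] != events[j]
    if not usable.any():
        raise ValueError("no outcome-discordant matched pairs; C-index undefined")
    i, j = i[usable], j[usable]
    s_event = np.where(events[i], scores[i], scores[j])
    s_other = np.where(events[i], scores[j], scores[i])
    credit = np.where(s_event > s_other, 1.0, np.where(s_event == s_other, 0.5, 0.0))
    return float(credit.mean()), int(usable.sum())


def mse(predictions: np.ndarray, observations: np.ndarray) -> float:
    predictions = np.asarray(predictions, float)
    observations = np.asarray(observations, float)
    if predictions.shape != observations.shape:
        raise ValueError("predictions and observations must be aligned")
    return float(np.mean((predictions - observations) ** 2))


# ---------------------------------------------------------------------------
# Per-cycle prediction frames and measure aggregation


def predict_observed_therapy(fit: PosteriorFit, cycles: pd.DataFrame) -> pd.DataFrame:
    """Predictions for each cycle's observed index therapy, sites zeroed.

    Returns one row per cycle with the point prediction (``pred``: expected
    count or event probability), the concordance score (``score``), the
    binarized observed event and the per-cycle log predictive density.
    """
    summary = glm.predict_counterfactual(fit, cycles)
    lppd, _ = glm.pointwise_log_lik(fit, cycles, zero_site=True)
    if fit.spec.response == "relapse":
        observed = cycles["n_relapses"].to_numpy(float)
        event = observed >= 1
    else:
        observed = cycles["cdp"].to_numpy(bool).astype(float)
        event = observed > 0
    # score to discriminate events: expected count, or CDP probability,
    # equivalently 1 - fraction of draws predicting a favorable outcome
    return pd.DataFrame(
        {
            "patient_id": cycles["patient_id"].to_numpy(),
            "duration": cycles["index_duration"].to_numpy(float),
            "pred": summary.mean,
            "score": 1.0 - summary.frac_favorable,
            "observed": observed,
            "event": event,
            "log_lik": lppd,
        }
    )


def compute_measures(frame: pd.DataFrame) -> dict[str, float]:
    """MSE, total NLL and duration-matched C-index of a prediction frame."""
    out = {
        "mse": mse(frame["pred"].to_numpy(), frame["observed"].to_numpy()),
        "nll": float(-frame["log_lik"].sum()),
    }
    pairs = match_pairs(frame["duration"].to_numpy())
    try:
        ci, n_pairs = c_index(
            pairs, frame["score"].to_numpy(), frame["event"].to_numpy()
        )
    except ValueError:
        ci, n_pairs = np.nan, 0
    out["c_index"] = ci
    out["n_pairs"] = float(n_pairs)
    out["n_obs"] = float(len(frame))
    return out


@dataclass
class ValidationReport:
    scheme: str
    response: str
    complexity: str
    out_of_sample: dict[str, float]
    in_sample: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    per_repeat: pd.DataFrame | None = None
    per_site: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split, meas in (("out_of_sample", self.out_of_sample), ("in_sample", self.in_sample)):
            for k, v in meas.items():
                rows.append(
                    {
                        "scheme": self.scheme,
                        "response": self.response,
                        "complexity": self.complexity,
                        "split": split,
                        "measure": k,
                        "value": v,
                        "se": self.se.get(f"{split}.{k}", np.nan),
                    }
                )
        return pd.DataFrame(rows)


Fitter = Callable[[ModelSpec, pd.DataFrame], PosteriorFit]


def _default_fitter(mcmc: MCMCConfig) -> Fitter:
    def fitter(spec: ModelSpec, train: pd.DataFrame) -> PosteriorFit:
        return glm.fit(spec, train, mcmc=mcmc)

    return fitter


def _fold_assignment(patients: np.ndarray, k: int, rng: np.random.Generator) -> dict:
    perm = rng.permutation(np.sort(patients))
    return {pid: i % k for i, pid in enumerate(perm)}


def run_kfold(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    k: int = 10,
    repeats: int = 40,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    fitter: Fitter | None = None,
) -> ValidationReport:
    """Repeated k-fold cross-validation with patient-level fold assignment.

    Per repeat every cycle receives exactly one out-of-sample prediction
    (from the model fitted without its fold) and one in-sample prediction
    (from the model of one uniformly chosen other fold, whose training data
    contain the cycle).  Standard errors of each measure are computed over
    repeats.  Folds whose fit fails to converge are dropped with a warning
    and the repeat is discarded.
    """
    if len(cohort) < k:
        raise ValueError("cohort smaller than the number of folds")
    fitter = fitter or _default_fitter(mcmc or MCMCConfig())
    rng = np.random.default_rng(seed)
    repeat_rows = []
    for rep in range(repeats):
        assign = _fold_assignment(cohort["patient_id"].unique(), k, rng)
        fold_of = cohort["patient_id"].map(assign).to_numpy()
        try:
            fits = {
                f: fitter(spec, cohort[fold_of != f]) for f in range(k)
            }
        except glm.ConvergenceError as exc:
            log.warning("repeat %d dropped: %s", rep, exc)
            continue
        oos_parts, is_parts = [], []
        for f in range(k):
            held = cohort[fold_of == f]
            if len(held) == 0:
                continue
            oos_parts.append(predict_observed_therapy(fits[f], held))
            other = int(rng.choice([g for g in range(k) if g != f]))
            is_parts.append(predict_observed_therapy(fits[other], held))
        oos = pd.concat(oos_parts, ignore_index=True)
        ins = pd.concat(is_parts, ignore_index=True)
        row = {f"out_of_sample.{m}": v for m, v in compute_measures(oos).items()}
        row |= {f"in_sample.{m}": v for m, v in compute_measures(ins).items()}
        row["repeat"] = rep
        repeat_rows.append(row)
    if not repeat_rows:
        raise glm.ConvergenceError("every cross-validation repeat failed to converge")
    per_repeat = pd.DataFrame(repeat_rows).set_index("repeat")
    means = per_repeat.mean()
    ses = per_repeat.std(ddof=1) / np.sqrt(len(per_repeat)) if len(per_repeat) > 1 else per_repeat.iloc[0] * np.nan
    return ValidationReport(
        scheme="kfold",
        response=spec.response,
        complexity=spec.complexity,
        out_of_sample={
            m.split(".", 1)[1]: float(means[m]) for m in means.index if m.startswith("out_of_sample.")
        },
        in_sample={
            m.split(".", 1)[1]: float(means[m]) for m in means.index if m.startswith("in_sample.")
        },
        se={m: float(ses[m]) for m in means.index},
        per_repeat=per_repeat,
    )


def run_leave_one_site_out(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    fitter: Fitter | None = None,
) -> ValidationReport:
    """Leave-one-site-out cross-validation over clinical sites.

    For each site, the model is fitted without that site's patients and the
    held-out site's cycles are predicted with the random intercept zeroed
    (a new site has no estimated intercept).  In-sample predictions come
    from the same fits evaluated on their own training cycles.  Also
    reports the per-held-out-site NLL dispersion.
    """
    sites = np.sort(cohort["site_id"].unique())
    if len(sites) < 3:
        raise ValueError("leave-one-site-out needs at least 3 sites")
    fitter = fitter or _default_fitter(mcmc or MCMCConfig())
    oos_parts, site_rows, is_measures = [], [], []
    for site in sites:
        held = cohort[cohort["site_id"] == site]
        train = cohort[cohort["site_id"] != site]
        try:
            f = fitter(spec, train)
        except glm.ConvergenceError as exc:
            log.warning("site %s dropped: %s", site, exc)
            continue
        frame = predict_observed_therapy(f, held)
        oos_parts.append(frame)
        site_rows.append(
            {
                "site_id": site,
                "n": len(held),
                "nll_total": float(-frame["log_lik"].sum()),
                "nll_mean": float(-frame["log_lik"].mean()),
            }
        )
        is_measures.append(compute_measures(predict_observed_therapy(f, train)))
    if not oos_parts:
        raise glm.ConvergenceError("no leave-one-site-out fit converged")
    oos = pd.concat(oos_parts, ignore_index=True)
    in_sample = {
        m: float(np.mean([d[m] for d in is_measures])) for m in is_measures[0]
    }
    return ValidationReport(
        scheme="leave_one_site_out",
        response=spec.response,
        complexity=spec.complexity,
        out_of_sample=compute_measures(oos),
        in_sample=in_sample,
        per_site=pd.DataFrame(site_rows),
    )


def run_test_set(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    fitter: Fitter | None = None,
) -> ValidationReport:
    """Fit on the development set, evaluate on the held-out test set."""
    fitter = fitter or _default_fitter(mcmc or MCMCConfig())
    f = fitter(spec, train)
    return ValidationReport(
        scheme="test_set",
        response=spec.response,
        complexity=spec.complexity,
        out_of_sample=compute_measures(predict_observed_therapy(f, test)),
        in_sample=compute_measures(predict_observed_therapy(f, train)),
    )


def window_stratified_eval(
    frame: pd.DataFrame, windows: Sequence[tuple[float, float]] = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Measures within right-closed forecast-duration windows.

    A cycle with duration d falls in window (lo, hi] iff lo < d <= hi;
    concordance pairs are restricted to cycles of the same stratum.  Empty
    strata are reported with missing measures.
    """
    rows = []
    for lo, hi in windows:
        sub = frame[(frame["duration"] > lo) & (frame["duration"] <= hi)]
        row = {"window_lo": lo, "window_hi": hi, "n_obs": len(sub)}
        if len(sub):
            row |= compute_measures(sub.reset_index(drop=True))
        else:
            row |= {"mse": np.nan, "nll": np.nan, "c_index": np.nan, "n_pairs": 0.0}
        rows.append(row)
    return pd.DataFrame(rows)


def compare_nested(
    cohort: pd.DataFrame,
    responses: Sequence[str] = ("relapse", "cdp"),
    prior: glm.PriorConfig | None = None,
    k: int = 10,
    repeats: int = 1,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    fitter: Fitter | None = None,
) -> pd.DataFrame:
    """Out-of-sample comparison of the three nested model complexities.

    Runs the k-fold scheme for every (response, complexity) combination and
    returns a tidy table of out-of-sample and in-sample measures mirroring
    the layout of a nested-model performance table.
    """
    prior = prior or glm.PriorConfig()
    frames = []
    for response in responses:
        for complexity in ("non_personalized", "prognostic", "predictive"):
            spec = ModelSpec(response=response, complexity=complexity, prior=prior)
            report = run_kfold(
                spec, cohort, k=k, repeats=repeats, seed=seed, mcmc=mcmc, fitter=fitter
            )
            frames.append(report.to_frame())
    return pd.concat(frames, ignore_index=True)


def sensitivity_scan(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    prior_scales: Sequence[float] = (1.0, 2.0),
    subsample_fractions: Sequence[float] = (),
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    tie_tolerance: float = 1e-6,
    near_tie_tolerance: float = 0.02,
) -> pd.DataFrame:
    """Stability of the personalized therapy ranking under perturbations.

    Refits the model with every prior-scale multiplier and training
    subsample, recomputes each cycle's best-ranked therapy, and reports the
    fraction of cycles whose top therapy agrees with the baseline fit,
    overall and among cycles whose baseline top-two predictions are
    separated by more than ``near_tie_tolerance`` (near-tied cycles are
    flagged: their ranking is not expected to be stable).
    """
    from .compare import rank_therapies

    mcmc = mcmc or MCMCConfig()
    rng = np.random.default_rng(seed)
    base_fit = glm.fit(spec, cohort, mcmc=mcmc)
    base_rank = rank_therapies(
        glm.predict_all_dmts(base_fit, cohort), spec.response, tie_tolerance
    )
    base_best = base_rank["dmt_star"].to_numpy()
    sep = base_rank["second_margin"].to_numpy()
    clear = sep > near_tie_tolerance

    variants: list[tuple[str, glm.ModelSpec, pd.DataFrame]] = []
    for s in prior_scales:
        variants.append(
            (
                f"prior_scale_x{s:g}",
                ModelSpec(spec.response, spec.complexity, spec.prior.scaled(s)),
                cohort,
            )
        )
    for frac in subsample_fractions:
        keep = rng.random(len(cohort)) < frac
        variants.append((f"subsample_{frac:g}", spec, cohort[keep]))

    rows = []
    for name, vspec, data in variants:
        if vspec == spec and data is cohort:
            vfit = base_fit  # identity variant: agreement is exactly 1
        else:
            vmcmc = MCMCConfig(**{**mcmc.__dict__, "seed": int(rng.integers(2**31 - 1))})
            vfit = glm.fit(vspec, data, mcmc=vmcmc)
        vrank = rank_therapies(
            glm.predict_all_dmts(vfit, cohort), spec.response, tie_tolerance
        )
        agree = vrank["dmt_star"].to_numpy() == base_best
        rows.append(
            {
                "variant": name,
                "agreement": float(agree.mean()),
                "agreement_clear": float(agree[clear].mean()) if clear.any() else np.nan,
                "n_near_tied": int((~clear).sum()),
                "n": len(cohort),
            }
        )
    return pd.DataFrame(rows)
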