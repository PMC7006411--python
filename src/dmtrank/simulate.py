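"""Synthetic RRMS registry generator with known ground truth.

Emulates the structure of a multi-site therapy-cycle registry: patient
covariates with plausible relapsing-remitting MS marginals, assignment to
one of six index DMTs (uniform-ish or covariate-dependent for confounding
studies), site-level random intercepts, negative-binomial on-therapy relapse
counts with a log-exposure offset, and Bernoulli CDP events on the logit
scale with the same offset.  Every realized parameter is returned so that
downstream fitting, validation, ranking and weighting stages can be tested
against known truth.

The generative laws mirror the fitted models exactly:

* ``relapses ~ NegBin(mean = T * exp(x'b + u_s), shape)`` with variance
  ``mu + mu^2/shape``;
* ``CDP ~ Bernoulli(logit^-1(x'g + u_s + log T))``.

True coefficients are expressed on the fitted models' own parameter scale,
i.e. per design column of :func:`dmtrank.glm.build_design` (continuous
predictors standardized on the generated sample).  Defaults below are
chosen as plausible for a treated RRMS population (on-therapy annualized
relapse rate around 0.35, annual CDP risk around 8-10%, moderate between-
site heterogeneity) and are all overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from . import glm
from .cohort import INDEX_DMTS, CURRENT_DMTS, EdssTrajectory

#: default true effects for the relapse model, per design column
DEFAULT_TRUE_RELAPSE: dict[str, float] = {
    "index_dmt[FTY]": -0.15,
    "index_dmt[GA]": 0.20,
    "index_dmt[IF]": 0.15,
    "index_dmt[NA]": -0.45,
    "index_dmt[TERI]": 0.10,
    "age": -0.15,
    "edss_baseline": 0.10,
    "relapses_count": 0.25,
    "relapse_distance": -0.10,
    "second_line[True]": 0.10,
}
#: default true effects for the CDP model, per design column
DEFAULT_TRUE_CDP: dict[str, float] = {
    "index_dmt[FTY]": -0.10,
    "index_dmt[GA]": 0.10,
    "index_dmt[IF]": 0.10,
    "index_dmt[NA]": -0.30,
    "index_dmt[TERI]": 0.05,
    "age": 0.10,
    "edss_baseline": 0.30,
    "relapses_count": 0.10,
}

DEFAULT_INTERCEPTS = {"relapse": float(np.log(0.35)), "cdp": -2.4}


@dataclass
class SimConfig:
    """Study conditions for one synthetic registry."""

    n_patients: int = 3400
    n_sites: int = 78
    site_sd: float = 0.25
    dispersion: float = 1.2  # NB shape; variance = mu + mu^2/shape
    intercepts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS)
    )
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "relapse": dict(DEFAULT_TRUE_RELAPSE),
            "cdp": dict(DEFAULT_TRUE_CDP),
        }
    )
    #: DMT assignment: "random" draws from dmt_marginals; "confounded" tilts
    #: second-line DMTs toward patients with more recent relapses/higher EDSS
    assignment: Literal["random", "confounded"] = "random"
    confounding_strength: float = 0.8
    dmt_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "DMF": 0.22, "FTY": 0.25, "GA": 0.13, "IF": 0.18, "NA": 0.09,
            "TERI": 0.13,
        }
    )
    duration_shape: float = 2.0  # Gamma shape of index duration (years)
    duration_mean: float = 2.0
    duration_min: float = 0.3
    duration_max: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be at least 2")
        if self.site_sd < 0:
            raise ValueError("site_sd must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """Everything realized by the generator, for parameter-recovery tests."""

    config: SimConfig
    columns: list[str]
    transform: glm.DesignTransform
    site_levels: list
    intercept: dict[str, float]
    beta: dict[str, np.ndarray]  # per response, aligned with columns
    site_u: dict[str, np.ndarray]
    eta: dict[str, np.ndarray]  # per-cycle linear predictor incl. site + offset
    mean_by_dmt: dict[str, pd.DataFrame]  # per response: n x 6, site zeroed
    dispersion: float
    site_sd: float

    def true_fit(self, response: str) -> glm.PosteriorFit:
        """The generator's true model packaged as a degenerate one-draw fit."""
        spec = glm.ModelSpec(response=response, complexity="predictive")
        return glm.PosteriorFit.from_point(
            spec=spec,
            columns=self.columns,
            transform=self.transform,
            site_levels=self.site_levels,
            intercept=self.intercept[response],
            beta=self.beta[response],
            site_u=self.site_u[response],
            site_sd=self.site_sd,
            dispersion=self.dispersion if response == "relapse" else None,
        )

    def best_dmt(self, response: str) -> pd.Series:
        """True best therapy per cycle (lowest expected outcome, sites zeroed)."""
        return self.mean_by_dmt[response].idxmin(axis=1)


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    age = np.clip(rng.normal(40.0, 11.0, n), 18.0, 75.0)
    gender = np.where(rng.random(n) < 0.7, "F", "M")
    edss = np.clip(np.round(rng.gamma(2.0, 1.1, n) * 2.0) / 2.0, 0.0, 6.0)
    diagnosis_distance = 0.6 + rng.exponential(5.5, n)
    # kept >= ~0.31 y so the baseline EDSS 84-day validity rule is satisfiable
    relapse_distance = 0.32 + rng.exponential(0.6, n)
    relapses_count = 1 + rng.poisson(0.8, n)
    dmts_count = rng.poisson(1.2, n)
    second_line = (dmts_count > 0) & (rng.random(n) < 0.35)
    current_dmt = np.where(
        dmts_count == 0,
        "NONE",
        rng.choice(INDEX_DMTS, size=n),
    )
    current_duration = np.where(
        current_dmt == "NONE", 0.0, rng.gamma(1.5, 1.0, n)
    )
    duration = np.clip(
        rng.gamma(cfg.duration_shape, cfg.duration_mean / cfg.duration_shape, n),
        cfg.duration_min,
        cfg.duration_max,
    )
    site_weights = rng.dirichlet(np.full(cfg.n_sites, 2.0))
    site = rng.choice(cfg.n_sites, size=n, p=site_weights)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "site_id": [f"S{s:03d}" for s in site],
            "age": age,
            "gender": gender,
            "edss_baseline": edss,
            "diagnosis_distance": diagnosis_distance,
            "relapse_distance": relapse_distance,
            "relapses_count": relapses_count,
            "dmts_count": dmts_count,
            "second_line": second_line,
            "current_dmt": current_dmt,
            "current_duration": current_duration,
            "index_duration": duration,
        }
    )


def _assign_dmt(cfg: SimConfig, cov: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    base = np.array([cfg.dmt_marginals[d] for d in INDEX_DMTS])
    logits = np.log(np.tile(base, (len(cov), 1)))
    if cfg.assignment == "confounded":
        # sicker patients (more recent relapses, higher EDSS) steered toward
        # the second-line therapies FTY and NA
        severity = (
            0.5 * (cov["relapses_count"].to_numpy(float) - 1.8)
            + 0.3 * (cov["edss_baseline"].to_numpy(float) - 2.0)
        )
        for second in ("FTY", "NA"):
            j = INDEX_DMTS.index(second)
            logits[:, j] += cfg.confounding_strength * severity
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(cov))[:, None]
    return np.array(INDEX_DMTS)[(u > cum).sum(axis=1)]


def _beta_vector(columns: list[str], effects: dict[str, float]) -> np.ndarray:
    unknown = set(effects) - set(columns)
    if unknown:
        raise KeyError(f"true coefficient(s) for unknown design column(s): {sorted(unknown)}")
    return np.array([effects.get(c, 0.0) for c in columns])


def generate_registry(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, EdssTrajectory], GroundTruth]:
    """Generate one synthetic registry: cycle table, trajectories, truth.

    Outcome draws per cycle: ``u_s ~ Normal(0, site_sd^2)`` per response;
    ``relapses ~ NegBin(mean = T * exp(x'b + u_s), shape)`` via the
    gamma-Poisson mixture; ``cdp ~ Bernoulli(logit^-1(x'g + u_s + log T))``.
    Byte-identical output for equal seeds.
    """
    rng = np.random.default_rng(config.seed)
    cov = _draw_covariates(config, rng)
    cov["index_dmt"] = _assign_dmt(config, cov, rng)

    spec = glm.ModelSpec(response="relapse", complexity="predictive")
    design = glm.build_design(cov, spec)
    betas = {
        r: _beta_vector(design.columns, config.true_coefficients.get(r, {}))
        for r in ("relapse", "cdp")
    }
    site_u = {
        r: rng.normal(0.0, config.site_sd, len(design.site_levels))
        for r in ("relapse", "cdp")
    }

    eta = {}
    for r in ("relapse", "cdp"):
        eta[r] = (
            config.intercepts[r]
            + design.X @ betas[r]
            + site_u[r][design.site_index]
            + design.offset
        )
    mu = np.exp(eta["relapse"])
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    cov["n_relapses"] = rng.poisson(lam)
    p_cdp = expit(eta["cdp"])
    cov["cdp"] = rng.random(len(cov)) < p_cdp

    mean_by_dmt = {}
    for r in ("relapse", "cdp"):
        cols = {}
        for dmt in INDEX_DMTS:
            alt = cov.copy()
            alt["index_dmt"] = dmt
            d_alt = glm.build_design(
                alt, spec, transform=design.transform, site_levels=design.site_levels
            )
            eta_alt = config.intercepts[r] + d_alt.X @ betas[r] + d_alt.offset
            cols[dmt] = np.exp(eta_alt) if r == "relapse" else expit(eta_alt)
        mean_by_dmt[r] = pd.DataFrame(cols, index=cov.index)

    truth = GroundTruth(
        config=config,
        columns=design.columns,
        transform=design.transform,
        site_levels=design.site_levels,
        intercept=dict(config.intercepts),
        beta=betas,
        site_u=site_u,
        eta=eta,
        mean_by_dmt=mean_by_dmt,
        dispersion=config.dispersion,
        site_sd=config.site_sd,
    )
    trajectories = _emit_trajectories(cov, rng)
    return cov, trajectories, truth


def _emit_trajectories(
    cycles: pd.DataFrame, rng: np.random.Generator
) -> dict[str, EdssTrajectory]:
    """EDSS series and relapse dates consistent with each cycle's endpoints.

    The cycle runs over days [0, 365 * index_duration].  The baseline
    measurement sits 5 days before the start, so it is always the
    measurement closest to the start (hence the reference the CDP rule
    picks) and is valid: the last pre-index relapse lies at least 110 days
    earlier by construction of ``relapse_distance``.  When the cycle's CDP
    flag is set, a sustained, confirmed progression is placed early in the
    cycle; on-therapy relapses are placed after the confirmation so they
    never invalidate it.
    """
    out: dict[str, EdssTrajectory] = {}
    for row in cycles.itertuples(index=False):
        end = 365.0 * float(row.index_duration)
        ref = float(row.edss_baseline)
        times = [-5.0]
        scores = [ref]
        relapses = [-365.0 * float(row.relapse_distance)]
        step = 1.0 if ref <= 5.5 else 0.5
        if bool(row.cdp):
            p1 = 10.0
            p2 = min(p1 + 92.0, end - 1.0)
            times += [p1, p2]
            scores += [min(ref + step, 10.0), min(ref + step, 10.0)]
            first_relapse_day = p2 + 2.0
        else:
            t = 150.0
            while t < end:
                times.append(t)
                scores.append(ref)
                t += 140.0
            first_relapse_day = 5.0
        n_rel = int(row.n_relapses)
        if n_rel:
            span = max(end - first_relapse_day - 1.0, 1.0)
            days = first_relapse_day + span * (np.arange(n_rel) + 0.5) / n_rel
            # drop follow-up measurements within 84 d after an on-therapy relapse
            keep_t, keep_s = [], []
            for t, s in zip(times, scores):
                if t <= 0 or all(not (d < t <= d + 84.0) for d in days):
                    keep_t.append(t)
                    keep_s.append(s)
            times, scores = keep_t, keep_s
            relapses.extend(days.tolist())
        order = np.argsort(times)
        out[row.patient_id] = EdssTrajectory(
            patient_id=row.patient_id,
            times=np.asarray(times)[order],
            edss=np.asarray(scores)[order],
            relapse_days=np.sort(relapses),
        )
    return out


# ---------------------------------------------------------------------------
# Labelled trajectory fixtures for the CDP detector


def generate_trajectories_with_cdp(
    n: int, seed: int = 0
) -> list[tuple[EdssTrajectory, float, float, bool]]:
    """Constructed EDSS series with known CDP truth labels.

    Cycles through templates that exercise the detector's edges: the
    1.0-versus-0.5 worsening threshold, the 91-day sustainment rule, the
    confirmation requirement, post-relapse measurement validity, and
    baseline selection.  Returns ``(trajectory, cycle_start, cycle_end,
    label)`` tuples; labels are ground truth by construction.
    """
    rng = np.random.default_rng(seed)
    out = []
    templates = (
        _tpl_progression,
        _tpl_progression_high_base,
        _tpl_subthreshold,
        _tpl_transient,
        _tpl_unconfirmed,
        _tpl_invalid_confirmation,
        _tpl_inflated_baseline,
        _tpl_stable,
        _tpl_progression_with_relapses,
        _tpl_late_unsustained,
    )
    for i in range(n):
        tpl = templates[i % len(templates)]
        out.append(tpl(f"T{i:05d}", rng))
    return out


def _grid(x: float) -> float:
    return float(np.clip(np.round(x * 2.0) / 2.0, 0.0, 10.0))


def _tpl_progression(pid, rng):
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(60, 200)
    t2 = t1 + rng.uniform(95, 200)
    traj = EdssTrajectory(pid, [-40.0, t1, t2], [ref, ref + 1.0, ref + 1.0])
    return traj, 0.0, t2 + 30.0, True


def _tpl_progression_high_base(pid, rng):
    ref = _grid(rng.uniform(6.0, 6.5))
    t1 = rng.uniform(60, 200)
    t2 = t1 + rng.uniform(95, 200)
    traj = EdssTrajectory(pid, [-40.0, t1, t2], [ref, ref + 0.5, ref + 0.5])
    return traj, 0.0, t2 + 30.0, True


def _tpl_subthreshold(pid, rng):
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(60, 200)
    t2 = t1 + rng.uniform(95, 200)
    traj = EdssTrajectory(pid, [-40.0, t1, t2], [ref, ref + 0.5, ref + 0.5])
    return traj, 0.0, t2 + 30.0, False


def _tpl_transient(pid, rng):
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(60, 200)
    t_back = t1 + rng.uniform(20, 85)  # reverts inside the 91-day window
    t3 = t1 + rng.uniform(95, 200)
    traj = EdssTrajectory(
        pid, [-40.0, t1, t_back, t3], [ref, ref + 1.0, ref, ref + 1.0]
    )
    # the day-t3 rise has no later confirming measurement either
    return traj, 0.0, t3 + 30.0, False


def _tpl_unconfirmed(pid, rng):
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(60, 200)
    traj = EdssTrajectory(pid, [-40.0, t1], [ref, ref + 1.5])
    return traj, 0.0, t1 + 300.0, False


def _tpl_invalid_confirmation(pid, rng):
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(60, 200)
    t2 = t1 + rng.uniform(95, 150)
    relapse = t2 - rng.uniform(10, 80)  # confirmation within 84 d of a relapse
    traj = EdssTrajectory(
        pid, [-40.0, t1, t2], [ref, ref + 1.0, ref + 1.0], [relapse]
    )
    return traj, 0.0, t2 + 30.0, False


def _tpl_inflated_baseline(pid, rng):
    # the nearest pre-start measurement is relapse-inflated and invalid; the
    # valid earlier one is the true reference, so the rise does qualify
    # (the first on-therapy measurement lies beyond the +91 d baseline window)
    ref = _grid(rng.uniform(1.0, 4.0))
    t1 = rng.uniform(100, 200)
    t2 = t1 + rng.uniform(95, 200)
    traj = EdssTrajectory(
        pid,
        [-170.0, -30.0, t1, t2],
        [ref, ref + 1.0, ref + 1.0, ref + 1.0],
        [-60.0],
    )
    return traj, 0.0, t2 + 30.0, True


def _tpl_stable(pid, rng):
    ref = _grid(rng.uniform(1.0, 6.0))
    times = [-40.0, 90.0, 200.0, 330.0]
    traj = EdssTrajectory(pid, times, [ref] * 4)
    return traj, 0.0, 360.0, False


def _tpl_progression_with_relapses(pid, rng):
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(150, 250)
    t2 = t1 + rng.uniform(95, 150)
    relapse = rng.uniform(5, t1 - 90.0)  # > 84 d before onset: stays valid
    traj = EdssTrajectory(
        pid, [-40.0, t1, t2], [ref, ref + 1.0, ref + 1.0], [relapse]
    )
    return traj, 0.0, t2 + 30.0, True


def _tpl_late_unsustained(pid, rng):
    # a qualifying rise whose confirmation lies beyond the cycle end
    ref = _grid(rng.uniform(1.0, 5.0))
    t1 = rng.uniform(60, 200)
    traj = EdssTrajectory(pid, [-40.0, t1, t1 + 200.0], [ref, ref + 1.0, ref + 1.0])
    return traj, 0.0, t1 + 50.0, False


# ---------------------------------------------------------------------------
# Adherence-comparison fixture (receivers vs non-receivers of a therapy)


def generate_adherence_cohort(
    n: int,
    log_rate_ratio: float = -float(np.log(2.0)),
    confounded: bool = False,
    response: str = "relapse",
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group outcome cohort with a known group effect.

    Emulates the receivers / non-receivers comparison: covariates as in the
    registry generator, a binary ``took_dmt_star`` indicator, and outcomes
    whose log rate (or log odds) differs between groups by exactly
    ``log_rate_ratio``.  With ``confounded=True`` sicker patients (higher
    relapses count and EDSS) are less likely to receive the top-ranked
    therapy, biasing the naive comparison while the true effect stays
    ``log_rate_ratio``.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_patients=n, n_sites=2, seed=int(rng.integers(2**31 - 1)))
    cov = _draw_covariates(cfg, rng)
    # severity acts through the covariates the propensity model observes
    # (EDSS by category, matching the weighting step's categorization)
    edss_cat = np.digitize(cov["edss_baseline"].to_numpy(float), [1.75, 3.75])
    severity = 0.45 * (cov["relapses_count"] - 1.8) + 0.45 * (
        edss_cat - 1.0
    ) + 0.1 * (cov["diagnosis_distance"] - 6.0) / 5.0
    if confounded:
        p_take = expit(0.3 - 2.0 * severity)
    else:
        p_take = np.full(n, 0.5)
    took = rng.random(n) < p_take
    cov["took_dmt_star"] = took
    base = np.log(0.4) + (0.9 * severity if confounded else 0.0)
    eta = base + np.where(took, log_rate_ratio, 0.0) + np.log(
        cov["index_duration"].to_numpy(float)
    )
    if response == "relapse":
        mu = np.exp(eta)
        lam = rng.gamma(shape=1.5, scale=mu / 1.5)
        cov["n_relapses"] = rng.poisson(lam)
    else:
        cov["cdp"] = rng.random(n) < expit(eta - 1.5)
    return cov


# ---------------------------------------------------------------------------
# CSV output matching the cohort module's reader


def write_registry(cycles: pd.DataFrame, trajectories, truth: GroundTruth, outdir) -> None:
    """Write cycles/EDSS/relapse CSVs plus the ground truth as JSON."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cycles.to_csv(outdir / "cycles.csv", index=False)
    edss_rows, relapse_rows = [], []
    for pid, traj in trajectories.items():
        for t, e in zip(traj.times, traj.edss):
            edss_rows.append((pid, t, e))
        for d in traj.relapse_days:
            relapse_rows.append((pid, d))
    pd.DataFrame(edss_rows, columns=["patient_id", "day", "edss"]).to_csv(
        outdir / "edss.csv", index=False
    )
    pd.DataFrame(relapse_rows, columns=["patient_id", "day"]).to_csv(
        outdir / "relapses.csv", index=False
    )
    payload = {
        "columns": truth.columns,
        "intercept": truth.intercept,
        "beta": {r: truth.beta[r].tolist() for r in truth.beta},
        "site_levels": [str(s) for s in truth.site_levels],
        "site_u": {r: truth.site_u[r].tolist() for r in truth.site_u},
        "dispersion": truth.dispersion,
        "site_sd": truth.site_sd,
        "seed": truth.config.seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
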