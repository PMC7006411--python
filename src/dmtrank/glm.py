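"""Hierarchical Bayesian GLMs for on-therapy relapse counts and CDP events.

Two outcome models over therapy cycles, sharing one design-matrix pipeline:

* relapse: ``y_i ~ NegBinomial(mean = T_i * exp(x_i'b + u_{s(i)}), shape = phi)``
  with a log link and the cycle duration ``T_i`` (years) as exposure offset;
* CDP: ``y_i ~ Bernoulli(logit^-1(x_i'g + u_{s(i)} + log T_i))``.

``u_s`` is a random intercept per clinical site.  Priors are weakly
informative: Normal(0, 10) on the intercept, Normal(0, 2.5) on fixed effects
(continuous predictors are standardized first), Half-Cauchy(0, 5) on the NB
shape and Gamma(1, 1) on the site standard deviation.

Posteriors are sampled with affine-invariant ensemble MCMC (emcee), run as
several independent ensembles initialized at a MAP estimate found with
analytic gradients; convergence is checked with the rank-normalized
Gelman-Rubin statistic (R-hat) across ensembles.  Counterfactual predictions
zero the site intercepts so a new patient gets identical predictions at
every site.

Model complexities (nested):

* ``non_personalized`` — index DMT only (plus site intercept and offset);
* ``prognostic`` — adds patient characteristics, no therapy interactions;
* ``predictive`` — adds index-DMT interactions with diagnosis distance,
  gender, relapses count and the second-line indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import expit, gammaln, logsumexp

from .cohort import CURRENT_DMTS, INDEX_DMTS

Response = Literal["relapse", "cdp"]
Complexity = Literal["non_personalized", "prognostic", "predictive"]

GENDERS = ("F", "M")

#: maximum linear predictor before exponentiation, guards overflow only
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters (all Normal scales are standard deviations)."""

    intercept_loc: float = 0.0
    intercept_scale: float = 10.0
    coef_loc: float = 0.0
    coef_scale: float = 2.5
    dispersion_scale: float = 5.0  # Half-Cauchy scale on the NB shape
    site_sd_shape: float = 1.0  # Gamma(shape, rate) on the site SD
    site_sd_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("intercept_scale", "coef_scale", "dispersion_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "PriorConfig":
        """Multiply all prior scales by ``factor`` (sensitivity variants)."""
        return replace(
            self,
            intercept_scale=self.intercept_scale * factor,
            coef_scale=self.coef_scale * factor,
            dispersion_scale=self.dispersion_scale * factor,
        )


# Terms per complexity.  Interactions are written "a:b".
_TERMS_NON_PERSONALIZED = ("index_dmt",)
_TERMS_PROGNOSTIC = _TERMS_NON_PERSONALIZED + (
    "age",
    "gender",
    "edss_baseline",
    "second_line",
    "current_dmt",
    "current_duration",
    "current_dmt:current_duration",
    "diagnosis_distance",
    "relapse_distance",
    "relapses_count",
    "dmts_count",
)
_TERMS_PREDICTIVE = _TERMS_PROGNOSTIC + (
    "index_dmt:diagnosis_distance",
    "index_dmt:gender",
    "index_dmt:relapses_count",
    "index_dmt:second_line",
)

TERMS_BY_COMPLEXITY: dict[str, tuple[str, ...]] = {
    "non_personalized": _TERMS_NON_PERSONALIZED,
    "prognostic": _TERMS_PROGNOSTIC,
    "predictive": _TERMS_PREDICTIVE,
}

#: terms present in the predictive model but not the prognostic one
INTERACTION_TERMS = tuple(t for t in _TERMS_PREDICTIVE if t not in _TERMS_PROGNOSTIC)

CONTINUOUS_VARS = (
    "age",
    "edss_baseline",
    "current_duration",
    "diagnosis_distance",
    "relapse_distance",
    "relapses_count",
    "dmts_count",
)
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "index_dmt": INDEX_DMTS,
    "current_dmt": CURRENT_DMTS,
    "gender": GENDERS,
}


@dataclass(frozen=True)
class ModelSpec:
    response: Response
    complexity: Complexity = "predictive"
    prior: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.response not in ("relapse", "cdp"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.complexity not in TERMS_BY_COMPLEXITY:
            raise ValueError(f"unknown complexity {self.complexity!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return TERMS_BY_COMPLEXITY[self.complexity]


# ---------------------------------------------------------------------------
# Design matrices


@dataclass(frozen=True)
class DesignTransform:
    """Standardization constants for continuous predictors (training stats)."""

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(cls, cycles: pd.DataFrame, variables: Sequence[str]) -> "DesignTransform":
        means, sds = {}, {}
        for v in variables:
            x = cycles[v].to_numpy(float)
            means[v] = float(np.mean(x))
            sd = float(np.std(x))
            sds[v] = sd if sd > 0 else 1.0
        return cls(means=means, sds=sds)

    def apply(self, cycles: pd.DataFrame, var: str) -> np.ndarray:
        return (cycles[var].to_numpy(float) - self.means[var]) / self.sds[var]


@dataclass
class Design:
    X: np.ndarray  # (n, p), no intercept column
    columns: list[str]
    offset: np.ndarray  # log index duration (years)
    site_levels: list
    site_index: np.ndarray  # (n,) int codes into site_levels
    transform: DesignTransform


def _categorical_columns(values: np.ndarray, var: str) -> tuple[list[str], np.ndarray]:
    """Dummy-code against the first (reference) level of the fixed level list."""
    levels = CATEGORICAL_LEVELS[var]
    unseen = set(np.unique(values)) - set(levels)
    if unseen:
        raise ValueError(f"unseen level(s) {sorted(unseen)!r} for predictor {var!r}")
    names = [f"{var}[{lev}]" for lev in levels[1:]]
    cols = np.column_stack([(values == lev).astype(float) for lev in levels[1:]])
    return names, cols


def _term_columns(
    cycles: pd.DataFrame, term: str, transform: DesignTransform
) -> tuple[list[str], np.ndarray]:
    def base(var: str) -> tuple[list[str], np.ndarray]:
        if var in CATEGORICAL_LEVELS:
            return _categorical_columns(cycles[var].to_numpy(), var)
        if var == "second_line":
            return ["second_line[True]"], cycles[var].to_numpy(bool).astype(float)[:, None]
        if var in CONTINUOUS_VARS:
            return [var], transform.apply(cycles, var)[:, None]
        raise KeyError(f"unknown model term {var!r}")

    if ":" not in term:
        return base(term)
    left, right = term.split(":")
    lnames, lcols = base(left)
    rnames, rcols = base(right)
    names, cols = [], []
    for i, ln in enumerate(lnames):
        for j, rn in enumerate(rnames):
            names.append(f"{ln}:{rn}")
            cols.append(lcols[:, i] * rcols[:, j])
    return names, np.column_stack(cols)


def build_design(
    cycles: pd.DataFrame,
    spec: ModelSpec,
    transform: DesignTransform | None = None,
    site_levels: Sequence | None = None,
) -> Design:
    """Assemble the fixed-effects design matrix for a model complexity.

    Continuous predictors are centered and scaled with training statistics
    (``transform``); categorical predictors are dummy-coded against fixed
    reference levels (first level of the documented level list); interaction
    columns are products of the coded columns.  The exposure offset
    ``log(index_duration)`` and the site coding are returned separately.
    """
    needed = {v.strip() for t in spec.terms for v in t.split(":")}
    continuous = [v for v in CONTINUOUS_VARS if v in needed]
    if transform is None:
        transform = DesignTransform.fit(cycles, continuous)
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for term in spec.terms:
        tn, tc = _term_columns(cycles, term, transform)
        names.extend(tn)
        blocks.append(tc)
    X = np.column_stack(blocks) if blocks else np.empty((len(cycles), 0))

    durations = cycles["index_duration"].to_numpy(float)
    if np.any(durations <= 0):
        raise ValueError("index_duration must be positive for the log offset")
    offset = np.log(durations)

    sites = cycles["site_id"].to_numpy()
    if site_levels is None:
        site_levels = sorted(pd.unique(sites).tolist())
    lookup = {s: i for i, s in enumerate(site_levels)}
    try:
        site_index = np.array([lookup[s] for s in sites], dtype=int)
    except KeyError as exc:  # pragma: no cover - message matters, not path
        raise ValueError(f"unseen clinical site {exc.args[0]!r}") from exc
    return Design(
        X=X,
        columns=names,
        offset=offset,
        site_levels=list(site_levels),
        site_index=site_index,
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Likelihoods


def nb_logpmf(y: np.ndarray, mu: np.ndarray, shape: float | np.ndarray) -> np.ndarray:
    """Negative binomial log-pmf, mean/shape parameterization.

    Variance is ``mu + mu**2 / shape``; equals ``scipy.stats.nbinom`` with
    ``n = shape`` and ``p = shape / (shape + mu)``.
    """
    y = np.asarray(y, dtype=float)
    return (
        gammaln(y + shape)
        - gammaln(shape)
        - gammaln(y + 1)
        + shape * np.log(shape / (shape + mu))
        + y * np.log(mu / (shape + mu))
    )


def bernoulli_logit_logpmf(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y * eta - np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# Posterior


class ConvergenceError(RuntimeError):
    """MCMC did not converge (R-hat above threshold)."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: independent MAP-initialized ensembles.

    ``chains`` independent emcee ensembles are run for ``warmup + post``
    steps each; ``draws`` states per chain are kept from steps evenly spaced
    across the post-warmup window.
    """

    chains: int = 4
    warmup: int = 500
    post: int = 250
    draws: int = 1000
    nwalkers: int | None = None
    seed: int = 0
    rhat_threshold: float = 1.1
    init_jitter: float = 0.1


class _Posterior:
    """Log joint posterior of one hierarchical GLM, with gradients.

    Parameter vector layout (centered site intercepts):
    ``[intercept, beta (p), u_site (S), log_site_sd, (log_dispersion)]``
    with ``u_s ~ Normal(0, site_sd^2)``.  The centered parameterization is
    the well-mixing one here because every site contributes many cycles, so
    the intercepts are strongly data-identified.
    """

    def __init__(self, design: Design, y: np.ndarray, spec: ModelSpec):
        self.X = design.X
        self.offset = design.offset
        self.site = design.site_index
        self.S = len(design.site_levels)
        self.p = design.X.shape[1]
        self.y = np.asarray(y, dtype=float)
        self.spec = spec
        self.is_nb = spec.response == "relapse"
        self.ndim = 1 + self.p + self.S + 1 + (1 if self.is_nb else 0)
        self._gammaln_y1 = gammaln(self.y + 1)
        # per-site aggregation matrix used in gradients
        self._site_onehot = np.zeros((self.S, len(self.y)))
        self._site_onehot[self.site, np.arange(len(self.y))] = 1.0

    # -- batched log-probability for the ensemble sampler ------------------
    def log_prob_batch(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        a = theta[:, 0]
        b = theta[:, 1 : 1 + self.p]
        u = theta[:, 1 + self.p : 1 + self.p + self.S]  # (B, S)
        log_sd = theta[:, 1 + self.p + self.S]
        sd = np.exp(log_sd)
        eta = (
            self.offset[:, None]
            + a[None, :]
            + (self.X @ b.T if self.p else 0.0)
            + u[:, self.site].T
        )
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        prior = self.spec.prior
        lp = (
            -0.5 * ((a - prior.intercept_loc) / prior.intercept_scale) ** 2
            - 0.5 * np.sum(((b - prior.coef_loc) / prior.coef_scale) ** 2, axis=1)
            - self.S * log_sd
            - 0.5 * np.sum(u**2, axis=1) / sd**2
        )
        # Gamma(shape, rate) prior on sd, log-parameterized (+ Jacobian)
        lp += (
            prior.site_sd_shape * log_sd
            - prior.site_sd_rate * sd
        )
        if self.is_nb:
            log_phi = theta[:, -1]
            phi = np.exp(log_phi)
            mu = np.exp(eta)
            ll = (
                gammaln(self.y[:, None] + phi[None, :])
                - gammaln(phi)[None, :]
                - self._gammaln_y1[:, None]
                + phi[None, :] * (np.log(phi)[None, :] - np.log(phi[None, :] + mu))
                + self.y[:, None] * (eta - np.log(phi[None, :] + mu))
            )
            lp += ll.sum(axis=0)
            # Half-Cauchy(0, c) on phi, log-parameterized (+ Jacobian)
            c = prior.dispersion_scale
            lp += log_phi - np.log1p((phi / c) ** 2)
        else:
            ll = self.y[:, None] * eta - np.logaddexp(0.0, eta)
            lp += ll.sum(axis=0)
        return np.where(np.isfinite(lp), lp, -np.inf)

    # -- single-point value and gradient for MAP optimization ---------------
    def neg_log_prob_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        a = theta[0]
        b = theta[1 : 1 + self.p]
        u = theta[1 + self.p : 1 + self.p + self.S]
        log_sd = theta[1 + self.p + self.S]
        sd = np.exp(log_sd)
        eta = self.offset + a + (self.X @ b if self.p else 0.0) + u[self.site]
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        prior = self.spec.prior

        if self.is_nb:
            log_phi = theta[-1]
            phi = np.exp(log_phi)
            mu = np.exp(eta)
            ll = np.sum(
                gammaln(self.y + phi)
                - gammaln(phi)
                - self._gammaln_y1
                + phi * np.log(phi / (phi + mu))
                + self.y * (eta - np.log(phi + mu))
            )
            r = self.y - (self.y + phi) * mu / (phi + mu)
            dphi = np.sum(
                special.digamma(self.y + phi)
                - special.digamma(phi)
                + np.log(phi)
                + 1.0
                - np.log(phi + mu)
                - (phi + self.y) / (phi + mu)
            )
        else:
            ll = np.sum(self.y * eta - np.logaddexp(0.0, eta))
            r = self.y - expit(eta)

        g_site = self._site_onehot @ r  # dll/du_s
        lp = ll
        grad = np.zeros_like(theta)
        lp += -0.5 * ((a - prior.intercept_loc) / prior.intercept_scale) ** 2
        grad[0] = r.sum() - (a - prior.intercept_loc) / prior.intercept_scale**2
        if self.p:
            lp += -0.5 * np.sum(((b - prior.coef_loc) / prior.coef_scale) ** 2)
            grad[1 : 1 + self.p] = self.X.T @ r - (b - prior.coef_loc) / prior.coef_scale**2
        lp += -self.S * log_sd - 0.5 * np.sum(u**2) / sd**2
        grad[1 + self.p : 1 + self.p + self.S] = g_site - u / sd**2
        lp += prior.site_sd_shape * log_sd - prior.site_sd_rate * sd
        grad[1 + self.p + self.S] = (
            np.sum(u**2) / sd**2
            - self.S
            + prior.site_sd_shape
            - prior.site_sd_rate * sd
        )
        if self.is_nb:
            c = prior.dispersion_scale
            lp += log_phi - np.log1p((phi / c) ** 2)
            grad[-1] = phi * dphi + 1.0 - 2.0 * phi**2 / (c**2 + phi**2)
        return -float(lp), -grad

    def map_estimate(self) -> np.ndarray:
        """Profile-style initialization point.

        The joint mode of the centered hierarchy degenerates (sd -> 0 pulls
        the intercepts with it), so the site SD is not optimized jointly:
        coefficients and site intercepts are optimized with the SD held at a
        moderate value, after which the SD coordinate is set from the
        empirical spread of the fitted intercepts and the rest re-polished.
        """
        i_sd = 1 + self.p + self.S

        def optimize_with_sd(x0: np.ndarray, sd: float) -> np.ndarray:
            bounds = [(None, None)] * self.ndim
            bounds[i_sd] = (np.log(sd), np.log(sd))
            if self.is_nb:
                bounds[-1] = (np.log(0.02), np.log(100.0))
            x0 = x0.copy()
            x0[i_sd] = np.log(sd)
            res = optimize.minimize(
                self.neg_log_prob_grad, x0, jac=True, method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 500},
            )
            return res.x

        x = optimize_with_sd(np.zeros(self.ndim), 1.0)
        u_hat = x[1 + self.p : 1 + self.p + self.S]
        sd_hat = float(np.clip(np.std(u_hat, ddof=1), 0.05, 5.0))
        return optimize_with_sd(x, sd_hat)


@dataclass
class PosteriorFit:
    """Posterior draws of one fitted model, plus everything needed to predict.

    Draw arrays are shaped ``(chains, draws, ...)``; ``site_u`` holds the
    realized random intercepts ``u_s = site_sd * z_s``.
    """

    spec: ModelSpec
    columns: list[str]
    transform: DesignTransform
    site_levels: list
    intercept: np.ndarray  # (c, d)
    beta: np.ndarray  # (c, d, p)
    site_u: np.ndarray  # (c, d, S)
    site_sd: np.ndarray  # (c, d)
    dispersion: np.ndarray | None  # (c, d), relapse only
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.intercept.shape[0] * self.intercept.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} not present for response {self.spec.response}")
        return arr.reshape(-1, *arr.shape[2:])

    def with_zeroed_coefficients(self, terms: Sequence[str]) -> "PosteriorFit":
        """Copy of the fit with the coefficients of ``terms`` pinned to zero.

        ``terms`` are model terms ("index_dmt:gender") or exact column names.
        """
        zero = set()
        for t in terms:
            matched = [
                j
                for j, c in enumerate(self.columns)
                if c == t or _column_term(c) == t
            ]
            if not matched:
                raise KeyError(f"no design columns match term {t!r}")
            zero.update(matched)
        beta = self.beta.copy()
        beta[:, :, sorted(zero)] = 0.0
        return replace(self, beta=beta)

    def save(self, directory) -> None:
        """Serialize draws (CSV) and metadata (JSON) to a directory."""
        import json
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        c, d = self.intercept.shape
        cols = {"chain": np.repeat(np.arange(c), d), "intercept": self.flat("intercept")}
        for j, name in enumerate(self.columns):
            cols[f"beta:{name}"] = self.flat("beta")[:, j]
        for j, lev in enumerate(self.site_levels):
            cols[f"site_u:{lev}"] = self.flat("site_u")[:, j]
        cols["site_sd"] = self.flat("site_sd")
        if self.dispersion is not None:
            cols["dispersion"] = self.flat("dispersion")
        pd.DataFrame(cols).to_csv(directory / "draws.csv", index=False)
        meta = {
            "response": self.spec.response,
            "complexity": self.spec.complexity,
            "prior": self.spec.prior.__dict__,
            "columns": self.columns,
            "site_levels": [str(s) for s in self.site_levels],
            "transform": {"means": self.transform.means, "sds": self.transform.sds},
            "rhat": self.rhat,
            "chains": c,
            "draws_per_chain": d,
        }
        (directory / "fit.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorFit":
        import json
        import pathlib

        directory = pathlib.Path(directory)
        meta = json.loads((directory / "fit.json").read_text())
        table = pd.read_csv(directory / "draws.csv")
        c, d = meta["chains"], meta["draws_per_chain"]

        def shaped(names):
            return np.stack(
                [table[n].to_numpy().reshape(c, d) for n in names], axis=-1
            )

        spec = ModelSpec(
            meta["response"], meta["complexity"], PriorConfig(**meta["prior"])
        )
        return cls(
            spec=spec,
            columns=meta["columns"],
            transform=DesignTransform(**meta["transform"]),
            site_levels=meta["site_levels"],
            intercept=table["intercept"].to_numpy().reshape(c, d),
            beta=shaped([f"beta:{n}" for n in meta["columns"]]),
            site_u=shaped([f"site_u:{s}" for s in meta["site_levels"]]),
            site_sd=table["site_sd"].to_numpy().reshape(c, d),
            dispersion=(
                table["dispersion"].to_numpy().reshape(c, d)
                if "dispersion" in table
                else None
            ),
            rhat=meta["rhat"],
        )

    @classmethod
    def from_point(
        cls,
        spec: ModelSpec,
        columns: Sequence[str],
        transform: DesignTransform,
        site_levels: Sequence,
        intercept: float,
        beta: np.ndarray,
        site_u: np.ndarray | None = None,
        site_sd: float = 0.0,
        dispersion: float | None = None,
    ) -> "PosteriorFit":
        """Degenerate one-draw 'fit' at known parameters (true-model scoring)."""
        S = len(site_levels)
        u = np.zeros(S) if site_u is None else np.asarray(site_u, float)
        return cls(
            spec=spec,
            columns=list(columns),
            transform=transform,
            site_levels=list(site_levels),
            intercept=np.array([[float(intercept)]]),
            beta=np.asarray(beta, float).reshape(1, 1, -1),
            site_u=u.reshape(1, 1, -1),
            site_sd=np.array([[float(site_sd)]]),
            dispersion=None if dispersion is None else np.array([[float(dispersion)]]),
            rhat={},
        )


def _column_term(column: str) -> str:
    """Map a design column name back to its model term."""
    parts = column.split(":")
    vars_ = [p.split("[")[0] for p in parts]
    return ":".join(vars_)


def fit(
    spec: ModelSpec,
    cycles: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    check_convergence: bool = True,
) -> PosteriorFit:
    """Sample the posterior of the hierarchical GLM given by ``spec``.

    Runs ``mcmc.chains`` independent ensembles, each initialized by jittering
    a MAP estimate, and fails loudly (``ConvergenceError``) when any
    parameter's rank-normalized R-hat across ensembles exceeds the threshold.
    """
    import emcee

    mcmc = mcmc or MCMCConfig()
    design = build_design(cycles, spec)
    if len(design.site_levels) < 2:
        raise ValueError("at least 2 clinical sites are required")
    y = (
        cycles["n_relapses"].to_numpy(int)
        if spec.response == "relapse"
        else cycles["cdp"].to_numpy(bool).astype(int)
    )
    post = _Posterior(design, y, spec)
    ndim = post.ndim
    nwalkers = mcmc.nwalkers or max(2 * ndim + 2, 48)
    theta_map = post.map_estimate()

    rng = np.random.default_rng(mcmc.seed)
    m_steps = int(np.ceil(mcmc.draws / nwalkers))
    step_idx = np.unique(
        np.linspace(0, mcmc.post - 1, m_steps).round().astype(int)
    )
    chains_draws = []
    for _ in range(mcmc.chains):
        p0 = theta_map + mcmc.init_jitter * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, post.log_prob_batch, vectorize=True
        )
        start = emcee.State(
            p0, random_state=np.random.RandomState(rng.integers(2**31 - 1)).get_state()
        )
        sampler.run_mcmc(start, mcmc.warmup + mcmc.post, progress=False)
        chain = sampler.get_chain(discard=mcmc.warmup)  # (post, walkers, ndim)
        kept = chain[step_idx].reshape(-1, ndim)[: mcmc.draws]
        chains_draws.append(kept)
    draws = np.stack(chains_draws)  # (chains, draws, ndim)

    p, S = post.p, post.S
    intercept = draws[:, :, 0]
    beta = draws[:, :, 1 : 1 + p]
    site_u = draws[:, :, 1 + p : 1 + p + S]
    site_sd = np.exp(draws[:, :, 1 + p + S])
    dispersion = np.exp(draws[:, :, -1]) if post.is_nb else None

    rhat = _compute_rhat(
        intercept, beta, site_u, site_sd, dispersion, design.columns,
        design.site_levels,
    )
    result = PosteriorFit(
        spec=spec,
        columns=design.columns,
        transform=design.transform,
        site_levels=design.site_levels,
        intercept=intercept,
        beta=beta,
        site_u=site_u,
        site_sd=site_sd,
        dispersion=dispersion,
        rhat=rhat,
    )
    if check_convergence:
        bad = {k: v for k, v in rhat.items() if not np.isfinite(v) or v > mcmc.rhat_threshold}
        if bad:
            worst = sorted(bad.items(), key=lambda kv: -kv[1])[:8]
            raise ConvergenceError(
                f"R-hat above {mcmc.rhat_threshold} for {len(bad)} parameter(s): "
                + ", ".join(f"{k}={v:.3f}" for k, v in worst)
            )
    return result


def _compute_rhat(intercept, beta, site_u, site_sd, dispersion, columns, site_levels):
    import warnings

    import arviz as az

    data = {"intercept": intercept, "site_sd": site_sd}
    if beta.shape[2]:
        data["beta"] = beta
    data["site_u"] = site_u
    if dispersion is not None:
        data["dispersion"] = dispersion
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(az.from_dict(posterior=data))
    out: dict[str, float] = {}
    out["intercept"] = float(rh["intercept"].values)
    out["site_sd"] = float(rh["site_sd"].values)
    if "beta" in rh:
        for name, val in zip(columns, np.atleast_1d(rh["beta"].values)):
            out[name] = float(val)
    for lev, val in zip(site_levels, np.atleast_1d(rh["site_u"].values)):
        out[f"site_u[{lev}]"] = float(val)
    if "dispersion" in rh:
        out["dispersion"] = float(rh["dispersion"].values)
    return out


# ---------------------------------------------------------------------------
# Prediction


@dataclass
class CounterfactualSummary:
    """Posterior-predictive summaries for one requested DMT.

    ``mean`` is the posterior-predictive expected outcome per cycle (counts
    for relapse, event probability for CDP); ``frac_favorable`` is the
    fraction of posterior draws predicting absence of relapse / absence of
    CDP, averaged analytically over each draw's sampling distribution.
    """

    dmt: str
    response: Response
    mean: np.ndarray
    frac_favorable: np.ndarray
    draws_mean: np.ndarray | None = None  # (n_draws, n) per-draw expected outcome


def _linear_predictor(
    fit: PosteriorFit,
    cycles: pd.DataFrame,
    dmt: str | None,
    duration: float | np.ndarray | None,
    zero_site: bool,
) -> np.ndarray:
    """Per-draw linear predictor, (n_draws, n_cycles)."""
    data = cycles
    if dmt is not None:
        if dmt not in INDEX_DMTS:
            raise ValueError(f"unseen level {dmt!r} for predictor 'index_dmt'")
        data = cycles.copy()
        data["index_dmt"] = dmt
    if duration is not None:
        data = data.copy() if data is cycles else data
        data["index_duration"] = duration
    design = build_design(
        data, fit.spec, transform=fit.transform,
        site_levels=None if zero_site else fit.site_levels,
    )
    a = fit.flat("intercept")[:, None]
    b = fit.flat("beta")
    eta = a + b @ design.X.T + design.offset[None, :]
    if not zero_site:
        u = fit.flat("site_u")
        eta = eta + u[:, design.site_index]
    return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)


def predict_counterfactual(
    fit: PosteriorFit,
    cycles: pd.DataFrame,
    dmt: str | None = None,
    duration: float | np.ndarray | None = None,
    keep_draws: bool = False,
) -> CounterfactualSummary:
    """Counterfactual posterior-predictive summaries under a requested DMT.

    Sets each cycle's index DMT (and thereby all its interaction columns) to
    ``dmt``, zeroes the site intercepts, and applies the exposure offset
    ``log(duration)`` (the observed index duration when ``duration`` is
    None).  Summaries are averaged analytically over posterior draws.
    """
    eta = _linear_predictor(fit, cycles, dmt, duration, zero_site=True)
    if fit.spec.response == "relapse":
        mu = np.exp(eta)
        phi = fit.flat("dispersion")[:, None]
        mean = mu.mean(axis=0)
        frac = ((phi / (phi + mu)) ** phi).mean(axis=0)  # P(y = 0) per draw
        per_draw = mu
    else:
        p = expit(eta)
        mean = p.mean(axis=0)
        frac = (1.0 - p).mean(axis=0)  # P(no CDP) per draw
        per_draw = p
    return CounterfactualSummary(
        dmt=dmt or "observed",
        response=fit.spec.response,
        mean=mean,
        frac_favorable=frac,
        draws_mean=per_draw if keep_draws else None,
    )


def sample_outcomes(
    fit: PosteriorFit,
    cycles: pd.DataFrame,
    dmt: str | None = None,
    duration: float | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample one predictive outcome per posterior draw and cycle."""
    rng = rng or np.random.default_rng()
    eta = _linear_predictor(fit, cycles, dmt, duration, zero_site=True)
    if fit.spec.response == "relapse":
        mu = np.exp(eta)
        phi = fit.flat("dispersion")[:, None]
        lam = rng.gamma(shape=np.broadcast_to(phi, mu.shape), scale=mu / phi)
        return rng.poisson(lam)
    return (rng.random(eta.shape) < expit(eta)).astype(int)


def predict_all_dmts(
    fit: PosteriorFit,
    cycles: pd.DataFrame,
    duration: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Ranking summary per cycle and DMT.

    Returns a DataFrame (n_cycles x 6) of mean predicted relapse counts
    (relapse model) or predicted CDP probabilities (CDP model), the
    quantities the personalized therapy ranking minimizes.
    """
    cols = {}
    for dmt in INDEX_DMTS:
        s = predict_counterfactual(fit, cycles, dmt=dmt, duration=duration)
        cols[dmt] = s.mean
    return pd.DataFrame(cols, index=cycles.index)


def pointwise_log_lik(
    fit: PosteriorFit, cycles: pd.DataFrame, zero_site: bool = True
) -> tuple[np.ndarray, float]:
    """Per-cycle predictive log-likelihood and its total.

    Computes ``log( mean over posterior draws of p(y_i | draw) )`` per cycle
    (the log pointwise predictive density); the negative of the returned
    values is the NLL used in validation.  ``zero_site=True`` scores with
    random intercepts set to zero, matching the prediction path for new
    patients and sites.
    """
    eta = _linear_predictor(fit, cycles, None, None, zero_site=zero_site)
    if fit.spec.response == "relapse":
        y = cycles["n_relapses"].to_numpy(int)
        phi = fit.flat("dispersion")[:, None]
        ll = nb_logpmf(y[None, :], np.exp(eta), phi)
    else:
        y = cycles["cdp"].to_numpy(bool).astype(int)
        ll = bernoulli_logit_logpmf(y[None, :], eta)
    n_draws = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(n_draws)
    return lppd, float(lppd.sum())
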