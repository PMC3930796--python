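"""Hierarchical Bayesian binary-logit choice model, fit by Metropolis-within-Gibbs.

Model
-----
Respondent ``i`` chooses product A in a paired scenario with probability
``logistic(d' beta_i)`` where ``d = x_A - x_B`` is the effect-coded utility
difference.  Individual part-worth vectors are exchangeable draws from a
multivariate normal population::

    choice_it ~ Bernoulli(logistic(d_it' beta_i))
    beta_i    ~ MVN(mu, Sigma)
    mu        ~ MVN(0, tau^2 I)           (tau^2 = 100 by default)
    Sigma     ~ Inverse-Wishart(p + 2, I)

The sampler alternates a blocked random-walk Metropolis update of each
``beta_i`` (all respondents updated in one vectorized step, proposals shaped
by the current Sigma cholesky) with conjugate Gibbs updates of ``mu`` and
``Sigma``.  Because the centered parameterization couples the location of
the betas to ``mu``, a joint translation move — shifting ``mu`` and every
``beta_i`` by the same vector, accepted against the full-data likelihood —
is interleaved to decorrelate the population location; chains initialize at
the pooled-logit MLE.  Per-respondent proposal scales adapt toward a 0.23
acceptance rate during burn-in and are frozen afterwards, so retained draws
come from a fixed-kernel chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .design import DesignPlan
from .schema import AttributeSchema, encode_product

__all__ = [
    "ChoiceDataset",
    "HBConfig",
    "PosteriorDraws",
    "PointEstimates",
    "log_likelihood",
    "run_mcmc",
    "posterior_point_estimates",
    "pooled_logit_mle",
    "PooledLogitResult",
]


@dataclass
class ChoiceDataset:
    """Coded paired-choice records ready for the likelihood.

    ``diffs`` holds one utility-difference vector ``x_A - x_B`` per record;
    ``chose_a`` is 1 when alternative A was picked; ``respondent_idx`` maps
    records to 0..N-1 in the order of ``respondent_ids``.
    """

    diffs: np.ndarray            # (M, p)
    respondent_idx: np.ndarray   # (M,)
    chose_a: np.ndarray          # (M,)
    respondent_ids: list[str]
    coef_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.diffs = np.atleast_2d(np.asarray(self.diffs, dtype=float))
        self.respondent_idx = np.asarray(self.respondent_idx, dtype=int)
        self.chose_a = np.asarray(self.chose_a, dtype=int)
        if len(self.respondent_idx) != len(self.diffs) or len(self.chose_a) != len(
            self.diffs
        ):
            raise ValueError("diffs, respondent_idx and chose_a lengths differ")
        if len(self.respondent_idx) and self.respondent_idx.max() >= len(
            self.respondent_ids
        ):
            raise ValueError("respondent index out of range")

    @property
    def n_records(self) -> int:
        return len(self.diffs) if self.diffs.size else 0

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_coefficients(self) -> int:
        return self.diffs.shape[1]

    @classmethod
    def from_frame(
        cls,
        choices: pd.DataFrame,
        plan: DesignPlan,
        schema: AttributeSchema | None = None,
    ) -> "ChoiceDataset":
        """Build from a tidy choice table (respondent_id, scenario_id, choice)."""
        schema = schema or plan.schema
        coded = {
            s.scenario_id: encode_product(schema, s.product_a)
            - encode_product(schema, s.product_b)
            for s in plan.scenarios
        }
        ids = list(pd.unique(choices["respondent_id"]))
        idx_of = {r: i for i, r in enumerate(ids)}
        unknown = set(choices["scenario_id"]) - set(coded)
        if unknown:
            raise ValueError(f"choices reference unknown scenarios: {sorted(unknown)[:5]}")
        diffs = np.array([coded[s] for s in choices["scenario_id"]])
        ridx = np.array([idx_of[r] for r in choices["respondent_id"]])
        y = (choices["choice"].to_numpy() == "A").astype(int)
        return cls(diffs, ridx, y, ids, coef_names=schema.coef_names)


def log_likelihood(
    beta: Sequence[float], diffs: np.ndarray, chose_a: np.ndarray
) -> float:
    """Binary-logit log likelihood of one respondent's records under ``beta``.

    ``sum log logistic(s * d' beta)`` with ``s = +1`` for an A choice and
    ``-1`` otherwise.
    """
    beta = np.asarray(beta, dtype=float)
    diffs = np.atleast_2d(diffs)
    if diffs.shape[1] != beta.shape[0]:
        raise ValueError(
            f"beta has length {beta.shape[0]}, records have {diffs.shape[1]} columns"
        )
    s = np.where(np.asarray(chose_a, dtype=int) == 1, 1.0, -1.0)
    return float(-np.logaddexp(0.0, -s * (diffs @ beta)).sum())


@dataclass
class HBConfig:
    """Sampler settings and priors for the hierarchical model."""

    n_chains: int = 2
    n_iterations: int = 20_000
    n_burnin: int = 10_000
    thin: int = 10
    target_accept: float = 0.23
    shift_target_accept: float = 0.44   # 1-d translation moves
    initial_step: float = 0.3
    initial_shift_step: float = 0.1
    adapt_interval: int = 50
    init_at_mle: bool = True
    # joint translation sweeps fix slow location mixing when per-respondent
    # data is weak (few choices each); with many records per respondent the
    # location is data-pinned and the sweeps can be disabled for speed
    shift_moves: bool = True
    prior_mu_var: float = 100.0      # tau^2 in mu ~ MVN(0, tau^2 I)
    iw_df: int | None = None         # defaults to p + 2
    iw_scale: np.ndarray | None = None  # defaults to I
    seed: int = 0

    def validate(self, p: int) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        df = self.iw_df if self.iw_df is not None else p + 2
        if df <= p - 1:
            raise ValueError("Inverse-Wishart df must exceed p - 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus acceptance bookkeeping.

    Arrays carry a leading chain axis: ``mu (C, K, p)``, ``sigma
    (C, K, p, p)``, ``beta (C, K, N, p)`` with K retained draws per chain.
    """

    mu: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    accept_rate: np.ndarray          # (N,) post burn-in mean across chains
    respondent_ids: list[str]
    coef_names: list[str]
    config: HBConfig

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]


@dataclass
class PointEstimates:
    """Posterior means: per-respondent betas, population mu and Sigma."""

    beta: np.ndarray     # (N, p)
    mu: np.ndarray       # (p,)
    sigma: np.ndarray    # (p, p)
    respondent_ids: list[str]
    coef_names: list[str]

    def betas_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.beta, columns=self.coef_names)
        df.insert(0, "respondent_id", self.respondent_ids)
        return df


def _sample_inverse_wishart(
    rng: np.random.Generator, df: int, scale: np.ndarray
) -> np.ndarray:
    """Draw Sigma ~ IW(df, scale) via the Bartlett decomposition.

    With ``scale = L L'`` and Bartlett factor ``A`` (lower triangular,
    chi-square diagonal), ``W = (L^-T A)(L^-T A)' ~ Wishart(df, scale^-1)``
    and ``Sigma = W^-1 = X'X`` with ``X = A^-1 L'``.
    """
    p = scale.shape[0]
    scale_chol = cholesky(scale, lower=True)
    bart = np.zeros((p, p))
    bart[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    lower = np.tril_indices(p, -1)
    bart[lower] = rng.standard_normal(len(lower[0]))
    x = solve_triangular(bart, scale_chol.T, lower=True)
    sigma = x.T @ x
    return 0.5 * (sigma + sigma.T)


def _pad_records(data: ChoiceDataset):
    """Group records by respondent into padded (N, T, p) tensors with a weight mask."""
    n, p = data.n_respondents, data.n_coefficients
    counts = np.bincount(data.respondent_idx, minlength=n) if data.n_records else np.zeros(n, int)
    t_max = int(counts.max()) if n else 0
    d = np.zeros((n, t_max, p))
    s = np.ones((n, t_max))
    w = np.zeros((n, t_max))
    fill = np.zeros(n, dtype=int)
    for m in range(data.n_records):
        i = data.respondent_idx[m]
        t = fill[i]
        d[i, t] = data.diffs[m]
        s[i, t] = 1.0 if data.chose_a[m] == 1 else -1.0
        w[i, t] = 1.0
        fill[i] += 1
    return d, s, w


def run_mcmc(data: ChoiceDataset, config: HBConfig | None = None) -> PosteriorDraws:
    """Fit the hierarchical logit by Metropolis-within-Gibbs.

    Deterministic given ``config.seed``; chains use independent substreams
    spawned from it.  With an empty dataset the draws are exact samples from
    the prior (the Metropolis step is skipped and both Gibbs updates reduce
    to their prior conditionals).
    """
    config = config or HBConfig()
    n, p = data.n_respondents, data.n_coefficients
    config.validate(p)
    iw_df = config.iw_df if config.iw_df is not None else p + 2
    iw_scale = (
        np.asarray(config.iw_scale, dtype=float)
        if config.iw_scale is not None
        else np.eye(p)
    )

    d, s, w = _pad_records(data)
    sw = s * w  # sign with padding zeroed: log-logistic(0) terms drop out exactly

    n_keep = -(-(config.n_iterations - config.n_burnin) // config.thin)
    mu_draws = np.empty((config.n_chains, n_keep, p))
    sig_draws = np.empty((config.n_chains, n_keep, p, p))
    beta_draws = np.empty((config.n_chains, n_keep, n, p))
    accept_total = np.zeros(n)

    init = np.zeros(p)
    if n and config.init_at_mle:
        try:
            mle = pooled_logit_mle(data)
            if not mle.separation:
                init = mle.params
        except Exception:
            pass

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        beta = np.tile(init, (n, 1))
        mu = init.copy()
        sigma = np.eye(p)
        step = np.full(n, config.initial_step)
        shift_step = np.full(p, config.initial_shift_step)
        acc_window = np.zeros(n)
        shift_window = np.zeros(p)
        acc_post = np.zeros(n)
        n_post = 0

        def ll_from_u(u: np.ndarray) -> np.ndarray:
            return -(np.logaddexp(0.0, -sw * u) * w).sum(axis=1)

        if n and d.shape[1]:
            u_cur = np.einsum("ntp,np->nt", d, beta)
        else:
            u_cur = np.zeros((n, d.shape[1]))
        ll_cur = ll_from_u(u_cur) if n else np.zeros(n)
        kept = 0
        for it in range(config.n_iterations):
            sig_chol = cholesky(sigma, lower=True)
            if n:
                # prior log density of betas under current (mu, Sigma); the
                # normalizing constant is shared by proposal and current state
                z = solve_triangular(sig_chol, (beta - mu).T, lower=True)
                lp_cur = -0.5 * (z * z).sum(axis=0)

                # individual moves shaped by the heterogeneity covariance
                prop = beta + step[:, None] * (
                    rng.standard_normal((n, p)) @ sig_chol.T
                )
                u_prop = np.einsum("ntp,np->nt", d, prop)
                ll_prop = ll_from_u(u_prop)
                zp = solve_triangular(sig_chol, (prop - mu).T, lower=True)
                lp_prop = -0.5 * (zp * zp).sum(axis=0)

                log_ratio = (ll_prop + lp_prop) - (ll_cur + lp_cur)
                accept = np.log(rng.random(n)) < log_ratio
                beta[accept] = prop[accept]
                u_cur[accept] = u_prop[accept]
                ll_cur[accept] = ll_prop[accept]
                acc_window += accept

                # joint translation moves, one coordinate at a time: shifting
                # mu[j] and every beta[i, j] together leaves beta - mu (and
                # hence the hierarchical prior term) unchanged, so only the
                # data likelihood and the mu prior enter the ratio.  These
                # moves decorrelate the population location, which the
                # centered Gibbs updates alone traverse extremely slowly.
                for j in range(p if config.shift_moves else 0):
                    delta = shift_step[j] * rng.standard_normal()
                    du = d[:, :, j] * delta
                    ll_new = ll_from_u(u_cur + du)
                    lp_mu = (mu[j] ** 2 - (mu[j] + delta) ** 2) / (
                        2.0 * config.prior_mu_var
                    )
                    if np.log(rng.random()) < (ll_new - ll_cur).sum() + lp_mu:
                        beta[:, j] += delta
                        mu[j] += delta
                        u_cur += du
                        ll_cur = ll_new
                        shift_window[j] += 1.0

                if it < config.n_burnin:
                    if (it + 1) % config.adapt_interval == 0:
                        rate = acc_window / config.adapt_interval
                        step *= np.exp(rate - config.target_accept)
                        np.clip(step, 1e-3, 10.0, out=step)
                        acc_window[:] = 0.0
                        shift_rate = shift_window / config.adapt_interval
                        shift_step *= np.exp(shift_rate - config.shift_target_accept)
                        np.clip(shift_step, 1e-4, 5.0, out=shift_step)
                        shift_window[:] = 0.0
                else:
                    acc_post += accept
                    n_post += 1

            # Gibbs: mu | beta, Sigma  with prior MVN(0, tau^2 I)
            sig_inv = cho_solve((sig_chol, True), np.eye(p))
            prec = n * sig_inv + np.eye(p) / config.prior_mu_var
            prec_chol = cholesky(prec, lower=True)
            rhs = sig_inv @ beta.sum(axis=0) if n else np.zeros(p)
            mu_mean = cho_solve((prec_chol, True), rhs)
            mu = mu_mean + solve_triangular(
                prec_chol.T, rng.standard_normal(p), lower=False
            )

            # Gibbs: Sigma | beta, mu  ~ IW(df0 + N, S0 + sum (b-mu)(b-mu)')
            dev = beta - mu
            sigma = _sample_inverse_wishart(rng, iw_df + n, iw_scale + dev.T @ dev)

            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                mu_draws[c, kept] = mu
                sig_draws[c, kept] = sigma
                beta_draws[c, kept] = beta
                kept += 1

        if n and n_post:
            accept_total += acc_post / n_post

    if config.n_chains < 2:
        warnings.warn("fewer than 2 chains: split-Rhat diagnostics unavailable")

    return PosteriorDraws(
        mu=mu_draws,
        sigma=sig_draws,
        beta=beta_draws,
        accept_rate=accept_total / max(config.n_chains, 1),
        respondent_ids=list(data.respondent_ids),
        coef_names=list(data.coef_names) or [f"b{i}" for i in range(p)],
        config=config,
    )


def posterior_point_estimates(draws: PosteriorDraws) -> PointEstimates:
    """Arithmetic means of the retained draws, pooled across chains."""
    if draws.n_draws == 0:
        raise ValueError("no retained draws")
    return PointEstimates(
        beta=draws.beta.mean(axis=(0, 1)),
        mu=draws.mu.mean(axis=(0, 1)),
        sigma=draws.sigma.mean(axis=(0, 1)),
        respondent_ids=draws.respondent_ids,
        coef_names=draws.coef_names,
    )


@dataclass
class PooledLogitResult:
    """Maximum-likelihood fit of a single shared beta (no heterogeneity)."""

    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    separation: bool
    coef_names: list[str]


def pooled_logit_mle(data: ChoiceDataset) -> PooledLogitResult:
    """Pooled binary-logit MLE; the sampler's independent fixed-effects oracle.

    Flags (quasi-)complete separation via non-convergence or runaway
    coefficient magnitudes instead of raising.
    """
    if data.n_records == 0:
        raise ValueError("dataset has no records")
    p = data.n_coefficients
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(data.chose_a, data.diffs)
            res = model.fit(disp=0, maxiter=200)
    except Exception:
        # singular/diverging optimization: (quasi-)complete separation
        return PooledLogitResult(
            params=np.full(p, np.nan),
            bse=np.full(p, np.nan),
            llf=np.nan,
            converged=False,
            separation=True,
            coef_names=list(data.coef_names) or [f"b{i}" for i in range(p)],
        )
    converged = bool(res.mle_retvals.get("converged", False))
    separation = (not converged) or bool(np.any(np.abs(res.params) > 30))
    return PooledLogitResult(
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        llf=float(res.llf),
        converged=converged,
        separation=separation,
        coef_names=list(data.coef_names) or [f"b{i}" for i in range(data.n_coefficients)],
    )
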