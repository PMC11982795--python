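"""Hierarchical Bayesian fit of the changepoint response surface.

The posterior is sampled with a self-contained No-U-Turn sampler (dynamic
Hamiltonian Monte Carlo with dual-averaging step-size adaptation and a
windowed diagonal mass matrix) over an unconstrained parameterization:

==================  =========================  =========================
population          unconstrained coordinate   prior (constrained scale)
==================  =========================  =========================
theta0              log theta0                 lognormal(log 1, 1)
lambda0             log lambda0                lognormal(log 1, 1)
alpha               a, alpha = |a|             half-normal(0.5)
beta                beta                       normal(0, 0.5)
psi_threshold       u, thr = -exp(u)           normal(-1, 1) trunc <= 0
sigma               log sigma                  half-normal(0.5)
RE sds (2)          log sd                     half-normal(0.5)
RE correlation      r, rho = tanh(r)           uniform(-1, 1)
level offsets       z (non-centred)            standard normal
==================  =========================  =========================

Plant-year levels act multiplicatively on theta0 and lambda0 via the
correlated non-centred offsets.  Convergence uses the rank-normalized
split R-hat and model comparison uses PSIS-LOO (both via arviz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "PosteriorDraws",
    "DiagnosticsReport",
    "fit_posterior",
    "compute_rhat",
    "compute_loo",
    "compute_loo_r2",
    "compute_bayes_r2",
    "ppc_coverage",
    "residual_summaries",
    "diagnostics_report",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: population parameters reported on the constrained scale
POPULATION_PARAMS = (
    "theta0",
    "lambda0",
    "alpha",
    "beta",
    "psi_threshold",
    "sigma",
    "sd_log_theta0",
    "sd_log_lambda0",
    "correlation",
)


@dataclass
class FitConfig:
    """Sampler settings; defaults mirror a 4 x 2000-iteration HMC run with
    the first half of each chain used for adaptation."""

    n_chains: int = 4
    n_iterations: int = 2000  # per chain, including warmup
    warmup_fraction: float = 0.5
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10
    no_threshold: bool = False  # fix alpha = beta = 0 (reduced model)
    prior_scales: dict = field(default_factory=dict)  # overrides, see _Priors
    rhat_limit: float = 1.01

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for split R-hat")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")

    @property
    def n_warmup(self) -> int:
        return int(self.n_iterations * self.warmup_fraction)


class _Priors:
    """Prior scales, overridable through FitConfig.prior_scales."""

    def __init__(self, overrides: dict):
        self.log_theta0_sd = overrides.get("log_theta0_sd", 1.0)
        self.log_lambda0_sd = overrides.get("log_lambda0_sd", 1.0)
        self.alpha_sd = overrides.get("alpha_sd", 0.5)
        self.beta_sd = overrides.get("beta_sd", 0.5)
        self.threshold_mean = overrides.get("threshold_mean", -1.0)
        self.threshold_sd = overrides.get("threshold_sd", 1.0)
        self.sigma_sd = overrides.get("sigma_sd", 0.5)
        self.re_sd_sd = overrides.get("re_sd_sd", 0.5)


class _Posterior:
    """Unconstrained log posterior and gradient for the hierarchical model."""

    def __init__(self, y, v, psi, level_idx, n_levels, priors: _Priors, no_threshold=False):
        self.y = np.asarray(y, float)
        self.v = np.asarray(v, float)
        self.psi = np.asarray(psi, float)
        self.li = np.asarray(level_idx, int)
        self.L = int(n_levels)
        self.n = len(self.y)
        self.pr = priors
        self.no_threshold = no_threshold
        self.dim = 9 + 2 * self.L

    # coordinate layout
    M_T, M_L, A, BETA, U_THR, S, LS1, LS2, R = range(9)

    def unpack(self, q):
        z1 = q[9 : 9 + self.L]
        z2 = q[9 + self.L :]
        return q[:9], z1, z2

    def constrained(self, q) -> dict:
        head, z1, z2 = self.unpack(q)
        rho = max(min(math.tanh(head[self.R]), 1.0 - 1e-12), -1.0 + 1e-12)
        alpha = abs(head[self.A])
        beta = head[self.BETA]
        if self.no_threshold:
            alpha = 0.0
            beta = 0.0
        return {
            "theta0": math.exp(head[self.M_T]),
            "lambda0": math.exp(head[self.M_L]),
            "alpha": alpha,
            "beta": beta,
            "psi_threshold": -math.exp(head[self.U_THR]),
            "sigma": math.exp(head[self.S]),
            "sd_log_theta0": math.exp(head[self.LS1]),
            "sd_log_lambda0": math.exp(head[self.LS2]),
            "correlation": rho,
            "z_theta": z1.copy(),
            "z_lambda": z2.copy(),
        }

    def _mean_parts(self, q):
        head, z1, z2 = self.unpack(q)
        sd1, sd2 = math.exp(head[self.LS1]), math.exp(head[self.LS2])
        # clamp away from +-1 so sqrt(1 - rho^2) stays positive in floats
        rho = max(min(math.tanh(head[self.R]), 1.0 - 1e-12), -1.0 + 1e-12)
        u_th = sd1 * z1
        u_lm = sd2 * (rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
        alpha = 0.0 if self.no_threshold else abs(head[self.A])
        beta = 0.0 if self.no_threshold else head[self.BETA]
        thr = -math.exp(head[self.U_THR])
        d = np.maximum(thr - self.psi, 0.0)
        theta = np.exp(head[self.M_T] + u_th[self.li] - alpha * d)
        lam = np.exp(head[self.M_L] + u_lm[self.li] - beta * d)
        E = np.exp(-lam * self.v)
        mu = theta * (1.0 - E)
        return head, z1, z2, sd1, sd2, rho, u_th, u_lm, alpha, beta, thr, d, theta, lam, E, mu

    def pointwise_loglik(self, q):
        *_, mu = self._mean_parts(q)
        sigma = math.exp(q[self.S])
        r = self.y - mu
        return -0.5 * _LOG_2PI - math.log(sigma) - 0.5 * (r / sigma) ** 2

    def mu(self, q):
        *_, mu = self._mean_parts(q)
        return mu

    def logp_grad(self, q):
        (head, z1, z2, sd1, sd2, rho, u_th, u_lm, alpha, beta, thr, d, theta, lam, E, mu) = self._mean_parts(q)
        pr = self.pr
        sigma = math.exp(head[self.S])
        resid = self.y - mu
        inv_s2 = 1.0 / (sigma * sigma)

        logp = (
            -self.n * math.log(sigma)
            - 0.5 * float(resid @ resid) * inv_s2
            - 0.5 * self.n * _LOG_2PI
        )
        grad = np.zeros_like(q)

        g = resid * inv_s2  # d logp / d mu
        A_th = g * mu  # d logp / d log(theta_i)
        A_lm = g * theta * self.v * lam * E  # d logp / d log(lambda_i)

        grad[self.M_T] = A_th.sum()
        grad[self.M_L] = A_lm.sum()
        if not self.no_threshold:
            sign_a = math.copysign(1.0, head[self.A]) if head[self.A] != 0 else 0.0
            grad[self.A] = -float(d @ A_th) * sign_a
            grad[self.BETA] = -float(d @ A_lm)
            below = d > 0
            dthr = -alpha * A_th[below].sum() - beta * A_lm[below].sum()
            grad[self.U_THR] = dthr * (-math.exp(head[self.U_THR]))  # chain rule thr=-e^u
        grad[self.S] = float(resid @ resid) * inv_s2 - self.n

        S_th = np.bincount(self.li, weights=A_th, minlength=self.L)
        S_lm = np.bincount(self.li, weights=A_lm, minlength=self.L)
        sq = math.sqrt(1.0 - rho * rho)
        grad[9 : 9 + self.L] = sd1 * S_th + sd2 * rho * S_lm
        grad[9 + self.L :] = sd2 * sq * S_lm
        grad[self.LS1] = float(S_th @ u_th)
        grad[self.LS2] = float(S_lm @ u_lm)
        du_drho = sd2 * (z1 - rho / sq * z2)
        grad[self.R] = float(S_lm @ du_drho) * (1.0 - rho * rho)

        # priors on unconstrained coordinates (with jacobians)
        logp += -0.5 * (head[self.M_T] / pr.log_theta0_sd) ** 2
        grad[self.M_T] += -head[self.M_T] / pr.log_theta0_sd**2
        logp += -0.5 * (head[self.M_L] / pr.log_lambda0_sd) ** 2
        grad[self.M_L] += -head[self.M_L] / pr.log_lambda0_sd**2
        logp += -0.5 * (head[self.A] / pr.alpha_sd) ** 2
        grad[self.A] += -head[self.A] / pr.alpha_sd**2
        logp += -0.5 * (head[self.BETA] / pr.beta_sd) ** 2
        grad[self.BETA] += -head[self.BETA] / pr.beta_sd**2
        logp += -0.5 * ((thr - pr.threshold_mean) / pr.threshold_sd) ** 2 + head[self.U_THR]
        grad[self.U_THR] += (thr - pr.threshold_mean) / pr.threshold_sd**2 * math.exp(
            head[self.U_THR]
        ) + 1.0
        for idx, scale in ((self.S, pr.sigma_sd), (self.LS1, pr.re_sd_sd), (self.LS2, pr.re_sd_sd)):
            val = math.exp(q[idx])
            logp += -0.5 * (val / scale) ** 2 + q[idx]
            grad[idx] += -(val * val) / scale**2 + 1.0
        logp += math.log1p(-rho * rho)  # tanh jacobian; uniform prior on rho
        grad[self.R] += -2.0 * rho
        logp += -0.5 * float(z1 @ z1) - 0.5 * float(z2 @ z2)
        grad[9 : 9 + self.L] += -z1
        grad[9 + self.L :] += -z2
        return logp, grad


# ---------------------------------------------------------------------------
# No-U-Turn sampler (Hoffman & Gelman 2014, Algorithm 6; diagonal metric)

_DIVERGENCE = 1000.0


class _NutsChain:
    def __init__(self, post: _Posterior, q0, rng, target_accept, max_treedepth, inv_mass=None):
        self.post = post
        self.q = np.asarray(q0, float)
        self.rng = rng
        self.delta = target_accept
        self.max_depth = max_treedepth
        self.inv_mass = np.ones_like(self.q) if inv_mass is None else np.asarray(inv_mass, float)
        self.depth_cap = max_treedepth
        self.logp, self.grad = post.logp_grad(self.q)
        self.divergences = 0
        self._init_step_size()

    def _init_step_size(self):
        self.eps = 0.1
        # crude heuristic: shrink/grow toward ~50% acceptance of one leapfrog
        for _ in range(50):
            p = self.rng.standard_normal(self.q.size) / np.sqrt(self.inv_mass)
            h0 = self.logp - 0.5 * float(p * self.inv_mass @ p)
            q1, p1, logp1, _ = self._leapfrog(self.q, p, self.grad, self.eps)
            h1 = logp1 - 0.5 * float(p1 * self.inv_mass @ p1)
            if not np.isfinite(h1) or h1 - h0 < math.log(0.5):
                self.eps *= 0.5
            else:
                break
        self.mu_eps = math.log(10.0 * self.eps)
        self.h_bar = 0.0
        self.log_eps_bar = 0.0
        self.adapt_count = 0

    def _leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * self.inv_mass * p
        logp, grad = self.post.logp_grad(q)
        p = p + 0.5 * eps * grad
        return q, p, logp, grad

    def _hamiltonian(self, logp, p):
        return logp - 0.5 * float(p * self.inv_mass @ p)

    def _build_tree(self, q, p, grad, logp, log_u, direction, depth, h0):
        if depth == 0:
            q1, p1, logp1, grad1 = self._leapfrog(q, p, grad, direction * self.eps)
            h1 = self._hamiltonian(logp1, p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n_keep = int(log_u <= h1)
            stop = (h1 - log_u) < -_DIVERGENCE
            if stop:
                self.divergences += 1
            accept = min(1.0, math.exp(min(0.0, h1 - h0)))
            return q1, p1, grad1, logp1, q1, p1, grad1, logp1, q1, logp1, n_keep, stop, accept, 1
        (
            qm, pm, gm, lpm, qp, pp, gp, lpp, qs, lps, n_keep, stop, acc, n_acc
        ) = self._build_tree(q, p, grad, logp, log_u, direction, depth - 1, h0)
        if not stop:
            if direction == -1:
                (qm, pm, gm, lpm, _, _, _, _, qs2, lps2, n2, stop2, acc2, na2) = self._build_tree(
                    qm, pm, gm, lpm, log_u, direction, depth - 1, h0
                )
            else:
                (_, _, _, _, qp, pp, gp, lpp, qs2, lps2, n2, stop2, acc2, na2) = self._build_tree(
                    qp, pp, gp, lpp, log_u, direction, depth - 1, h0
                )
            if n2 > 0 and self.rng.random() < n2 / max(n_keep + n2, 1):
                qs, lps = qs2, lps2
            n_keep += n2
            acc += acc2
            n_acc += na2
            dq = qp - qm
            stop = stop2 or (float(dq * self.inv_mass @ pm) < 0) or (
                float(dq * self.inv_mass @ pp) < 0
            )
        return qm, pm, gm, lpm, qp, pp, gp, lpp, qs, lps, n_keep, stop, acc, n_acc

    def step(self, adapt: bool):
        p0 = self.rng.standard_normal(self.q.size) / np.sqrt(self.inv_mass)
        h0 = self._hamiltonian(self.logp, p0)
        log_u = h0 + math.log(self.rng.random())
        qm = qp = self.q
        pm = pp = p0
        gm = gp = self.grad
        lpm = lpp = self.logp
        q_new, logp_new = self.q, self.logp
        n_keep, depth, stop = 1, 0, False
        sum_acc, n_acc = 0.0, 0
        while not stop and depth < min(self.max_depth, self.depth_cap):
            direction = 1 if self.rng.random() < 0.5 else -1
            if direction == -1:
                (qm, pm, gm, lpm, _, _, _, _, qs, lps, n2, stop2, acc, na) = self._build_tree(
                    qm, pm, gm, lpm, log_u, direction, depth, h0
                )
            else:
                (_, _, _, _, qp, pp, gp, lpp, qs, lps, n2, stop2, acc, na) = self._build_tree(
                    qp, pp, gp, lpp, log_u, direction, depth, h0
                )
            if not stop2 and n2 > 0 and self.rng.random() < min(1.0, n2 / n_keep):
                q_new, logp_new = qs, lps
            n_keep += n2
            sum_acc += acc
            n_acc += na
            dq = qp - qm
            stop = stop2 or (float(dq * self.inv_mass @ pm) < 0) or (
                float(dq * self.inv_mass @ pp) < 0
            )
            depth += 1
        if not np.array_equal(q_new, self.q):
            self.q = q_new
            self.logp, self.grad = self.post.logp_grad(q_new)
        accept_stat = sum_acc / max(n_acc, 1)
        if adapt:
            self.adapt_count += 1
            m = self.adapt_count
            kappa, gamma, t0 = 0.75, 0.05, 10.0
            self.h_bar = (1 - 1 / (m + t0)) * self.h_bar + (self.delta - accept_stat) / (m + t0)
            log_eps = self.mu_eps - math.sqrt(m) / gamma * self.h_bar
            self.eps = math.exp(log_eps)
            w = m**-kappa
            self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        return accept_stat

    def freeze_step_size(self):
        self.eps = math.exp(self.log_eps_bar)

    def set_inv_mass(self, inv_mass):
        self.inv_mass = np.maximum(inv_mass, 1e-8)
        self.mu_eps = math.log(10.0 * self.eps)
        self.h_bar = 0.0
        self.adapt_count = 0


@dataclass
class PosteriorDraws:
    """Posterior sample with everything diagnostics need."""

    posterior: dict[str, np.ndarray]  # name -> (chain, draw[, level])
    log_likelihood: np.ndarray  # (chain, draw, observation)
    levels: list[str]
    records: pd.DataFrame
    config: FitConfig
    divergences: int = 0
    max_rhat: float = math.nan
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return next(iter(self.posterior.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.posterior.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Flatten (chain, draw) for one parameter."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def mu_draws(self) -> np.ndarray:
        """Posterior draws of the mean surface at the observed records,
        shape (chain*draw, n_obs)."""
        post = self.posterior
        level_idx = pd.Categorical(
            self.records["season_label"], categories=self.levels
        ).codes
        v = self.records["vpd_max_day"].to_numpy(float)
        psi = self.records["psi_soil_day"].to_numpy(float)
        th0 = self.stacked("theta0")[:, None]
        lm0 = self.stacked("lambda0")[:, None]
        al = self.stacked("alpha")[:, None]
        be = self.stacked("beta")[:, None]
        thr = self.stacked("psi_threshold")[:, None]
        off_t = self.stacked("offset_log_theta0")[:, level_idx]
        off_l = self.stacked("offset_log_lambda0")[:, level_idx]
        d = np.maximum(thr - psi[None, :], 0.0)
        theta = th0 * np.exp(off_t - al * d)
        lam = lm0 * np.exp(off_l - be * d)
        return theta * -np.expm1(-lam * v[None, :])

    def to_inferencedata(self) -> az.InferenceData:
        coords = {"level": self.levels, "obs_id": np.arange(self.log_likelihood.shape[-1])}
        post_vars = {}
        for name, arr in self.posterior.items():
            dims = ("chain", "draw") if arr.ndim == 2 else ("chain", "draw", "level")
            post_vars[name] = (dims, arr)
        posterior = xr.Dataset(post_vars, coords={"level": self.levels})
        loglik = xr.Dataset(
            {"delta_psi": (("chain", "draw", "obs_id"), self.log_likelihood)},
            coords={"obs_id": coords["obs_id"]},
        )
        return az.InferenceData(posterior=posterior, log_likelihood=loglik)

    def to_netcdf(self, path) -> None:
        self.to_inferencedata().to_netcdf(str(path))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in POPULATION_PARAMS:
            flat = self.stacked(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std()),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q50": float(np.quantile(flat, 0.5)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                }
            )
        return pd.DataFrame(rows)


def fit_posterior(records: pd.DataFrame, config: FitConfig | None = None) -> PosteriorDraws:
    """Sample the hierarchical changepoint model on a daily-record table.

    ``records`` needs columns ``delta_psi_max, vpd_max_day, psi_soil_day,
    season_label``.  With a single plant-year level the hierarchy degrades
    to a fixed-effects fit (warning).  Stores the pointwise log-likelihood
    for LOO and flags non-convergence via rank-normalized split R-hat.
    """
    config = config or FitConfig()
    levels = sorted(records["season_label"].astype(str).unique())
    if len(levels) < 2:
        logger.warning("only one plant-year level: hierarchy degrades to fixed effects")
    level_idx = pd.Categorical(records["season_label"].astype(str), categories=levels).codes
    post = _Posterior(
        records["delta_psi_max"].to_numpy(float),
        records["vpd_max_day"].to_numpy(float),
        records["psi_soil_day"].to_numpy(float),
        level_idx,
        len(levels),
        _Priors(config.prior_scales),
        no_threshold=config.no_threshold,
    )
    n_keep = config.n_iterations - config.n_warmup
    rng_master = np.random.default_rng(config.seed)
    chain_states = np.empty((config.n_chains, n_keep, post.dim))
    divergences = 0

    y = post.y
    q_init = np.zeros(post.dim)
    q_init[post.M_T] = math.log(max(float(np.quantile(y, 0.9)), 0.2))
    q_init[post.M_L] = 0.0
    q_init[post.A] = 0.1
    q_init[post.U_THR] = 0.0
    q_init[post.S] = math.log(max(float(y.std() / 2), 0.02))
    q_init[post.LS1] = q_init[post.LS2] = math.log(0.1)

    warm = config.n_warmup
    # adaptation schedule: collect draws early, re-estimate the diagonal
    # mass twice, and cap tree depth until the first estimate exists (the
    # identity metric otherwise wastes deep trees on ill-scaled directions)
    win_edges = [max(int(warm * f), 1) for f in (0.05, 0.3, 0.7)]
    init_inv_mass = np.full(post.dim, 0.01)
    init_inv_mass[9:] = 1.0  # non-centred offsets are ~unit scale
    for c in range(config.n_chains):
        rng = np.random.default_rng(rng_master.integers(2**63))
        q0 = q_init + 0.1 * rng.standard_normal(post.dim)
        chain = _NutsChain(
            post, q0, rng, config.target_accept, config.max_treedepth, inv_mass=init_inv_mass
        )
        chain.depth_cap = min(7, config.max_treedepth)
        window: list[np.ndarray] = []
        for it in range(config.n_iterations):
            adapt = it < warm
            chain.step(adapt)
            if adapt:
                if it >= win_edges[0]:
                    window.append(chain.q.copy())
                if it + 1 in win_edges[1:] and len(window) > 10:
                    draws = np.asarray(window)
                    n = len(draws)
                    var = draws.var(axis=0, ddof=1)
                    var = n / (n + 5.0) * var + 1e-3 * (5.0 / (n + 5.0))
                    chain.set_inv_mass(var)
                    chain.depth_cap = config.max_treedepth
                    window = []
                if it + 1 == warm:
                    chain.freeze_step_size()
            else:
                chain_states[c, it - warm] = chain.q
        divergences += chain.divergences
        logger.info(
            "chain %d: step size %.4g, %d divergence(s)", c, chain.eps, chain.divergences
        )

    # constrained draws
    names_scalar = list(POPULATION_PARAMS)
    posterior = {k: np.empty((config.n_chains, n_keep)) for k in names_scalar}
    posterior["offset_log_theta0"] = np.empty((config.n_chains, n_keep, post.L))
    posterior["offset_log_lambda0"] = np.empty((config.n_chains, n_keep, post.L))
    loglik = np.empty((config.n_chains, n_keep, post.n))
    for c in range(config.n_chains):
        for d in range(n_keep):
            q = chain_states[c, d]
            con = post.constrained(q)
            for k in names_scalar:
                posterior[k][c, d] = con[k]
            sd1, sd2, rho = con["sd_log_theta0"], con["sd_log_lambda0"], con["correlation"]
            posterior["offset_log_theta0"][c, d] = sd1 * con["z_theta"]
            posterior["offset_log_lambda0"][c, d] = sd2 * (
                rho * con["z_theta"] + math.sqrt(1 - rho * rho) * con["z_lambda"]
            )
            loglik[c, d] = post.pointwise_loglik(q)

    draws = PosteriorDraws(
        posterior=posterior,
        log_likelihood=loglik,
        levels=levels,
        records=records.reset_index(drop=True),
        config=config,
        divergences=divergences,
    )
    rhat = compute_rhat(draws)
    finite = [v for v in rhat.values() if np.isfinite(v)]
    draws.max_rhat = max(finite) if finite else math.nan
    draws.converged = bool(draws.max_rhat < config.rhat_limit)
    if not draws.converged:
        logger.warning("non-convergence: max R-hat %.4f >= %.2f", draws.max_rhat, config.rhat_limit)
    return draws


def compute_rhat(draws: PosteriorDraws, params: Sequence[str] = POPULATION_PARAMS) -> dict:
    """Rank-normalized split R-hat per population parameter.

    Requires >= 2 chains; parameters with (near-)zero variance across all
    chains are flagged with NaN.
    """
    out = {}
    for name in params:
        arr = draws.posterior[name]
        if arr.shape[0] < 2:
            raise ValueError("R-hat needs at least 2 chains")
        if float(arr.std()) < 1e-12:
            out[name] = math.nan
            continue
        out[name] = float(az.rhat(az.convert_to_dataset(arr), method="rank")["x"].values)
    return out


def compute_loo(draws: PosteriorDraws) -> az.ELPDData:
    """PSIS-LOO expected log predictive density."""
    return az.loo(draws.to_inferencedata(), pointwise=True)


def compute_loo_r2(
    draws: PosteriorDraws, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """LOO R-squared with a 95% interval.

    Leave-one-out predictive means come from Pareto-smoothed importance
    weights applied to the posterior mean-surface draws; the interval is a
    Bayesian bootstrap over observations.  Attaches a log warning when more
    than 5% of the Pareto shape diagnostics exceed 0.7.
    """
    ll = draws.log_likelihood.reshape(-1, draws.log_likelihood.shape[-1])
    log_w, k = az.psislw(-ll.T)
    frac_bad = float(np.mean(np.asarray(k) > 0.7))
    if frac_bad > 0.05:
        logger.warning("PSIS-LOO: %.1f%% of Pareto k diagnostics exceed 0.7", 100 * frac_bad)
    w = np.exp(np.asarray(log_w))  # (n_obs, n_draws), normalized
    mu = draws.mu_draws()  # (n_draws, n_obs)
    y = draws.records["delta_psi_max"].to_numpy(float)
    y_loo = np.einsum("os,so->o", w, mu)
    resid = y - y_loo
    point = 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        om = rng.dirichlet(np.ones(n))
        ybar = float(om @ y)
        boots[b] = 1.0 - float(om @ resid**2) / float(om @ (y - ybar) ** 2)
    return point, (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))


def compute_bayes_r2(draws: PosteriorDraws) -> tuple[float, tuple[float, float]]:
    """Ordinary Bayesian R-squared: draw-wise ``var(mu) / (var(mu) + sigma^2)``."""
    mu = draws.mu_draws()
    sigma = draws.stacked("sigma")
    var_fit = mu.var(axis=1)
    r2 = var_fit / (var_fit + sigma**2)
    return float(r2.mean()), (float(np.quantile(r2, 0.025)), float(np.quantile(r2, 0.975)))


def ppc_coverage(draws: PosteriorDraws, level: float = 0.95, seed: int = 0) -> float:
    """Fraction of observations inside the central posterior-predictive interval."""
    rng = np.random.default_rng(seed)
    mu = draws.mu_draws()
    sigma = draws.stacked("sigma")[:, None]
    y_rep = mu + rng.standard_normal(mu.shape) * sigma
    lo = np.quantile(y_rep, (1 - level) / 2, axis=0)
    hi = np.quantile(y_rep, 1 - (1 - level) / 2, axis=0)
    y = draws.records["delta_psi_max"].to_numpy(float)
    return float(np.mean((y >= lo) & (y <= hi)))


def residual_summaries(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-plant mean and mean-absolute residual against the posterior-mean fit."""
    mu_hat = draws.mu_draws().mean(axis=0)
    df = draws.records.copy()
    df["residual"] = df["delta_psi_max"].to_numpy(float) - mu_hat
    out = (
        df.assign(abs_residual=lambda d: d["residual"].abs())
        .groupby("plant_id")[["residual", "abs_residual"]]
        .mean()
        .reset_index()
    )
    return out


@dataclass
class DiagnosticsReport:
    rhat: dict[str, float]
    loo_elpd: float
    loo_se: float
    loo_r2: float
    loo_r2_ci: tuple[float, float]
    bayes_r2: float
    bayes_r2_ci: tuple[float, float]
    ppc_coverage: float
    residuals_by_plant: pd.DataFrame
    converged: bool

    def to_dict(self) -> dict:
        return {
            "rhat": {k: (None if math.isnan(v) else v) for k, v in self.rhat.items()},
            "max_rhat": max((v for v in self.rhat.values() if np.isfinite(v)), default=None),
            "loo_elpd": self.loo_elpd,
            "loo_se": self.loo_se,
            "loo_r2": self.loo_r2,
            "loo_r2_ci": list(self.loo_r2_ci),
            "bayes_r2": self.bayes_r2,
            "bayes_r2_ci": list(self.bayes_r2_ci),
            "ppc_coverage": self.ppc_coverage,
            "converged": self.converged,
            "residuals_by_plant": self.residuals_by_plant.to_dict(orient="records"),
        }


def diagnostics_report(draws: PosteriorDraws) -> DiagnosticsReport:
    """Full diagnostic suite for one fit."""
    rhat = compute_rhat(draws)
    loo = compute_loo(draws)
    loo_r2, loo_ci = compute_loo_r2(draws)
    br2, br2_ci = compute_bayes_r2(draws)
    cov = ppc_coverage(draws)
    return DiagnosticsReport(
        rhat=rhat,
        loo_elpd=float(loo.elpd_loo),
        loo_se=float(loo.se),
        loo_r2=loo_r2,
        loo_r2_ci=loo_ci,
        bayes_r2=br2,
        bayes_r2_ci=br2_ci,
        ppc_coverage=cov,
        residuals_by_plant=residual_summaries(draws),
        converged=bool(draws.converged),
    )
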