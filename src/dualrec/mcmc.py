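"""Latent-trait MCMC sampler for the hierarchical dual-recollection model.

Model: participant i's probability parameters are theta_i = Phi(alpha_i)
elementwise, alpha_i ~ MVN(mu, Sigma) on the probit scale; cell counts are
independent binomials at the tree probabilities.  Priors: mu_s ~ N(0, 1)
independently (uniform on the probability scale marginally), Sigma ~
Inverse-Wishart(df = K + 2, scale = I), a weakly informative choice whose
prior mode is close to unit probit-scale variances.

Sampling is Metropolis-within-Gibbs: per iteration, each of the nine
alpha columns gets a vectorized random-walk Metropolis update across all
participants (only the tree cells that depend on that parameter are
re-evaluated), then mu and Sigma are drawn from their conjugate full
conditionals.  Proposal step sizes adapt per participant x parameter
during burn-in toward ~44% acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import invwishart, norm

from .design import DesignSpec, ItemClass, ProbeType
from .params import PARAM_NAMES
from .trees import _BIAS, _F, _RC, _RT, _cell_prob

K = len(PARAM_NAMES)
_EPS = 1e-9  # likelihood clamp; keeps log finite without moving interior optima


@dataclass(frozen=True)
class PriorConfig:
    """Priors of the latent-trait model (probit scale)."""

    mu_mean: float = 0.0
    mu_sd: float = 1.0
    wishart_df: float = K + 2
    wishart_scale: np.ndarray | None = None  # default: identity

    def scale_matrix(self) -> np.ndarray:
        if self.wishart_scale is None:
            return np.eye(K)
        return np.asarray(self.wishart_scale, float)


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.  Defaults suit a final fit; replication studies in
    the test suite use fewer chains/draws for speed."""

    chains: int = 4
    draws: int = 2000
    burn: int = 1000
    adapt_every: int = 25
    target_accept: float = 0.44
    rhat_threshold: float = 1.05


def _param_cell_dependencies(design: DesignSpec) -> list[np.ndarray]:
    """For each parameter, the indices of cells whose probability involves it."""
    deps: list[list[int]] = [[] for _ in range(K)]
    for j, (probe, item) in enumerate(design.cells):
        deps[_BIAS[probe]].append(j)
        if item.studied:
            c = "A" if item == ItemClass.target_A else "B"
            deps[_RC[c]].append(j)
            deps[_RT[c]].append(j)
            if probe == ProbeType.ask_A_or_B:
                deps[_F[c]].append(j)
    return [np.array(d, dtype=int) for d in deps]


def _cell_ll(theta: np.ndarray, yes: np.ndarray, n: np.ndarray,
             design: DesignSpec, cols: np.ndarray) -> np.ndarray:
    """Per-participant, per-cell binomial log-likelihood kernel for a subset
    of cells (binomial coefficients omitted: they cancel in MH ratios)."""
    out = np.empty((theta.shape[0], cols.size))
    cells = design.cells
    for k, j in enumerate(cols):
        probe, item = cells[j]
        p = np.clip(_cell_prob(theta, probe, item), _EPS, 1.0 - _EPS)
        out[:, k] = yes[:, j] * np.log(p) + (n[:, j] - yes[:, j]) * np.log1p(-p)
    return out


def _init_alpha(yes: np.ndarray, n: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Initialize probit effects near each participant's smoothed cell rates.

    A crude common start (probit of the pooled rate, jittered) is robust:
    the burn-in walks participants to their own region.
    """
    pooled = (yes.sum(axis=0) + 1.0) / (n.sum(axis=0) + 2.0)
    base = norm.ppf(np.clip(pooled.mean(), 0.05, 0.95))
    return base + 0.5 * rng.standard_normal((yes.shape[0], K))


def run_chain(
    yes: np.ndarray,
    n: np.ndarray,
    design: DesignSpec,
    prior: PriorConfig,
    mcmc: McmcConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Run one chain; returns retained draws of mu, Sigma and alpha."""
    N = yes.shape[0]
    deps = _param_cell_dependencies(design)
    all_cols = np.arange(design.n_cells)

    alpha = _init_alpha(yes, n, rng)
    theta = norm.cdf(alpha)
    L = _cell_ll(theta, yes, n, design, all_cols)  # (N, C) cache

    mu = np.zeros(K)
    sigma = 0.25 * np.eye(K)
    prec = np.linalg.inv(sigma)

    step = np.full((N, K), 0.5)
    acc = np.zeros((N, K))
    shift_step = np.full(K, 0.3)
    shift_acc = np.zeros(K)
    prop_count = 0

    S0 = prior.scale_matrix()
    nu0 = prior.wishart_df
    prior_prec_mu = 1.0 / prior.mu_sd**2

    n_iter = mcmc.burn + mcmc.draws
    mu_out = np.empty((mcmc.draws, K))
    sigma_out = np.empty((mcmc.draws, K, K))
    alpha_out = np.empty((mcmc.draws, N, K))

    for it in range(n_iter):
        # --- Metropolis updates of the probit effects, one column at a time
        for s in range(K):
            cols = deps[s]
            d = step[:, s] * rng.standard_normal(N)
            alpha_prop = alpha[:, s] + d
            theta_prop = theta.copy()
            theta_prop[:, s] = norm.cdf(alpha_prop)
            L_new = _cell_ll(theta_prop, yes, n, design, cols)
            dll = L_new.sum(axis=1) - L[:, cols].sum(axis=1)
            r = alpha - mu[None, :]
            q = r @ prec[s]
            dprior = -(0.5 * prec[s, s] * d**2 + d * q)
            accept = np.log(rng.random(N)) < dll + dprior
            if accept.any():
                alpha[accept, s] = alpha_prop[accept]
                theta[accept, s] = theta_prop[accept, s]
                L[np.ix_(accept, cols)] = L_new[accept]
            acc[:, s] += accept

        # --- interweaving: joint shift of mu_s and all alpha_is (the
        # non-centered update; crucial for weakly informed parameters such
        # as familiarity, where the centered walk mixes slowly)
        for s in range(K):
            eps = shift_step[s] * rng.standard_normal()
            theta_prop = theta.copy()
            theta_prop[:, s] = norm.cdf(alpha[:, s] + eps)
            cols = deps[s]
            L_new = _cell_ll(theta_prop, yes, n, design, cols)
            dll = L_new.sum() - L[:, cols].sum()
            mu_new = mu[s] + eps
            dprior = (
                (mu[s] - prior.mu_mean) ** 2 - (mu_new - prior.mu_mean) ** 2
            ) / (2.0 * prior.mu_sd**2)
            if np.log(rng.random()) < dll + dprior:
                alpha[:, s] += eps
                mu[s] = mu_new
                theta[:, s] = theta_prop[:, s]
                L[:, cols] = L_new
                shift_acc[s] += 1

        prop_count += 1
        if it < mcmc.burn and prop_count == mcmc.adapt_every:
            rate = acc / prop_count
            step *= np.where(rate > mcmc.target_accept, 1.15, 0.87)
            np.clip(step, 0.01, 5.0, out=step)
            acc[:] = 0.0
            srate = shift_acc / prop_count
            shift_step *= np.where(srate > mcmc.target_accept, 1.15, 0.87)
            np.clip(shift_step, 0.005, 3.0, out=shift_step)
            shift_acc[:] = 0.0
            prop_count = 0

        # --- conjugate draw of mu | alpha, Sigma  (prior mu_s ~ N(m0, sd0))
        post_prec = prior_prec_mu * np.eye(K) + N * prec
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (
            prec @ alpha.sum(axis=0) + prior_prec_mu * prior.mu_mean * np.ones(K)
        )
        mu = rng.multivariate_normal(post_mean, post_cov, method="cholesky")

        # --- conjugate draw of Sigma | alpha, mu
        r = alpha - mu[None, :]
        scale = S0 + r.T @ r
        sigma = invwishart.rvs(df=nu0 + N, scale=scale, random_state=rng)
        prec = np.linalg.inv(sigma)

        if it >= mcmc.burn:
            t = it - mcmc.burn
            mu_out[t] = mu
            sigma_out[t] = sigma
            alpha_out[t] = alpha

    return {"mu": mu_out, "sigma": sigma_out, "alpha": alpha_out}


def run_chains(
    yes: np.ndarray,
    n: np.ndarray,
    design: DesignSpec,
    prior: PriorConfig,
    mcmc: McmcConfig,
    seed: int,
) -> dict[str, np.ndarray]:
    """Run all chains from independent child seeds of ``seed``; stacks
    results to (chains, draws, ...) arrays."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(mcmc.chains)
    results = [
        run_chain(yes, n, design, prior, mcmc, np.random.default_rng(child))
        for child in children
    ]
    return {
        key: np.stack([res[key] for res in results], axis=0)
        for key in ("mu", "sigma", "alpha")
    }
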