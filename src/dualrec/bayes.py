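"""Posterior containers, difference tests and posterior predictive checks.

Group-level parameters are reported as Phi(mu) per draw (the probability-
scale location of the latent-trait distribution), matching how hierarchical
MPT group means are conventionally tabulated.  Difference tests operate on
these per-draw group parameters:

* within-group: the posterior of ``param_p - param_q`` with an equal-tailed
  95% credible interval (BCI); evidence for a difference when the BCI
  excludes zero;
* between-group: draws from two independently fitted groups are paired
  (after a fixed-seed permutation) and the difference summarized the same
  way, plus ``p_b``, the posterior probability that the difference is
  below zero (ties split evenly), so ``p_b`` near 0 or 1 signals a
  directionally consistent difference.

Fit is assessed with posterior-predictive p values on two discrepancies:
T1 targets the mean structure (a Pearson-type statistic on the per-cell
mean frequencies), T2 the covariance structure (sum of squared deviations
between the across-participant covariance matrix of cell frequencies and
the model-implied one).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import DesignSpec
from .mcmc import McmcConfig, PriorConfig
from .params import PARAM_NAMES
from .trees import cell_probabilities

__all__ = [
    "PosteriorSamples",
    "HierarchicalResults",
    "DifferenceSummary",
    "FitDiagnostics",
    "parameter_difference",
    "between_group_difference",
    "posterior_predictive_check",
]

K = len(PARAM_NAMES)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of the latent-trait model.

    ``mu``: (chains, draws, 9) probit-scale group means; ``sigma``:
    (chains, draws, 9, 9) random-effect covariance; ``alpha``: (chains,
    draws, n_participants, 9) probit-scale participant parameters.
    """

    mu: np.ndarray
    sigma: np.ndarray
    alpha: np.ndarray
    participant_ids: list[str]
    seed: int
    prior: PriorConfig
    mcmc: McmcConfig

    def __post_init__(self) -> None:
        c, d, k = self.mu.shape
        if k != K or self.sigma.shape[:2] != (c, d) or self.alpha.shape[:2] != (c, d):
            raise ValueError("inconsistent draw shapes")

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def group_means(self) -> np.ndarray:
        """Probability-scale group parameters, (chains, draws, 9)."""
        return norm.cdf(self.mu)

    def flat_group_means(self) -> np.ndarray:
        """(chains*draws, 9), chains concatenated."""
        return self.group_means.reshape(-1, K)

    def param_draws(self, name: str) -> np.ndarray:
        """Flattened probability-scale draws of one group parameter."""
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        return self.flat_group_means()[:, PARAM_NAMES.index(name)]

    def rhat(self) -> pd.Series:
        """Split-Rhat of the probit-scale group means, per parameter."""
        ds = az.convert_to_dataset(self.mu[:, :, :], group="posterior")
        rh = az.rhat(ds)["x"].values
        return pd.Series(rh, index=list(PARAM_NAMES), name="rhat")


@dataclass
class DifferenceSummary:
    """Posterior summary of a parameter difference."""

    delta_mean: float
    bci_low: float
    bci_high: float
    excludes_zero: bool
    p_b: float | None = None

    def __repr__(self) -> str:
        s = (
            f"delta={self.delta_mean:+.3f}, BCI=[{self.bci_low:.3f}, "
            f"{self.bci_high:.3f}], excludes_zero={self.excludes_zero}"
        )
        if self.p_b is not None:
            s += f", p_b={self.p_b:.3f}"
        return f"<DifferenceSummary {s}>"


@dataclass
class FitDiagnostics:
    """Posterior-predictive p values and convergence summary."""

    t1_ppp: float
    t2_ppp: float
    rhat: pd.Series

    @property
    def converged(self) -> bool:
        return bool((self.rhat <= 1.05).all())


def _summarize_delta(delta: np.ndarray, p_b: float | None = None) -> DifferenceSummary:
    lo, hi = np.percentile(delta, [2.5, 97.5])
    excludes = (lo > 0.0) or (hi < 0.0)
    return DifferenceSummary(
        delta_mean=float(delta.mean()),
        bci_low=float(lo),
        bci_high=float(hi),
        excludes_zero=bool(excludes),
        p_b=p_b,
    )


def parameter_difference(samples: PosteriorSamples, p: str, q: str) -> DifferenceSummary:
    """Posterior of the within-group difference ``p - q`` of group parameters."""
    delta = samples.param_draws(p) - samples.param_draws(q)
    return _summarize_delta(delta)


def between_group_difference(
    samples_g1: PosteriorSamples,
    samples_g2: PosteriorSamples,
    p: str,
    permute: bool = True,
    seed: int = 2024,
) -> DifferenceSummary:
    """Difference of one group parameter between two independent fits.

    Draws from the two posteriors are paired after a fixed-seed random
    permutation (the groups were fit independently, so any pairing is
    valid; fixing the permutation makes runs reproducible).  ``p_b`` is the
    posterior probability that group1 - group2 < 0, counting ties as half.
    """
    d1 = samples_g1.param_draws(p)
    d2 = samples_g2.param_draws(p)
    m = min(d1.size, d2.size)
    rng = np.random.default_rng(seed)
    if permute:
        d1 = rng.permutation(d1)[:m]
        d2 = rng.permutation(d2)[:m]
    else:
        d1, d2 = d1[:m], d2[:m]
    delta = d1 - d2
    p_b = float(np.mean(delta < 0.0) + 0.5 * np.mean(delta == 0.0))
    return _summarize_delta(delta, p_b=p_b)


def _t1(mean_obs: np.ndarray, mean_exp: np.ndarray) -> float:
    """Pearson-type discrepancy on per-cell mean frequencies."""
    e = np.maximum(mean_exp, 1e-12)
    return float(np.sum((mean_obs - mean_exp) ** 2 / e))


def _t2(cov_obs: np.ndarray, cov_exp: np.ndarray) -> float:
    """Sum of squared deviations between covariance matrices."""
    return float(np.sum((cov_obs - cov_exp) ** 2))


def posterior_predictive_check(
    samples: PosteriorSamples,
    yes: np.ndarray,
    n: np.ndarray,
    design: DesignSpec,
    n_rep: int = 200,
    seed: int = 0,
) -> FitDiagnostics:
    """Posterior-predictive p values for mean (T1) and covariance (T2)
    structure of the individual cell frequencies.

    For each of ``n_rep`` retained draws, the participant-level parameters
    at that draw give expected frequencies and a replicated dataset; the
    ppp value is the fraction of draws whose replicated discrepancy exceeds
    the observed one.  Well-calibrated values lie away from 0 and 1.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if yes.shape[0] == 0:
        raise ValueError("posterior predictive check requires participants")
    total = samples.n_chains * samples.n_draws
    if n_rep > total:
        raise ValueError(f"n_rep={n_rep} exceeds available draws ({total})")
    alpha_flat = samples.alpha.reshape(total, *samples.alpha.shape[2:])
    idx = np.linspace(0, total - 1, n_rep).astype(int)
    rng = np.random.default_rng(seed)
    n_row = n[0]  # cell sizes are shared across participants by design

    t1_exceed = 0
    t2_exceed = 0
    for t in idx:
        theta = norm.cdf(alpha_flat[t])  # (N, 9)
        p = cell_probabilities(theta, design)  # (N, C)
        exp_freq = n * p
        mean_exp = exp_freq.mean(axis=0)
        # model-implied covariance of cell frequencies across participants:
        # between-participant spread of expectations + binomial noise
        cov_exp = np.cov(exp_freq.T, bias=False) + np.diag(
            (n * p * (1 - p)).mean(axis=0)
        )
        yrep = rng.binomial(n.astype(int), p)

        t1_obs = _t1(yes.mean(axis=0), mean_exp)
        t1_rep = _t1(yrep.mean(axis=0), mean_exp)
        t2_obs = _t2(np.cov(yes.T, bias=False), cov_exp)
        t2_rep = _t2(np.cov(yrep.T, bias=False), cov_exp)
        t1_exceed += t1_rep >= t1_obs
        t2_exceed += t2_rep >= t2_obs

    return FitDiagnostics(
        t1_ppp=t1_exceed / n_rep,
        t2_ppp=t2_exceed / n_rep,
        rhat=samples.rhat(),
    )


class HierarchicalResults:
    """Results of the hierarchical latent-trait fit.

    Carries the posterior draws plus convenience methods mirroring the
    analyses a conjoint-recognition study reports: a Table-style summary of
    group parameters, within-group parameter differences, and posterior
    predictive fit diagnostics.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples
        self._rhat: pd.Series | None = None

    @property
    def rhat(self) -> pd.Series:
        if self._rhat is None:
            self._rhat = self.samples.rhat()
        return self._rhat

    @property
    def converged(self) -> bool:
        return bool((self.rhat <= self.samples.mcmc.rhat_threshold).all())

    def params_series(self) -> pd.Series:
        return pd.Series(
            self.samples.flat_group_means().mean(axis=0),
            index=list(PARAM_NAMES),
            name="posterior_mean",
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and equal-tailed 95% BCI per group parameter,
        probability scale, plus split-Rhat."""
        flat = self.samples.flat_group_means()
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        df = pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "bci_low": lo,
                "bci_high": hi,
                "rhat": self.rhat.values,
            },
            index=list(PARAM_NAMES),
        )
        return df

    def difference(self, p: str, q: str) -> DifferenceSummary:
        return parameter_difference(self.samples, p, q)

    def ppc(self, n_rep: int = 200, seed: int = 0) -> FitDiagnostics:
        return posterior_predictive_check(
            self.samples, self.model.yes, self.model.n, self.model.design,
            n_rep=n_rep, seed=seed,
        )

    def plot_params(self, ax=None, truth=None):
        """Posterior means with 95% BCI error bars; optionally overlay the
        generating truths of a simulation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        summ = self.summary()
        x = np.arange(len(summ))
        err = np.vstack(
            [summ["mean"] - summ["bci_low"], summ["bci_high"] - summ["mean"]]
        )
        ax.errorbar(x, summ["mean"], yerr=err, fmt="o", capsize=3,
                    color="black", label="posterior mean (95% BCI)")
        if truth is not None:
            ax.plot(x, np.asarray(truth, float), "x", color="tab:red",
                    markersize=8, label="generating value")
            ax.legend(frameon=False)
        ax.set_xticks(x)
        ax.set_xticklabels(summ.index)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("probability")
        return ax

    def participant_means(self) -> pd.DataFrame:
        """Posterior-mean probability parameters per participant."""
        theta = norm.cdf(self.samples.alpha)  # (chains, draws, N, K)
        m = theta.reshape(-1, *theta.shape[2:]).mean(axis=0)
        return pd.DataFrame(
            m, index=self.samples.participant_ids, columns=list(PARAM_NAMES)
        )

    def __repr__(self) -> str:
        return (
            f"<HierarchicalResults chains={self.samples.n_chains} "
            f"draws={self.samples.n_draws} converged={self.converged}>"
        )
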