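"""Model and results objects for the dual-recollection MPT.

`DualRecollectionModel` is built from per-participant cell counts and a
design; `fit()` maximizes the pooled (aggregate) binomial likelihood and
returns an `MLResults`, while `fit_bayes()` runs the hierarchical
latent-trait sampler and returns a `HierarchicalResults` (see
:mod:`dualrec.bayes`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignSpec, ResponseCounts
from .mcmc import McmcConfig, PriorConfig, run_chains
from .params import PARAM_NAMES, ParameterVector
from .trees import cell_probabilities, moment_estimator

__all__ = ["DualRecollectionModel", "MLResults"]

K = len(PARAM_NAMES)
_EPS = 1e-9


class DualRecollectionModel:
    """Dual-recollection MPT over conjoint-recognition cell counts.

    Parameters
    ----------
    counts : sequence of ResponseCounts or tidy DataFrame
        A DataFrame needs columns ``participant``, ``probe``,
        ``item_class``, ``yes``, ``n``.
    design : DesignSpec
        The cell layout the counts must conform to.
    """

    def __init__(self, counts, design: DesignSpec):
        self.design = design
        if isinstance(counts, pd.DataFrame):
            counts = self._counts_from_frame(counts)
        counts = list(counts)
        if not counts:
            raise ValueError("at least one participant is required")
        for c in counts:
            if not c.conforms_to(design):
                raise ValueError(
                    f"participant {c.participant_id}: cells do not match design"
                )
        self.counts = counts
        self.participant_ids = [c.participant_id for c in counts]
        keys = design.cell_keys
        self.yes = np.array([[c.counts[k][0] for k in keys] for c in counts], float)
        self.n = np.array([[c.counts[k][1] for k in keys] for c in counts], float)

    @staticmethod
    def _counts_from_frame(df: pd.DataFrame) -> list[ResponseCounts]:
        required = {"participant", "probe", "item_class", "yes", "n"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"counts frame missing columns {sorted(missing)}")
        out = []
        for pid, grp in df.groupby("participant", sort=True):
            cells = {
                f"{row.probe}:{row.item_class}": (int(row.yes), int(row.n))
                for row in grp.itertuples()
            }
            out.append(ResponseCounts(participant_id=str(pid), counts=cells))
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: DesignSpec):
        return cls(df, design)

    @property
    def nobs(self) -> int:
        return len(self.counts)

    # ------------------------------------------------------------------
    # pooled likelihood
    def pooled_counts(self) -> tuple[np.ndarray, np.ndarray]:
        return self.yes.sum(axis=0), self.n.sum(axis=0)

    def loglike(self, theta) -> float:
        """Pooled binomial log-likelihood of probability-scale ``theta``."""
        arr = theta.to_array() if isinstance(theta, ParameterVector) else np.asarray(theta, float)
        yes, n = self.pooled_counts()
        p = np.clip(cell_probabilities(arr, self.design), _EPS, 1 - _EPS)
        return float(np.sum(yes * np.log(p) + (n - yes) * np.log1p(-p)))

    def fit(self) -> "MLResults":
        """Aggregate maximum likelihood on the pooled counts.

        Starts from the algebraic moment estimate of the pooled rates and
        polishes with L-BFGS-B; standard errors come from the observed
        information (finite-difference Hessian).
        """
        yes, n = self.pooled_counts()
        rates = np.clip(yes / n, 1e-4, 1 - 1e-4)
        start = np.clip(
            moment_estimator(rates, self.design).theta.to_array(), 1e-3, 1 - 1e-3
        )

        def nll(x):
            return -self.loglike(x)

        res = optimize.minimize(
            nll,
            start,
            method="L-BFGS-B",
            bounds=[(1e-6, 1 - 1e-6)] * K,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
        )
        params = np.clip(res.x, 0.0, 1.0)
        at_boundary = [
            PARAM_NAMES[i]
            for i in range(K)
            if params[i] < 1e-5 or params[i] > 1 - 1e-5
        ]
        bse = self._observed_info_se(params, nll)
        return MLResults(
            model=self,
            params=params,
            bse=bse,
            llf=-float(res.fun),
            converged=bool(res.success),
            at_boundary=at_boundary,
        )

    @staticmethod
    def _observed_info_se(x: np.ndarray, nll, h: float = 1e-5) -> np.ndarray:
        """SEs from a central-difference Hessian of the negative
        log-likelihood; NaN where the information is singular or the
        parameter sits on the boundary."""
        hess = np.empty((K, K))
        x = np.clip(x, 2 * h, 1 - 2 * h)
        f0 = nll(x)
        for i in range(K):
            for j in range(i, K):
                ei = np.zeros(K); ei[i] = h
                ej = np.zeros(K); ej[j] = h
                if i == j:
                    val = (nll(x + ei) - 2 * f0 + nll(x - ei)) / h**2
                else:
                    val = (
                        nll(x + ei + ej) - nll(x + ei - ej)
                        - nll(x - ei + ej) + nll(x - ei - ej)
                    ) / (4 * h**2)
                hess[i, j] = hess[j, i] = val
        try:
            cov = np.linalg.inv(hess)
            var = np.diag(cov).copy()
            var[var < 0] = np.nan
            return np.sqrt(var)
        except np.linalg.LinAlgError:
            return np.full(K, np.nan)

    # ------------------------------------------------------------------
    def fit_bayes(
        self,
        prior: PriorConfig | None = None,
        mcmc: McmcConfig | None = None,
        seed: int = 0,
    ):
        """Hierarchical latent-trait fit; see :class:`dualrec.bayes.HierarchicalResults`."""
        from .bayes import HierarchicalResults, PosteriorSamples

        if self.nobs < 2:
            raise ValueError("hierarchical fit requires at least 2 participants")
        prior = prior or PriorConfig()
        mcmc = mcmc or McmcConfig()
        if mcmc.chains < 2:
            raise ValueError("at least 2 chains are required for convergence checks")
        draws = run_chains(self.yes, self.n, self.design, prior, mcmc, seed)
        samples = PosteriorSamples(
            mu=draws["mu"],
            sigma=draws["sigma"],
            alpha=draws["alpha"],
            participant_ids=list(self.participant_ids),
            seed=seed,
            prior=prior,
            mcmc=mcmc,
        )
        return HierarchicalResults(model=self, samples=samples)


class MLResults:
    """Aggregate (pooled) maximum-likelihood estimates with SEs."""

    def __init__(self, model, params, bse, llf, converged, at_boundary):
        self.model = model
        self.params = np.asarray(params, float)
        self.bse = np.asarray(bse, float)
        self.llf = llf
        self.converged = converged
        self.at_boundary = list(at_boundary)

    @property
    def theta(self) -> ParameterVector:
        return ParameterVector.from_array(self.params)

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=list(PARAM_NAMES), name="estimate")

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_low": stats.norm.ppf(0.025, self.params, self.bse),
                "ci_high": stats.norm.ppf(0.975, self.params, self.bse),
            },
            index=list(PARAM_NAMES),
        )
        df["ci_low"] = df["ci_low"].clip(lower=0.0)
        df["ci_high"] = df["ci_high"].clip(upper=1.0)
        df["at_boundary"] = [n in self.at_boundary for n in PARAM_NAMES]
        return df

    def __repr__(self) -> str:
        flag = "" if not self.at_boundary else f", boundary={self.at_boundary}"
        return (
            f"<MLResults llf={self.llf:.2f} converged={self.converged}{flag}>"
        )
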