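"""Synthetic participants and response counts.

The generator mirrors the hierarchy the analysis assumes: participant i's
parameter vector is Phi(mu + delta_i) elementwise, with probit-scale group
means mu and individual deviations delta_i ~ MVN(0, Sigma); responses are
binomial per design cell at the tree probabilities.

Presets reproduce the two value-directed-remembering experiments the
package targets: a within-subject important/unimportant study (48
participants, 9 cells: targets 6 trials per cell, distractors 12) and a
between-subject truth/falsity prioritization study (36 or 38 participants
per group, 12 cells of 6 trials).  Preset group means are the studies'
published group-level parameter estimates, so simulated data live at a
realistic operating point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .design import DesignSpec, ResponseCounts, make_design
from .params import PARAM_NAMES, ParameterVector
from .trees import cell_probabilities

__all__ = [
    "GroupHyperparameters",
    "SimulationConfig",
    "sample_participants",
    "simulate_counts",
    "experiment1_preset",
    "experiment2_preset",
    "simulate_experiment",
]

K = len(PARAM_NAMES)

#: default probit-scale SD of individual deviations (diagonal Sigma);
#: produces visible but moderate heterogeneity between participants
DEFAULT_PROBIT_SD = 0.4

# published group-mean estimates used as generating truths
_EXP1_MEANS = dict(
    RC_A=0.62, RC_B=0.35, RT_A=0.52, RT_B=0.26,
    F_A=0.22, F_B=0.10, b_A=0.01, b_B=0.05, b_AB=0.02,
)
_EXP2_MEANS = {
    # contexts: A = Truth, B = Falsity
    "true_prioritized": dict(
        RC_A=0.75, RC_B=0.51, RT_A=0.33, RT_B=0.20,
        F_A=0.35, F_B=0.22, b_A=0.05, b_B=0.09, b_AB=0.03,
    ),
    "false_prioritized": dict(
        RC_A=0.50, RC_B=0.59, RT_A=0.31, RT_B=0.30,
        F_A=0.17, F_B=0.14, b_A=0.09, b_B=0.02, b_AB=0.03,
    ),
}


@dataclass(frozen=True)
class GroupHyperparameters:
    """Probit-scale group means and covariance of individual deviations."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != (K,):
            raise ValueError(f"mu must have shape ({K},)")
        if sigma.shape != (K, K):
            raise ValueError(f"sigma must have shape ({K}, {K})")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        eig = np.linalg.eigvalsh(sigma)
        if eig.min() < -1e-10:
            raise ValueError("sigma must be positive semidefinite")

    @classmethod
    def from_probability_means(
        cls, means, probit_sd: float | np.ndarray = DEFAULT_PROBIT_SD
    ) -> "GroupHyperparameters":
        """Build hyperparameters from probability-scale means and a
        diagonal probit-scale SD (scalar or per-parameter)."""
        if isinstance(means, ParameterVector):
            m = means.to_array()
        elif isinstance(means, dict):
            m = np.array([means[n] for n in PARAM_NAMES], float)
        else:
            m = np.asarray(means, float)
        sd = np.broadcast_to(np.asarray(probit_sd, float), (K,))
        return cls(mu=norm.ppf(m), sigma=np.diag(sd**2))

    @property
    def probability_means(self) -> np.ndarray:
        """Phi(mu): the probability-scale location of the group."""
        return norm.cdf(self.mu)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate one synthetic dataset."""

    design: DesignSpec
    hyper: GroupHyperparameters
    n_participants: int
    seed: int
    label: str = "sim"

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": int(self.seed),
            "n_participants": int(self.n_participants),
            "design": {
                "context_names": dict(self.design.context_names),
                "distractor_classes": self.design.distractor_classes,
                "n_per_cell": {k: int(v) for k, v in self.design.n_per_cell.items()},
                "n_participants": self.design.n_participants,
            },
            "hyper": {
                "mu": self.hyper.mu.tolist(),
                "sigma": self.hyper.sigma.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        dd = d["design"]
        design = DesignSpec(
            context_names=dd["context_names"],
            distractor_classes=dd["distractor_classes"],
            n_per_cell=dd["n_per_cell"],
            n_participants=dd.get("n_participants", 0),
        )
        hyper = GroupHyperparameters(
            mu=np.array(d["hyper"]["mu"], float),
            sigma=np.array(d["hyper"]["sigma"], float),
        )
        return cls(
            design=design,
            hyper=hyper,
            n_participants=d["n_participants"],
            seed=d["seed"],
            label=d.get("label", "sim"),
        )

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


def sample_participants(
    hyper: GroupHyperparameters, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n participant parameter vectors, shape (n, 9), probability scale.

    Participant s-th parameter is Phi(mu_s + delta_s), delta ~ MVN(0, sigma).
    """
    rng = np.random.default_rng(seed)
    delta = rng.multivariate_normal(
        np.zeros(K), hyper.sigma, size=n, method="eigh"
    )
    return norm.cdf(hyper.mu[None, :] + delta)


def simulate_counts(
    thetas, design: DesignSpec, seed: int | np.random.Generator
) -> list[ResponseCounts]:
    """Binomial counts per participant and cell at the tree probabilities."""
    rng = np.random.default_rng(seed)
    th = np.asarray(
        [t.to_array() if isinstance(t, ParameterVector) else t for t in thetas],
        dtype=float,
    )
    probs = cell_probabilities(th, design)  # (n, C)
    ns = np.array([design.n_per_cell[k] for k in design.cell_keys], int)
    yes = rng.binomial(ns[None, :], probs)
    out = []
    for i in range(th.shape[0]):
        cells = {
            k: (int(yes[i, j]), int(ns[j]))
            for j, k in enumerate(design.cell_keys)
        }
        out.append(ResponseCounts(participant_id=f"p{i + 1:03d}", counts=cells))
    return out


def experiment1_preset(seed: int = 0) -> SimulationConfig:
    """Within-subject important/unimportant design: 48 participants,
    9 cells; 36 targets (6 per target cell) and 36 distractors (12 per
    distractor cell); generating means at the published estimates."""
    design = make_design(
        distractor_classes=1,
        n_target=6,
        n_distractor=12,
        context_names={"A": "Important", "B": "Unimportant"},
        n_participants=48,
    )
    hyper = GroupHyperparameters.from_probability_means(_EXP1_MEANS)
    return SimulationConfig(
        design=design, hyper=hyper, n_participants=48, seed=seed, label="exp1"
    )


def experiment2_preset(condition: str, seed: int = 0) -> SimulationConfig:
    """Between-subject truth/falsity prioritization design: 12 cells of 6
    trials; 36 (true-prioritized) or 38 (false-prioritized) participants."""
    if condition not in _EXP2_MEANS:
        raise ValueError(
            "condition must be 'true_prioritized' or 'false_prioritized'"
        )
    n = 36 if condition == "true_prioritized" else 38
    design = make_design(
        distractor_classes=2,
        n_target=6,
        n_distractor=6,
        context_names={"A": "Truth", "B": "Falsity"},
        n_participants=n,
    )
    hyper = GroupHyperparameters.from_probability_means(_EXP2_MEANS[condition])
    return SimulationConfig(
        design=design, hyper=hyper, n_participants=n, seed=seed, label=condition
    )


def simulate_experiment(config: SimulationConfig):
    """Sample participants then counts; returns (thetas, counts).

    Independent child seeds for the two stages are derived from the config
    seed, so the counts stream does not alias the parameter stream.
    """
    ss = np.random.SeedSequence(config.seed)
    s_theta, s_counts = ss.spawn(2)
    thetas = sample_participants(
        config.hyper, config.n_participants, np.random.default_rng(s_theta)
    )
    counts = simulate_counts(thetas, config.design, np.random.default_rng(s_counts))
    return thetas, counts
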