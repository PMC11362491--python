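"""Descriptive and classical inferential statistics for recognition data.

Corrected acceptance rates (CAR = hit rate minus false-alarm rate on the
same probe) summarize raw performance alongside the model-based analysis.
The classical tests mirror a standard recognition-memory results section:
paired t with Cohen's d, Wilcoxon signed-rank with the rank-biserial
correlation, and a 2 (within) x 2 (between) mixed ANOVA with partial eta
squared, optionally on arcsine-transformed rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, ItemClass, ProbeType, cell_key

__all__ = [
    "TestResult",
    "corrected_acceptance_rates",
    "default_car_contrasts",
    "paired_t_and_d",
    "wilcoxon_signed_rank",
    "mixed_anova_2x2",
    "arcsine_transform",
    "car_to_unit",
    "plot_car_means",
]


@dataclass
class TestResult:
    """One classical test: statistic, degrees of freedom, p, effect size."""

    name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_value: float
    effect_size: float
    effect_name: str
    note: str = ""

    def to_row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            self.effect_name: self.effect_size,
            "note": self.note,
        }


# ----------------------------------------------------------------------
# corrected acceptance rates

def default_car_contrasts(design: DesignSpec) -> list[tuple[str, ProbeType, ItemClass, ItemClass]]:
    """One contrast per (probe, target class): hit cell vs the same-probe
    distractor cell (the same-context distractor class when there are two)."""
    contrasts = []
    for probe in (ProbeType.ask_A, ProbeType.ask_B, ProbeType.ask_A_or_B):
        for target in (ItemClass.target_A, ItemClass.target_B):
            if design.distractor_classes == 1:
                dist = ItemClass.distractor
            else:
                dist = (
                    ItemClass.distractor_A
                    if target == ItemClass.target_A
                    else ItemClass.distractor_B
                )
            label = f"{target.value}@{probe.value}"
            contrasts.append((label, probe, target, dist))
    return contrasts


def corrected_acceptance_rates(
    counts, design: DesignSpec, contrasts=None
) -> pd.DataFrame:
    """Per-participant CAR table, one column per contrast.

    CAR = yes-rate on the target cell minus yes-rate on the distractor cell
    of the same probe; cells with zero trials yield NaN (flagged missing,
    never silently zero).
    """
    contrasts = contrasts or default_car_contrasts(design)
    rows = {}
    for c in counts:
        vals = {}
        for label, probe, target, dist in contrasts:
            hy, hn = c.counts[cell_key(probe, target)]
            fy, fn = c.counts[cell_key(probe, dist)]
            if hn == 0 or fn == 0:
                vals[label] = np.nan
            else:
                vals[label] = hy / hn - fy / fn
        rows[c.participant_id] = vals
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant"
    return df


# ----------------------------------------------------------------------
# classical tests

def paired_t_and_d(x, y) -> TestResult:
    """Paired-samples t test with Cohen's d for dependent samples
    (mean difference over SD of differences)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        stat = 0.0 if d.mean() == 0.0 else np.copysign(np.inf, d.mean())
        return TestResult(
            "paired_t", stat, float(n - 1),
            p_value=np.nan if stat == 0.0 else 0.0,
            effect_size=np.nan, effect_name="cohen_d",
            note="zero difference variance",
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(
        "paired_t", float(t), float(n - 1), float(p),
        effect_size=float(d.mean() / sd), effect_name="cohen_d",
    )


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank test with the rank-biserial correlation.

    W is the positive-rank sum (zeros dropped, midranks for ties);
    r_rb = (W+ - W-) / (W+ + W-).  The p value is exact for n <= 25
    without ties, otherwise a continuity-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    r_rb = (w_pos - w_neg) / (w_pos + w_neg)
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) else "approx"
    res = stats.wilcoxon(d, correction=True, method=method)
    return TestResult(
        "wilcoxon_signed_rank", w_pos, None, float(res.pvalue),
        effect_size=float(r_rb), effect_name="r_rb",
        note=f"method={method}",
    )


def mixed_anova_2x2(values: pd.DataFrame, group) -> dict[str, TestResult]:
    """2 (within) x 2 (between) mixed ANOVA.

    ``values`` is a participant-indexed frame with exactly two columns (the
    within-subject levels); ``group`` assigns each participant to one of two
    groups.  Returns the within main effect, between main effect and their
    interaction, each with F, (df1, df2), p and partial eta squared.

    With two within levels the design decomposes exactly: subject means
    carry the between effect; difference scores carry the within effect and
    the interaction.  Main effects use unweighted (Type-III) cell means, so
    unequal group sizes are handled the way standard ANOVA software does.
    """
    if values.shape[1] != 2:
        raise ValueError("values must have exactly two within-level columns")
    group = pd.Series(group, index=values.index) if not isinstance(group, pd.Series) else group
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    if values.isna().any().any():
        raise ValueError("missing cells are not allowed")
    g_sizes = group.value_counts()
    if (g_sizes < 2).any():
        raise ValueError("each group needs at least 2 participants")

    y1 = values.iloc[:, 0].to_numpy(float)
    y2 = values.iloc[:, 1].to_numpy(float)
    m = (y1 + y2) / 2.0  # subject means -> between-subject part
    d = y1 - y2          # difference scores -> within-subject part
    g = group.to_numpy()
    n_tot = len(values)
    df2 = float(n_tot - 2)

    def _one_way_F(v):
        """One-way between-group ANOVA on v (2 groups)."""
        sse = 0.0
        ssb = 0.0
        means = []
        grand = 0.0
        for lev in levels:
            vi = v[g == lev]
            means.append(vi.mean())
            sse += ((vi - vi.mean()) ** 2).sum()
        grand = v.mean()
        for lev, mean_i in zip(levels, means):
            ni = (g == lev).sum()
            ssb += ni * (mean_i - grand) ** 2
        return ssb, sse

    def _result(name, ss_eff, ss_err):
        F = (ss_eff / 1.0) / (ss_err / df2)
        p = float(stats.f.sf(F, 1, df2))
        eta = ss_eff / (ss_eff + ss_err)
        return TestResult(
            name, float(F), (1.0, df2), p,
            effect_size=float(eta), effect_name="partial_eta_sq",
        )

    # between main effect: one-way ANOVA on subject means (x2 for the two
    # within observations per subject; F is scale-invariant)
    ssb_m, sse_m = _one_way_F(m)
    between = _result("between_main", 2.0 * ssb_m, 2.0 * sse_m)

    # within part: error is the within-group spread of difference scores
    sse_d = sum(((d[g == lev] - d[g == lev].mean()) ** 2).sum() for lev in levels)
    n1, n2 = (int((g == levels[0]).sum()), int((g == levels[1]).sum()))
    d1_bar, d2_bar = d[g == levels[0]].mean(), d[g == levels[1]].mean()

    # within main effect: unweighted mean of group difference-means vs 0
    c = (d1_bar + d2_bar) / 2.0
    ss_within = c**2 / (0.25 / n1 + 0.25 / n2)
    within = _result("within_main", ss_within / 2.0, sse_d / 2.0)

    # interaction: group difference in difference scores
    ss_inter = (d1_bar - d2_bar) ** 2 / (1.0 / n1 + 1.0 / n2)
    interaction = _result("interaction", ss_inter / 2.0, sse_d / 2.0)

    return {"within": within, "between": between, "interaction": interaction}


# ----------------------------------------------------------------------
# transforms

def arcsine_transform(p) -> np.ndarray | float:
    """Variance-stabilizing arcsine-square-root transform, asin(sqrt(p))."""
    arr = np.asarray(p, float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def plot_car_means(car_table: pd.DataFrame, ax=None):
    """Bar plot of mean CAR per contrast with standard-error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * car_table.shape[1] + 1, 4))
    means = car_table.mean()
    sems = car_table.sem()
    ax.bar(range(len(means)), means, yerr=sems, capsize=3, color="0.7",
           edgecolor="black")
    ax.set_xticks(range(len(means)))
    ax.set_xticklabels(means.index, rotation=45, ha="right")
    ax.set_ylabel("corrected acceptance rate")
    ax.axhline(0.0, color="black", lw=0.8)
    return ax


def car_to_unit(car) -> np.ndarray | float:
    """Shift a CAR from [-1, 1] into [0, 1] via (car + 1) / 2 so the
    arcsine transform applies."""
    arr = np.asarray(car, float)
    if np.any((arr < -1.0) | (arr > 1.0)):
        raise ValueError("CAR values must lie in [-1, 1]")
    out = (arr + 1.0) / 2.0
    return float(out) if np.isscalar(car) or arr.ndim == 0 else out
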