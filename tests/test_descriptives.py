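"""Corrected acceptance rates and the classical test battery."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import dualrec as dr

DESIGN1 = dr.make_design(1, n_target=6, n_distractor=12)


def _participant(pid, hits, fas, design=DESIGN1):
    cells = {}
    for k in design.cell_keys:
        probe, item = k.split(":")
        n = design.n_per_cell[k]
        cells[k] = (hits if "target" in item else fas, n)
    return dr.ResponseCounts(pid, cells)


# ----------------------------------------------------------------------
# corrected acceptance rates

def test_car_arithmetic():
    cells = {k: (0, DESIGN1.n_per_cell[k]) for k in DESIGN1.cell_keys}
    cells["ask_A:target_A"] = (5, 6)
    cells["ask_A:distractor"] = (1, 12)
    cells["ask_B:target_B"] = (3, 6)
    cells["ask_B:distractor"] = (6, 12)
    c = dr.ResponseCounts("p1", cells)
    car = dr.corrected_acceptance_rates([c], DESIGN1)
    assert car.loc["p1", "target_A@ask_A"] == pytest.approx(
        5 / 6 - 1 / 12, abs=1e-10
    )
    assert car.loc["p1", "target_B@ask_B"] == pytest.approx(0.0, abs=1e-10)

    perfect = dict(cells)
    perfect["ask_A:target_A"] = (6, 6)
    perfect["ask_A:distractor"] = (0, 12)
    car2 = dr.corrected_acceptance_rates(
        [dr.ResponseCounts("p2", perfect)], DESIGN1
    )
    assert car2.loc["p2", "target_A@ask_A"] == 1.0


def test_car_zero_trial_cell_is_flagged_missing():
    cells = {k: (0, DESIGN1.n_per_cell[k]) for k in DESIGN1.cell_keys}
    cells["ask_A:target_A"] = (0, 0)
    c = dr.ResponseCounts("p1", cells)
    car = dr.corrected_acceptance_rates([c], DESIGN1)
    assert math.isnan(car.loc["p1", "target_A@ask_A"])
    assert car.loc["p1", "target_B@ask_B"] == 0.0


def test_car_uses_same_context_distractor_in_two_class_designs():
    design2 = dr.make_design(2, n_target=6, n_distractor=6)
    contrasts = dr.default_car_contrasts(design2)
    by_label = {lab: (probe, tgt, dist) for lab, probe, tgt, dist in contrasts}
    assert by_label["target_A@ask_A"][2] == dr.ItemClass.distractor_A
    assert by_label["target_B@ask_B"][2] == dr.ItemClass.distractor_B


# ----------------------------------------------------------------------
# paired t / Cohen's d

def test_paired_t_pinned_and_edge_cases():
    x = np.array([2.0, 4.0, 6.0])
    y = np.array([1.0, 2.0, 3.0])  # differences 1, 2, 3
    r = dr.paired_t_and_d(x, y)
    assert r.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-10)
    assert r.df == 2
    assert r.effect_size == pytest.approx(2.0, abs=1e-10)

    same = dr.paired_t_and_d(x, x)
    assert same.statistic == 0.0 and same.note == "zero difference variance"

    const = dr.paired_t_and_d(x, x - 1.0)
    assert math.isinf(const.statistic) and const.statistic > 0


def test_paired_t_sign_equivariance():
    rng = np.random.default_rng(3)
    x, y = rng.random(20), rng.random(20)
    a = dr.paired_t_and_d(x, y)
    b = dr.paired_t_and_d(y, x)
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p_value == pytest.approx(b.p_value)
    assert a.effect_size == pytest.approx(-b.effect_size)


# ----------------------------------------------------------------------
# Wilcoxon signed rank

def test_wilcoxon_pinned_and_antisymmetry():
    x = np.array([1.0, 0.0, 3.0])
    y = np.array([0.0, 2.0, 0.0])  # differences 1, -2, 3
    r = dr.wilcoxon_signed_rank(x, y)
    assert r.statistic == 4.0  # ranks 1 + 3
    assert r.effect_size == pytest.approx(1 / 3, abs=1e-10)

    flipped = dr.wilcoxon_signed_rank(y, x)
    assert flipped.statistic == 2.0
    assert flipped.effect_size == pytest.approx(-1 / 3, abs=1e-10)
    assert flipped.p_value == pytest.approx(r.p_value)

    allpos = dr.wilcoxon_signed_rank(np.arange(1.0, 9.0), np.zeros(8))
    assert allpos.effect_size == 1.0

    with pytest.raises(ValueError, match="all differences are zero"):
        dr.wilcoxon_signed_rank(x, x)


def test_wilcoxon_matches_scipy_p_at_study_scale():
    rng = np.random.default_rng(8)
    x = rng.normal(0.3, 0.3, size=48)
    y = rng.normal(0.1, 0.3, size=48)
    r = dr.wilcoxon_signed_rank(x, y)
    from scipy.stats import wilcoxon as sp_wilcoxon
    ref = sp_wilcoxon(x - y, correction=True, method="approx")
    assert r.p_value == pytest.approx(ref.pvalue)


# ----------------------------------------------------------------------
# mixed ANOVA

def brute_force_mixed_ss(values: pd.DataFrame, group: pd.Series):
    """Textbook sums-of-squares decomposition for a balanced 2x2 mixed
    design, written directly from cell/subject means."""
    y = values.to_numpy(float)
    g = group.to_numpy()
    levels = pd.unique(g)
    N = len(y)
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    within_mean = y.mean(axis=0)

    ss_group = sum(
        2 * (g == lev).sum() * (y[g == lev].mean() - grand) ** 2 for lev in levels
    )
    ss_subj = sum(
        2 * (subj_mean[i] - y[g == g[i]].mean()) ** 2 for i in range(N)
    )
    ss_within = N * sum((within_mean[j] - grand) ** 2 for j in range(2))
    ss_inter = sum(
        (g == lev).sum() * (y[g == lev, j].mean() - y[g == lev].mean()
                            - within_mean[j] + grand) ** 2
        for lev in levels for j in range(2)
    )
    ss_err_within = sum(
        (y[i, j] - subj_mean[i] - y[g == g[i], j].mean() + y[g == g[i]].mean()) ** 2
        for i in range(N) for j in range(2)
    )
    return {
        "F_between": (ss_group / 1) / (ss_subj / (N - 2)),
        "F_within": (ss_within / 1) / (ss_err_within / (N - 2)),
        "F_inter": (ss_inter / 1) / (ss_err_within / (N - 2)),
    }


@pytest.fixture
def anova_fixture():
    values = pd.DataFrame(
        {
            "lvl1": [0.80, 0.65, 0.72, 0.91, 0.55, 0.60, 0.47, 0.66],
            "lvl2": [0.42, 0.50, 0.38, 0.61, 0.52, 0.58, 0.50, 0.68],
        },
        index=[f"p{i}" for i in range(8)],
    )
    group = pd.Series(["g1"] * 4 + ["g2"] * 4, index=values.index)
    return values, group


def test_mixed_anova_matches_brute_force(anova_fixture):
    values, group = anova_fixture
    res = dr.mixed_anova_2x2(values, group)
    ref = brute_force_mixed_ss(values, group)
    assert res["between"].statistic == pytest.approx(ref["F_between"], abs=1e-10)
    assert res["within"].statistic == pytest.approx(ref["F_within"], abs=1e-10)
    assert res["interaction"].statistic == pytest.approx(ref["F_inter"], abs=1e-10)
    for r in res.values():
        assert r.df == (1.0, 6.0)
        # partial eta^2 consistent with F and dfs when df1 = 1
        assert r.effect_size == pytest.approx(
            r.statistic / (r.statistic + 6.0), abs=1e-10
        )


def test_mixed_anova_agrees_with_pingouin(anova_fixture):
    values, group = anova_fixture
    res = dr.mixed_anova_2x2(values, group)
    long = values.reset_index(names="subject").melt(
        id_vars="subject", var_name="within", value_name="dv"
    )
    long["group"] = long["subject"].map(dict(zip(values.index, group)))
    ref = pg.mixed_anova(
        data=long, dv="dv", within="within", subject="subject", between="group"
    ).set_index("Source")
    assert res["between"].statistic == pytest.approx(ref.loc["group", "F"], rel=1e-6)
    assert res["within"].statistic == pytest.approx(ref.loc["within", "F"], rel=1e-6)
    assert res["interaction"].statistic == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-6
    )


def test_mixed_anova_null_between_effect():
    # identical data in both groups: the between effect vanishes
    base = pd.DataFrame(
        {"lvl1": [0.5, 0.7, 0.3, 0.6], "lvl2": [0.4, 0.55, 0.28, 0.5]}
    )
    values = pd.concat([base, base], ignore_index=True)
    group = pd.Series(["a"] * 4 + ["b"] * 4)
    res = dr.mixed_anova_2x2(values, group)
    assert res["between"].statistic == pytest.approx(0.0, abs=1e-12)
    assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-12)

    # with equal group difference-means, F_within = t^2 * (N-2)/(N-1)
    t = dr.paired_t_and_d(values["lvl1"], values["lvl2"])
    N = len(values)
    assert res["within"].statistic == pytest.approx(
        t.statistic**2 * (N - 2) / (N - 1), abs=1e-10
    )


def test_mixed_anova_validation():
    values = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
    with pytest.raises(ValueError, match="two groups"):
        dr.mixed_anova_2x2(values, pd.Series(["g1", "g1"]))
    with pytest.raises(ValueError, match="at least 2"):
        dr.mixed_anova_2x2(
            pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 2.0]}),
            pd.Series(["g1", "g1", "g2"]),
        )


# ----------------------------------------------------------------------
# transforms

def test_arcsine_transform_values():
    assert dr.arcsine_transform(0.0) == 0.0
    assert dr.arcsine_transform(1.0) == pytest.approx(math.pi / 2)
    assert dr.arcsine_transform(0.25) == pytest.approx(math.pi / 6, abs=1e-12)
    with pytest.raises(ValueError):
        dr.arcsine_transform(1.2)
    assert dr.car_to_unit(-1.0) == 0.0 and dr.car_to_unit(1.0) == 1.0
    with pytest.raises(ValueError):
        dr.car_to_unit(1.5)


def test_car_invariant_to_common_count_scaling():
    """CARs depend only on rates: scaling all trial counts while keeping
    rates fixed leaves the table unchanged."""
    cells = {k: (0, DESIGN1.n_per_cell[k]) for k in DESIGN1.cell_keys}
    cells["ask_A:target_A"] = (3, 6)
    cells["ask_A:distractor"] = (2, 12)
    small = dr.ResponseCounts("p", cells)
    big_design = dr.make_design(1, n_target=18, n_distractor=36)
    big_cells = {k: (3 * yes, 3 * n) for k, (yes, n) in cells.items()}
    big = dr.ResponseCounts("p", big_cells)
    a = dr.corrected_acceptance_rates([small], DESIGN1)
    b = dr.corrected_acceptance_rates([big], big_design)
    pd.testing.assert_frame_equal(a, b)
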