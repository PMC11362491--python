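"""Tree probabilities, likelihood and the algebraic moment estimator."""

import math

import numpy as np
import pytest

import dualrec as dr
from dualrec.design import ItemClass, ProbeType
from conftest import random_thetas

EXP1 = dr.make_design(1, n_target=6, n_distractor=12)
EXP2 = dr.make_design(2, n_target=6, n_distractor=6)


# ----------------------------------------------------------------------
# independent oracle: explicit leaf enumeration of each processing tree

def tree_leaves(theta: dr.ParameterVector, probe, item):
    """All (path probability, outcome) leaves of one probe x item tree,
    written out branch by branch, independently of the implementation."""
    b = {"ask_A": theta.b_A, "ask_B": theta.b_B, "ask_A_or_B": theta.b_AB}[probe]
    if not ItemClass(item).studied:
        return [(b, "yes"), (1 - b, "no")]
    ctx = "A" if item == "target_A" else "B"
    rc = theta.RC_A if ctx == "A" else theta.RC_B
    rt = theta.RT_A if ctx == "A" else theta.RT_B
    f = theta.F_A if ctx == "A" else theta.F_B
    if probe == "ask_A_or_B":
        return [
            (rc, "yes"),
            ((1 - rc) * rt, "yes"),
            ((1 - rc) * (1 - rt) * f, "yes"),
            ((1 - rc) * (1 - rt) * (1 - f) * b, "yes"),
            ((1 - rc) * (1 - rt) * (1 - f) * (1 - b), "no"),
        ]
    consistent = (probe == "ask_A") == (ctx == "A")
    leaves = [
        (rc, "yes" if consistent else "no"),
        ((1 - rc) * rt, "yes"),
        ((1 - rc) * (1 - rt) * b, "yes"),
        ((1 - rc) * (1 - rt) * (1 - b), "no"),
    ]
    return leaves


def leaf_yes_probability(theta, probe, item):
    return sum(p for p, o in tree_leaves(theta, probe, item) if o == "yes")


# ----------------------------------------------------------------------
# yes_probability

@pytest.mark.parametrize(
    "updates, probe, item, expected",
    [
        # context recollection forces acceptance on the consistent probe
        (dict(RC_A=1.0), "ask_A", "target_A", 1.0),
        # ... and rejection on the inconsistent probe
        (dict(RC_A=1.0), "ask_B", "target_A", 0.0),
        # hand arithmetic of the three-branch consistent-probe formula
        (dict(RC_A=0.62, RT_A=0.52, b_A=0.01), "ask_A", "target_A",
         0.62 + 0.38 * 0.52 + 0.38 * 0.48 * 0.01),
        # distractor acceptance is the probe bias alone
        (dict(b_AB=0.02), "ask_A_or_B", "distractor", 0.02),
    ],
)
def test_yes_probability_pinned(updates, probe, item, expected):
    base = dict(RC_A=0.3, RC_B=0.3, RT_A=0.4, RT_B=0.4, F_A=0.2, F_B=0.2,
                b_A=0.05, b_B=0.05, b_AB=0.05)
    base.update(updates)
    theta = dr.ParameterVector(**base)
    assert dr.yes_probability(theta, probe, item) == pytest.approx(expected, abs=1e-10)


def test_yes_probability_rejects_items_outside_design():
    theta = dr.ParameterVector(*[0.3] * 9)
    with pytest.raises(ValueError, match="not part of this design"):
        dr.yes_probability(theta, "ask_A", "distractor_A", design=EXP1)


def test_trees_match_leaf_enumeration_and_normalize():
    """Yes-probabilities equal the sum of yes-leaves, and all leaf paths of
    every tree sum to one, over a grid plus random parameter draws."""
    rng = np.random.default_rng(7)
    grid = [0.0, 0.25, 0.5, 1.0]
    draws = [random_thetas(1, rng)[0] for _ in range(200)]
    corners = [np.full(9, g) for g in grid]
    for arr in draws + corners:
        theta = dr.ParameterVector.from_array(arr)
        for probe, item in EXP2.cells + EXP1.cells:
            leaves = tree_leaves(theta, probe.value, item.value)
            assert sum(p for p, _ in leaves) == pytest.approx(1.0, abs=1e-12)
            assert dr.yes_probability(theta, probe, item) == pytest.approx(
                leaf_yes_probability(theta, probe.value, item.value), abs=1e-12
            )


def test_monotonicity_in_memory_parameters():
    """Consistent/old probes are nondecreasing in RC, RT (and F for old);
    the inconsistent probe is nonincreasing in RC."""
    rng = np.random.default_rng(13)
    th = random_thetas(300, rng)
    for idx, probe, item, sign in [
        (0, "ask_A", "target_A", +1),   # RC_A on consistent
        (2, "ask_A", "target_A", +1),   # RT_A on consistent
        (0, "ask_A_or_B", "target_A", +1),
        (2, "ask_A_or_B", "target_A", +1),
        (4, "ask_A_or_B", "target_A", +1),  # F_A on old probe
        (0, "ask_B", "target_A", -1),   # RC_A on inconsistent
    ]:
        bumped = th.copy()
        bumped[:, idx] = np.minimum(bumped[:, idx] + 0.05, 1.0)
        p0 = np.array([dr.yes_probability(t, probe, item) for t in th])
        p1 = np.array([dr.yes_probability(t, probe, item) for t in bumped])
        assert np.all(sign * (p1 - p0) >= -1e-12)


# ----------------------------------------------------------------------
# cell tables

def test_cell_table_shapes_and_distractor_symmetry():
    theta = dr.ParameterVector(0.5, 0.35, 0.4, 0.26, 0.3, 0.1, 0.01, 0.05, 0.02)
    t1 = dr.cell_probability_table(theta, EXP1)
    assert len(t1) == 9
    t2 = dr.cell_probability_table(theta, EXP2)
    assert len(t2) == 12
    for probe in ("ask_A", "ask_B", "ask_A_or_B"):
        assert t2[f"{probe}:distractor_A"] == t2[f"{probe}:distractor_B"]
    zero = dr.ParameterVector(*[0.0] * 9)
    assert all(v == 0.0 for v in dr.cell_probability_table(zero, EXP1).values())


# ----------------------------------------------------------------------
# likelihood

def test_log_likelihood_values():
    theta = dr.ParameterVector(0.62, 0.35, 0.52, 0.26, 0.22, 0.10, 0.01, 0.05, 0.02)
    p_aa = dr.yes_probability(theta, "ask_A", "target_A")
    empty = dr.ResponseCounts("p1", {k: (0, 0) for k in EXP1.cell_keys})
    assert dr.log_likelihood(theta, empty, EXP1) == 0.0

    one = dr.ResponseCounts(
        "p2",
        {k: ((1, 1) if k == "ask_A:target_A" else (0, 0)) for k in EXP1.cell_keys},
    )
    assert dr.log_likelihood(theta, one, EXP1) == pytest.approx(math.log(p_aa), abs=1e-10)

    # a certain cell observed as certain contributes zero
    sure = dr.ParameterVector(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    hit = dr.ResponseCounts(
        "p3",
        {k: ((4, 4) if k == "ask_A:target_A" else (0, 0)) for k in EXP1.cell_keys},
    )
    assert dr.log_likelihood(sure, hit, EXP1) == pytest.approx(0.0, abs=1e-12)

    with pytest.raises(ValueError, match="do not match"):
        dr.log_likelihood(theta, dr.ResponseCounts("p4", {"ask_A:target_A": (0, 1)}), EXP1)


# ----------------------------------------------------------------------
# moment estimator

def test_moment_estimator_pinned_round_trip():
    theta = dr.ParameterVector(0.5, 0.35, 0.4, 0.26, 0.3, 0.1, 0.01, 0.05, 0.02)
    rates = dr.cell_probability_table(theta, EXP1)
    est = dr.moment_estimator(rates, EXP1)
    assert est.clean
    np.testing.assert_allclose(est.theta.to_array(), theta.to_array(), atol=1e-10)


def test_moment_estimator_table_values_round_trip():
    # published posterior means as the seed of a forward/backward trip
    theta = dr.ParameterVector(0.62, 0.35, 0.52, 0.26, 0.22, 0.10, 0.01, 0.05, 0.02)
    for design in (EXP1, EXP2):
        rates = dr.cell_probability_table(theta, design)
        est = dr.moment_estimator(rates, design)
        np.testing.assert_allclose(est.theta.to_array(), theta.to_array(), atol=1e-10)


def test_moment_estimator_zero_rates():
    rates = {k: 0.0 for k in EXP1.cell_keys}
    est = dr.moment_estimator(rates, EXP1)
    assert est.theta.to_array()[:4].tolist() == [0.0, 0.0, 0.0, 0.0]
    assert not est.out_of_range


def test_moment_estimator_flags_degenerate_rc_one():
    # a perfect consistent-probe rate with zero inconsistent acceptance
    # implies RC=1, leaving RT and F unidentified: flagged, not silently
    # clamped
    rates = {k: 0.0 for k in EXP1.cell_keys}
    rates["ask_A:target_A"] = 1.0
    est = dr.moment_estimator(rates, EXP1)
    assert est.theta.RC_A == 1.0
    assert "RT_A" in est.degenerate
    assert "F_A" in est.degenerate


def test_moment_estimator_flags_out_of_range():
    # a low consistent rate with a very high inconsistent rate implies
    # P(RC fails) > 1: the algebraic RC leaves [0, 1] and is flagged
    rates = {k: 0.0 for k in EXP1.cell_keys}
    rates["ask_A:target_A"] = 0.2
    rates["ask_B:target_A"] = 0.9
    rates["ask_A_or_B:target_A"] = 0.5
    est = dr.moment_estimator(rates, EXP1)
    assert "RC_A" in est.out_of_range
    assert est.theta.RC_A == 0.0  # clamped
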