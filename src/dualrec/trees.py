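"""Processing trees of the dual-recollection model.

Each (probe, item-class) cell is a binary tree whose "yes" probability is a
polynomial in the nine parameters:

* consistent context probe (probe matches the target's study context c):
  ``RC_c + (1-RC_c)*RT_c + (1-RC_c)*(1-RT_c)*b``
* inconsistent context probe (probe names the other context): context
  recollection forces rejection, so ``(1-RC_c)*RT_c + (1-RC_c)*(1-RT_c)*b``
* old probe ("A or B?"): familiarity joins recollection,
  ``RC_c + (1-RC_c)*RT_c + (1-RC_c)*(1-RT_c)*F_c
  + (1-RC_c)*(1-RT_c)*(1-F_c)*b_AB``
* distractors (any class): the probe's bias ``b`` alone.

This module also provides the binomial likelihood over cells and an exact
algebraic moment estimator that inverts the trees, used throughout the test
suite as an oracle independent of the samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignSpec, ItemClass, ProbeType, ResponseCounts, cell_key
from .params import PARAM_NAMES, ParameterVector

__all__ = [
    "yes_probability",
    "cell_probabilities",
    "cell_probability_table",
    "log_likelihood",
    "moment_estimator",
    "MomentEstimate",
]

# fixed parameter positions, matching PARAM_NAMES
_RC = {"A": 0, "B": 1}
_RT = {"A": 2, "B": 3}
_F = {"A": 4, "B": 5}
_BIAS = {ProbeType.ask_A: 6, ProbeType.ask_B: 7, ProbeType.ask_A_or_B: 8}


def _target_context(item: ItemClass) -> str:
    return "A" if item == ItemClass.target_A else "B"


def _cell_prob(theta: np.ndarray, probe: ProbeType, item: ItemClass) -> np.ndarray:
    """Yes-probability of one cell; theta has shape (..., 9)."""
    th = np.asarray(theta, dtype=float)
    b = th[..., _BIAS[probe]]
    if not ItemClass(item).studied:
        return b
    c = _target_context(ItemClass(item))
    rc = th[..., _RC[c]]
    rt = th[..., _RT[c]]
    no_rec = (1.0 - rc) * (1.0 - rt)
    if probe == ProbeType.ask_A_or_B:
        f = th[..., _F[c]]
        return rc + (1.0 - rc) * rt + no_rec * f + no_rec * (1.0 - f) * b
    if (probe == ProbeType.ask_A) == (c == "A"):  # consistent
        return rc + (1.0 - rc) * rt + no_rec * b
    return (1.0 - rc) * rt + no_rec * b  # inconsistent


def yes_probability(theta, probe, item, design: DesignSpec | None = None) -> float:
    """Probability of a "yes" response for one (probe, item-class) cell.

    Parameters may be a :class:`ParameterVector` or a length-9 array in
    canonical order.  When ``design`` is given, the item class is validated
    against it.
    """
    probe = ProbeType(probe)
    item = ItemClass(item)
    if design is not None:
        design.validate_item(item)
    arr = theta.to_array() if isinstance(theta, ParameterVector) else np.asarray(theta, float)
    return float(_cell_prob(arr, probe, item))


def cell_probabilities(theta, design: DesignSpec) -> np.ndarray:
    """Vectorized yes-probabilities for every design cell.

    ``theta`` has shape (..., 9); the result has shape (..., n_cells) with
    cells ordered as ``design.cells``.
    """
    th = np.asarray(
        theta.to_array() if isinstance(theta, ParameterVector) else theta, float
    )
    cols = [_cell_prob(th, p, i) for p, i in design.cells]
    return np.stack(cols, axis=-1)


def cell_probability_table(theta, design: DesignSpec) -> dict[str, float]:
    """Yes-probability per cell, keyed ``"probe:item"``."""
    probs = cell_probabilities(theta, design)
    return {k: float(v) for k, v in zip(design.cell_keys, probs)}


def log_likelihood(theta, counts: ResponseCounts, design: DesignSpec) -> float:
    """Independent-binomial log-likelihood of one participant's counts.

    Returns ``-inf`` only when a cell probability is exactly 0 or 1 and the
    observed counts contradict it.
    """
    if not counts.conforms_to(design):
        raise ValueError(
            f"counts of participant {counts.participant_id} do not match the "
            f"design cells"
        )
    table = cell_probability_table(theta, design)
    total = 0.0
    for key, p in table.items():
        yes, n = counts.counts[key]
        if n == 0:
            continue
        total += float(stats.binom.logpmf(yes, n, p))
    return total


@dataclass
class MomentEstimate:
    """Result of the algebraic tree inversion.

    ``theta`` holds the clamped estimates; ``out_of_range`` lists parameters
    whose algebraic solution left [0, 1] before clamping; ``degenerate``
    maps parameter names to a reason when the system could not be solved
    (the parameter is then set to the stated fallback).
    """

    theta: ParameterVector
    out_of_range: list[str] = field(default_factory=list)
    degenerate: dict[str, str] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.out_of_range and not self.degenerate


def _record(raw: float, name: str, out_of_range: list[str]) -> float:
    if raw < 0.0 or raw > 1.0:
        out_of_range.append(name)
    return float(min(1.0, max(0.0, raw)))


def moment_estimator(rates, design: DesignSpec) -> MomentEstimate:
    """Invert the trees algebraically: cell rates -> parameter estimates.

    The biases are read directly off the distractor cells (averaged over
    distractor classes in two-class designs).  Per context c, write
    ``u = 1 - RC_c``, ``v = u * RT_c``, ``w = u * (1 - RT_c)``; the
    consistent-probe rate gives ``w = (1 - p_con) / (1 - b_con)``, the
    inconsistent-probe rate gives ``v = p_inc - w * b_inc``, and the
    old-probe rate gives ``F_c = 1 - (1 - p_old) / (w * (1 - b_AB))``.
    The round trip ``moment_estimator(cell_probability_table(theta))``
    is exact on interior parameter vectors.
    """
    if isinstance(rates, np.ndarray):
        rates = dict(zip(design.cell_keys, np.asarray(rates, float)))
    missing = set(design.cell_keys) - set(rates)
    if missing:
        raise ValueError(f"rates missing design cells {sorted(missing)}")

    oor: list[str] = []
    degen: dict[str, str] = {}
    est: dict[str, float] = {}

    # biases from distractor cells
    if design.distractor_classes == 1:
        dist_items = [ItemClass.distractor]
    else:
        dist_items = [ItemClass.distractor_A, ItemClass.distractor_B]
    for probe, bname in [
        (ProbeType.ask_A, "b_A"),
        (ProbeType.ask_B, "b_B"),
        (ProbeType.ask_A_or_B, "b_AB"),
    ]:
        vals = [rates[cell_key(probe, it)] for it in dist_items]
        est[bname] = _record(float(np.mean(vals)), bname, oor)

    for ctx, item in [("A", ItemClass.target_A), ("B", ItemClass.target_B)]:
        con_probe = ProbeType.ask_A if ctx == "A" else ProbeType.ask_B
        inc_probe = ProbeType.ask_B if ctx == "A" else ProbeType.ask_A
        p_con = float(rates[cell_key(con_probe, item)])
        p_inc = float(rates[cell_key(inc_probe, item)])
        p_old = float(rates[cell_key(ProbeType.ask_A_or_B, item)])
        b_con = est["b_A" if ctx == "A" else "b_B"]
        b_inc = est["b_B" if ctx == "A" else "b_A"]
        b_old = est["b_AB"]

        rc_n, rt_n, f_n = f"RC_{ctx}", f"RT_{ctx}", f"F_{ctx}"
        if b_con >= 1.0:
            degen[rc_n] = "consistent-probe bias at 1: trees uninformative"
            est[rc_n], est[rt_n], est[f_n] = 0.0, 0.0, 0.0
            continue
        w = (1.0 - p_con) / (1.0 - b_con)  # P(neither RC nor RT)
        v = p_inc - w * b_inc  # P(RC fails, RT succeeds)
        u = v + w  # P(RC fails)
        est[rc_n] = _record(1.0 - u, rc_n, oor)
        if u <= 0.0:
            # RC_c = 1: RT unidentified; any residual inconsistent acceptance
            # contradicts the model
            if p_inc > 0.0:
                degen[rt_n] = (
                    "rates imply RC=1 yet inconsistent-probe acceptance is "
                    "nonzero"
                )
            else:
                degen[rt_n] = "RC=1 leaves RT unidentified"
            est[rt_n] = 0.0
        else:
            est[rt_n] = _record(v / u, rt_n, oor)
        if w <= 0.0 or b_old >= 1.0:
            degen[f_n] = "no recollection-failure mass: F unidentified"
            est[f_n] = 0.0
        else:
            est[f_n] = _record(1.0 - (1.0 - p_old) / (w * (1.0 - b_old)), f_n, oor)

    theta = ParameterVector(**{n: est[n] for n in PARAM_NAMES})
    return MomentEstimate(theta=theta, out_of_range=oor, degenerate=degen)
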