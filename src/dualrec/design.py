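"""Experimental design vocabulary for conjoint-recognition tests.

A conjoint-recognition test probes every item with one of three questions
("was it context A?", "was it context B?", "was it A or B, i.e. old at
all?").  Items are targets studied in one of two contexts, or unstudied
distractors.  A design enumerates the (probe, item-class) cells, the trial
count per cell, and the display names of the two contexts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "ProbeType",
    "ItemClass",
    "DesignSpec",
    "ResponseCounts",
    "PROBES",
    "cell_key",
]


class ProbeType(str, Enum):
    """The three test questions of the conjoint-recognition paradigm."""

    ask_A = "ask_A"
    ask_B = "ask_B"
    ask_A_or_B = "ask_A_or_B"


class ItemClass(str, Enum):
    """Test-item classes: targets carry a study context, distractors none.

    One-distractor-class designs use ``distractor``; two-class designs keep
    ``distractor_A``/``distractor_B`` as separate cells (the model assigns
    them identical probabilities, but observed frequencies can be checked
    separately).
    """

    target_A = "target_A"
    target_B = "target_B"
    distractor = "distractor"
    distractor_A = "distractor_A"
    distractor_B = "distractor_B"

    @property
    def studied(self) -> bool:
        return self in (ItemClass.target_A, ItemClass.target_B)


PROBES = (ProbeType.ask_A, ProbeType.ask_B, ProbeType.ask_A_or_B)


def cell_key(probe: ProbeType, item: ItemClass) -> str:
    """Canonical string key for a design cell, ``"probe:item"``."""
    return f"{ProbeType(probe).value}:{ItemClass(item).value}"


@dataclass(frozen=True)
class DesignSpec:
    """A conjoint-recognition design: cells, trial counts, context labels.

    Parameters
    ----------
    context_names : mapping
        Display names for the two study contexts, e.g.
        ``{"A": "Important", "B": "Unimportant"}``.
    distractor_classes : int
        1 (a single pooled distractor class; 9 cells) or 2 (context-labelled
        distractor classes; 12 cells).
    n_per_cell : mapping
        Trial count per cell key ``"probe:item"``; all strictly positive.
    n_participants : int
        Planned sample size (used by the simulator presets).
    """

    context_names: Mapping[str, str] = field(
        default_factory=lambda: {"A": "A", "B": "B"}
    )
    distractor_classes: int = 1
    n_per_cell: Mapping[str, int] = field(default_factory=dict)
    n_participants: int = 0

    def __post_init__(self) -> None:
        if self.distractor_classes not in (1, 2):
            raise ValueError("distractor_classes must be 1 or 2")
        expected = {cell_key(p, i) for p in PROBES for i in self.item_classes}
        got = set(self.n_per_cell)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"n_per_cell keys do not match the design cells; "
                f"missing={missing}, unexpected={extra}"
            )
        bad = [k for k, v in self.n_per_cell.items() if int(v) <= 0]
        if bad:
            raise ValueError(f"non-positive trial counts in cells {bad}")

    @property
    def item_classes(self) -> tuple[ItemClass, ...]:
        if self.distractor_classes == 1:
            return (ItemClass.target_A, ItemClass.target_B, ItemClass.distractor)
        return (
            ItemClass.target_A,
            ItemClass.target_B,
            ItemClass.distractor_A,
            ItemClass.distractor_B,
        )

    @property
    def cells(self) -> tuple[tuple[ProbeType, ItemClass], ...]:
        """All (probe, item-class) cells, probes varying slowest."""
        return tuple((p, i) for p in PROBES for i in self.item_classes)

    @property
    def cell_keys(self) -> tuple[str, ...]:
        return tuple(cell_key(p, i) for p, i in self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_n(self, probe: ProbeType, item: ItemClass) -> int:
        return int(self.n_per_cell[cell_key(probe, item)])

    def validate_item(self, item: ItemClass) -> None:
        if ItemClass(item) not in self.item_classes:
            raise ValueError(
                f"item class {ItemClass(item).value!r} is not part of this "
                f"design ({self.distractor_classes} distractor class(es))"
            )


def make_design(
    distractor_classes: int,
    n_target: int,
    n_distractor: int,
    context_names: Mapping[str, str] | None = None,
    n_participants: int = 0,
) -> DesignSpec:
    """Build a balanced design with uniform per-class cell sizes."""
    names = dict(context_names) if context_names else {"A": "A", "B": "B"}
    items: tuple[ItemClass, ...]
    if distractor_classes == 1:
        items = (ItemClass.target_A, ItemClass.target_B, ItemClass.distractor)
    else:
        items = (
            ItemClass.target_A,
            ItemClass.target_B,
            ItemClass.distractor_A,
            ItemClass.distractor_B,
        )
    n_per_cell = {
        cell_key(p, i): (n_target if i.studied else n_distractor)
        for p in PROBES
        for i in items
    }
    return DesignSpec(
        context_names=names,
        distractor_classes=distractor_classes,
        n_per_cell=n_per_cell,
        n_participants=n_participants,
    )


@dataclass
class ResponseCounts:
    """Per-participant yes/total counts for every design cell.

    ``counts`` maps cell key ``"probe:item"`` to ``(yes_count, n)``.
    """

    participant_id: str
    counts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for key, (yes, n) in self.counts.items():
            if not (0 <= yes <= n):
                raise ValueError(
                    f"participant {self.participant_id}: cell {key} has "
                    f"yes={yes} outside [0, n={n}]"
                )

    def conforms_to(self, design: DesignSpec) -> bool:
        return set(self.counts) == set(design.cell_keys)
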