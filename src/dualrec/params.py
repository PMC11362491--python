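"""Parameter vectors of the dual-recollection model.

The model has nine probability parameters: context recollection (RC),
target recollection (RT) and familiarity (F), each split by study context
A/B, plus one yes-guessing bias per probe type (b_A, b_B, b_AB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

__all__ = ["PARAM_NAMES", "ParameterVector"]

PARAM_NAMES = ("RC_A", "RC_B", "RT_A", "RT_B", "F_A", "F_B", "b_A", "b_B", "b_AB")


@dataclass(frozen=True)
class ParameterVector:
    """The nine latent probabilities for one participant or group mean.

    RC_c: probability of consciously retrieving the study context of a
    context-c target; RT_c: probability of retrieving the target itself;
    F_c: familiarity, an automatic old-signal that enters only the
    "A or B?" probe; b_A/b_B/b_AB: probability of guessing "yes" on each
    probe type when no memory process succeeded.
    """

    RC_A: float
    RC_B: float
    RT_A: float
    RT_B: float
    F_A: float
    F_B: float
    b_A: float
    b_B: float
    b_AB: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"parameter {f.name}={v} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "ParameterVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected shape ({len(PARAM_NAMES)},), got {a.shape}")
        return cls(**dict(zip(PARAM_NAMES, a.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d) -> "ParameterVector":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "ParameterVector":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
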