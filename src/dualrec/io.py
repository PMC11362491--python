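"""Canonical data formats: trial-level and counts-level CSV.

Trial-level schema (one row per probe trial)::

    participant_id, condition, item_id, item_class, probe, response

with ``item_class`` in {target_A, target_B, distractor, distractor_A,
distractor_B}, ``probe`` in {ask_A, ask_B, ask_A_or_B} and ``response``
yes/no.  Deposited datasets with other column names are ingested through a
user-supplied column mapping rather than guessed.  Pre-aggregated counts
(participant, probe, item_class, yes, n) are accepted as an alternative
input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DesignSpec, ItemClass, ProbeType, ResponseCounts, cell_key

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "aggregate_counts",
    "counts_to_frame",
    "counts_from_frame",
    "read_counts",
    "write_counts",
    "trials_from_counts",
]

TRIAL_COLUMNS = (
    "participant_id", "condition", "item_id", "item_class", "probe", "response",
)
_VALID_ITEMS = {i.value for i in ItemClass}
_VALID_PROBES = {p.value for p in ProbeType}
_VALID_RESPONSES = {"yes", "no"}


def read_trials(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    ``column_map`` maps canonical names to the file's column names for
    deposits using a different header.  Malformed rows raise a ValueError
    listing the offending line numbers (1-based, header excluded).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns {sorted(missing)}")
    df = df[list(TRIAL_COLUMNS)]

    bad: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        if row.item_class not in _VALID_ITEMS:
            bad.append(f"line {idx}: unknown item_class {row.item_class!r}")
        if row.probe not in _VALID_PROBES:
            bad.append(f"line {idx}: unknown probe {row.probe!r}")
        if row.response not in _VALID_RESPONSES:
            bad.append(f"line {idx}: unknown response {row.response!r}")
    if bad:
        head = "; ".join(bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise ValueError(f"malformed trial rows: {head}{more}")

    dup = df.duplicated(subset=["participant_id", "item_id"])
    if dup.any():
        lines = (np.flatnonzero(dup.to_numpy()) + 1).tolist()[:10]
        raise ValueError(
            f"duplicate (participant, item) pairs at lines {lines}"
        )
    return df.reset_index(drop=True)


def write_trials(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df, columns=list(TRIAL_COLUMNS)).to_csv(path, index=False)


def aggregate_counts(trials: pd.DataFrame, design: DesignSpec | None = None) -> list[ResponseCounts]:
    """Collapse validated trials to per-participant cell counts.

    When a design is given, every design cell is present in the output
    (zero-trial cells get (0, 0)) and trials outside the design's cells
    raise an error.
    """
    grouped = (
        trials.assign(is_yes=trials["response"].eq("yes"))
        .groupby(["participant_id", "probe", "item_class"], sort=True)["is_yes"]
        .agg(yes="sum", n="count")
        .reset_index()
    )
    out = []
    for pid, grp in grouped.groupby("participant_id", sort=True):
        cells = {
            cell_key(ProbeType(r.probe), ItemClass(r.item_class)): (int(r.yes), int(r.n))
            for r in grp.itertuples()
        }
        if design is not None:
            extra = set(cells) - set(design.cell_keys)
            if extra:
                raise ValueError(
                    f"participant {pid}: cells {sorted(extra)} not in design"
                )
            for k in design.cell_keys:
                cells.setdefault(k, (0, 0))
        out.append(ResponseCounts(participant_id=str(pid), counts=cells))
    return out


def counts_to_frame(counts) -> pd.DataFrame:
    """Tidy counts frame: participant, probe, item_class, yes, n."""
    rows = []
    for c in counts:
        for key, (yes, n) in c.counts.items():
            probe, item = key.split(":")
            rows.append(
                {"participant": c.participant_id, "probe": probe,
                 "item_class": item, "yes": yes, "n": n}
            )
    return pd.DataFrame(rows)


def counts_from_frame(df: pd.DataFrame) -> list[ResponseCounts]:
    required = {"participant", "probe", "item_class", "yes", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts frame missing columns {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("participant", sort=True):
        cells = {}
        for r in grp.itertuples():
            if r.probe not in _VALID_PROBES or r.item_class not in _VALID_ITEMS:
                raise ValueError(
                    f"participant {pid}: unknown cell {r.probe}:{r.item_class}"
                )
            cells[f"{r.probe}:{r.item_class}"] = (int(r.yes), int(r.n))
        out.append(ResponseCounts(participant_id=str(pid), counts=cells))
    return out


def read_counts(path) -> list[ResponseCounts]:
    return counts_from_frame(pd.read_csv(path))


def write_counts(counts, path) -> None:
    counts_to_frame(counts).to_csv(path, index=False)


def trials_from_counts(counts, design: DesignSpec, condition: str = "sim") -> pd.DataFrame:
    """Expand cell counts into a deterministic trial-level table.

    Yes-trials come first within each cell; item ids are synthetic and
    unique per participant, so a write/read/aggregate round trip reproduces
    the counts exactly.
    """
    rows = []
    for c in counts:
        item_no = 0
        for key in design.cell_keys:
            yes, n = c.counts[key]
            probe, item = key.split(":")
            for t in range(n):
                item_no += 1
                rows.append(
                    {
                        "participant_id": c.participant_id,
                        "condition": condition,
                        "item_id": f"it{item_no:03d}",
                        "item_class": item,
                        "probe": probe,
                        "response": "yes" if t < yes else "no",
                    }
                )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
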