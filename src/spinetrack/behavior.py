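"""Novel-object-recognition scoring.

The discrimination index DI = (t_novel - t_familiar) / (t_novel + t_familiar)
lies in [-1, 1]; "total time" is the summed interaction time with the two
objects, which is what keeps the index bounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "UnscoreableTrialError",
    "discrimination_index",
    "score_table",
    "paired_day_comparison",
]


class UnscoreableTrialError(ValueError):
    """Zero total object-interaction time; DI undefined."""


@dataclass(frozen=True)
class InteractionRecord:
    mouse_id: str
    group: str
    phase: str  # "learning" | "testing"
    day: int
    time_novel_s: float
    time_familiar_s: float

    def __post_init__(self) -> None:
        for name in ("time_novel_s", "time_familiar_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


def discrimination_index(record_or_novel, familiar: float | None = None) -> float:
    """DI of one trial; accepts an InteractionRecord or (novel, familiar)."""
    if familiar is None:
        novel, familiar = record_or_novel.time_novel_s, record_or_novel.time_familiar_s
    else:
        novel = float(record_or_novel)
    total = novel + familiar
    if total <= 0:
        raise UnscoreableTrialError("zero total interaction time; trial unscoreable")
    return (novel - familiar) / total


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``di`` column to an interaction table.

    Expects columns mouse_id, group, phase, day, time_novel_s,
    time_familiar_s.  Unscoreable trials (zero total) get NaN and a
    ``flag`` of 'unscoreable'.
    """
    out = df.copy()
    total = out["time_novel_s"] + out["time_familiar_s"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["di"] = (out["time_novel_s"] - out["time_familiar_s"]) / total
    out.loc[total <= 0, "di"] = np.nan
    out["flag"] = np.where(total <= 0, "unscoreable", "")
    return out


def paired_day_comparison(
    df: pd.DataFrame, day_a: int = 18, day_b: int = 53, phase: str = "testing"
) -> pd.DataFrame:
    """Per-mouse DI pairs across two test days, ready for a paired t-test.

    Mice missing either day are excluded with a warning; duplicate records
    for one mouse/day raise.
    """
    sub = df[df["phase"] == phase]
    scored = score_table(sub)
    rows = []
    for (mouse, group), grp in scored.groupby(["mouse_id", "group"], sort=True):
        pair = {}
        for day in (day_a, day_b):
            at = grp[grp["day"] == day]
            if len(at) > 1:
                raise ValueError(f"duplicate records for mouse {mouse} day {day}")
            if len(at) == 1 and np.isfinite(at["di"].iloc[0]):
                pair[day] = float(at["di"].iloc[0])
        if len(pair) < 2:
            warnings.warn(f"mouse {mouse} missing a scoreable day; excluded", stacklevel=2)
            continue
        rows.append(
            {
                "mouse_id": mouse,
                "group": group,
                f"di_day{day_a}": pair[day_a],
                f"di_day{day_b}": pair[day_b],
                "difference": pair[day_b] - pair[day_a],
            }
        )
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", f"di_day{day_a}", f"di_day{day_b}", "difference"]
    )
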