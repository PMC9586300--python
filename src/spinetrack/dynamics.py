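"""Spine-dynamics metrics over binary presence matrices.

All headline quantities of the analysis live here: formation and
elimination fractions against the day-11 baseline, newborn counts per
segment, the per-cohort survival index, long-/short-lived classification,
spine density, and the reverse-time validation that recomputes
formation/elimination with day 18 as the reference.

Aggregation hierarchy is dendrite -> mouse -> group; the mouse is the
statistical unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import SpineTrack

__all__ = [
    "PresenceMatrix",
    "formation_fraction",
    "elimination_fraction",
    "newborn_count_per_segment",
    "survival_index",
    "classify_lifetime",
    "spine_density",
    "reverse_time_metrics",
    "check_conservation",
    "aggregate_by_mouse",
    "compute_metric_table",
]


@dataclass
class PresenceMatrix:
    """Spines x sessions binary table with per-spine annotations.

    ``presence``: DataFrame indexed by spine_id, one column per session day
    (int8 0/1).  ``meta``: DataFrame sharing the index with columns
    dendrite_id, mouse_id, group, cohort_day, reappearance_events,
    segment_length_um.
    """

    presence: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.presence.index.equals(self.meta.index):
            raise ValueError("presence and meta must share the same index")
        vals = self.presence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("presence entries must be binary")
        if vals.size and (vals.sum(axis=1) == 0).any():
            raise ValueError("every spine row must be present at >= 1 session")
        days = list(self.presence.columns)
        if days != sorted(days):
            raise ValueError("session-day columns must be increasing")
        # cohort column entry must be 1
        for sid, cd in self.meta["cohort_day"].items():
            if self.presence.at[sid, cd] != 1:
                raise ValueError(f"cohort day {cd} not marked present for {sid}")

    @property
    def session_days(self) -> list[int]:
        return [int(d) for d in self.presence.columns]

    @classmethod
    def from_tracks(
        cls,
        tracks: list[SpineTrack],
        mouse_id: str,
        group: str,
        segment_length_um: float,
    ) -> "PresenceMatrix":
        if not tracks:
            raise ValueError("no tracks")
        days = list(tracks[0].session_days)
        rows = {t.spine_id: t.presence.astype(np.int8) for t in tracks}
        presence = pd.DataFrame.from_dict(rows, orient="index", columns=days)
        meta = pd.DataFrame(
            {
                "dendrite_id": [t.dendrite_id for t in tracks],
                "mouse_id": mouse_id,
                "group": group,
                "cohort_day": [t.cohort_day for t in tracks],
                "reappearance_events": [t.reappearance_events for t in tracks],
                "segment_length_um": segment_length_um,
            },
            index=presence.index,
        )
        return cls(presence, meta)

    @classmethod
    def concat(cls, mats: list["PresenceMatrix"]) -> "PresenceMatrix":
        return cls(
            pd.concat([m.presence for m in mats]),
            pd.concat([m.meta for m in mats]),
        )

    def for_dendrite(self, dendrite_id: str) -> "PresenceMatrix":
        sel = self.meta["dendrite_id"] == dendrite_id
        return PresenceMatrix(self.presence[sel], self.meta[sel])


def _per_dendrite(
    pm: PresenceMatrix, func, metric: str, warn_empty: str | None = None
) -> pd.DataFrame:
    """Apply ``func(presence, meta) -> value | None`` per dendrite."""
    rows = []
    for did, idx in pm.meta.groupby("dendrite_id", sort=True).groups.items():
        sub_p = pm.presence.loc[idx]
        sub_m = pm.meta.loc[idx]
        val = func(sub_p, sub_m)
        if val is None:
            if warn_empty:
                warnings.warn(f"{warn_empty} for dendrite {did}; excluded", stacklevel=3)
            continue
        rows.append(
            {
                "dendrite_id": did,
                "mouse_id": sub_m["mouse_id"].iloc[0],
                "group": sub_m["group"].iloc[0],
                metric: float(val),
            }
        )
    return pd.DataFrame(rows, columns=["dendrite_id", "mouse_id", "group", metric])


def _check_days(pm: PresenceMatrix, *days: int) -> None:
    for d in days:
        if d not in pm.session_days:
            raise ValueError(f"day {d} not in session calendar {pm.session_days}")


def formation_fraction(pm: PresenceMatrix, baseline_day: int, t: int) -> pd.DataFrame:
    """New-location spines present at day t per baseline spine, per dendrite.

    Numerator: tracks first observed after ``baseline_day`` and present at
    ``t`` (reappearance-merged originals carry the baseline cohort and are
    excluded).  Denominator: tracks present at baseline.  Dendrites without
    baseline spines are excluded with a warning.
    """
    _check_days(pm, baseline_day, t)
    if t == baseline_day:
        raise ValueError("t must differ from baseline_day")

    def f(p: pd.DataFrame, m: pd.DataFrame):
        n_base = int(p[baseline_day].sum())
        if n_base == 0:
            return None
        new = (m["cohort_day"] > baseline_day) & (p[t] == 1)
        return new.sum() / n_base

    return _per_dendrite(pm, f, "formation_fraction", warn_empty="zero baseline spines")


def elimination_fraction(pm: PresenceMatrix, baseline_day: int, t: int) -> pd.DataFrame:
    """Fraction of baseline spines eliminated by day t, per dendrite.

    A baseline spine counts as eliminated at ``t`` only if it is absent at
    ``t`` and at every later session — a gap followed by a return is a
    reappearance of the original spine, not an elimination.
    """
    _check_days(pm, baseline_day, t)
    if t == baseline_day:
        raise ValueError("t must differ from baseline_day")
    later = [d for d in pm.session_days if d >= t]

    def f(p: pd.DataFrame, m: pd.DataFrame):
        base = p[p[baseline_day] == 1]
        if len(base) == 0:
            return None
        gone = (base[later].sum(axis=1) == 0).sum()
        return gone / len(base)

    return _per_dendrite(pm, f, "elimination_fraction", warn_empty="zero baseline spines")


def newborn_count_per_segment(pm: PresenceMatrix, t: int) -> pd.DataFrame:
    """Number of spines first observed at day t, per dendritic segment."""
    _check_days(pm, t)
    if t == pm.session_days[0]:
        raise ValueError("t must be after the first session")

    def f(p: pd.DataFrame, m: pd.DataFrame):
        return float((m["cohort_day"] == t).sum())

    return _per_dendrite(pm, f, "newborn_count")


def _continuous_presence(p: pd.DataFrame, days: list[int], birth: int, t: int) -> pd.Series:
    """Present at every session from birth day through t (inclusive)."""
    span = [d for d in days if birth <= d <= t]
    return p[span].sum(axis=1) == len(span)


def survival_index(pm: PresenceMatrix, cohort_day: int, t: int) -> pd.DataFrame:
    """Per-dendrite fraction of a birth cohort still present at day t.

    A newborn that vanished and reappeared is short-lived: survival to ``t``
    requires presence at every session from first observation through
    ``t``.  Dendrites with an empty cohort are undefined and excluded with
    a warning.
    """
    _check_days(pm, cohort_day, t)
    if t <= cohort_day:
        raise ValueError("t must be strictly after the cohort day")
    days = pm.session_days

    def f(p: pd.DataFrame, m: pd.DataFrame):
        sel = m["cohort_day"] == cohort_day
        if sel.sum() == 0:
            return None
        surv = _continuous_presence(p[sel], days, cohort_day, t)
        return surv.sum() / sel.sum()

    return _per_dendrite(pm, f, "survival_index", warn_empty=f"empty S{cohort_day} cohort")


def classify_lifetime(presence: np.ndarray, reappearance_events: int = 0) -> str:
    """'long_lived' iff present at every session after birth through the end
    and never merged from a gap; otherwise 'short_lived'."""
    presence = np.asarray(presence)
    birth = int(np.argmax(presence))
    if presence[birth:].all() and reappearance_events == 0:
        return "long_lived"
    return "short_lived"


def spine_density(pm: PresenceMatrix, t: int) -> pd.DataFrame:
    """Spines per um of dendrite at day t, plus the baseline/t count ratio.

    ``density_per_um`` (spine count at t / segment length) is the primary
    output; ``density_ratio`` (baseline count / count at t) is the
    alternative bookkeeping ratio, reported alongside.
    """
    _check_days(pm, t)
    baseline_day = pm.session_days[0]
    rows = []
    for did, idx in pm.meta.groupby("dendrite_id", sort=True).groups.items():
        p = pm.presence.loc[idx]
        m = pm.meta.loc[idx]
        length = float(m["segment_length_um"].iloc[0])
        if length <= 0:
            raise ValueError(f"zero-length trace for dendrite {did}")
        n_t = int(p[t].sum())
        n_base = int(p[baseline_day].sum())
        rows.append(
            {
                "dendrite_id": did,
                "mouse_id": m["mouse_id"].iloc[0],
                "group": m["group"].iloc[0],
                "density_per_um": n_t / length,
                "density_ratio": (n_base / n_t) if n_t else np.nan,
            }
        )
    return pd.DataFrame(rows)


def reverse_time_metrics(pm: PresenceMatrix, reverse_baseline_day: int = 18) -> pd.DataFrame:
    """Formation/elimination recomputed backwards from a late reference day.

    Columns up to ``reverse_baseline_day`` are reversed in time, cohorts are
    re-derived as first-present in the reversed order, and the forward
    formulas are applied; validates that the choice of the first imaging day
    as baseline does not drive the metrics.
    """
    days = pm.session_days
    if reverse_baseline_day not in days:
        raise ValueError(f"reverse baseline {reverse_baseline_day} not in calendar {days}")
    if len([d for d in days if d <= reverse_baseline_day]) < 2:
        raise ValueError("need at least two sessions at or before the reverse baseline")
    use = [d for d in days if d <= reverse_baseline_day][::-1]
    # re-index columns by pseudo-days that increase along reversed time
    pseudo = {d: i for i, d in enumerate(use)}
    p = pm.presence[use].copy()
    p.columns = [pseudo[d] for d in use]
    keep = p.sum(axis=1) > 0
    p = p[keep]
    meta = pm.meta[keep].copy()
    arr = p.to_numpy()
    meta["cohort_day"] = arr.argmax(axis=1)
    sub = PresenceMatrix(p, meta)
    out = []
    for target in range(1, len(use)):
        ff = formation_fraction(sub, 0, target).rename(columns={"formation_fraction": "value"})
        ff["metric"] = "reverse_formation_fraction"
        ef = elimination_fraction(sub, 0, target).rename(columns={"elimination_fraction": "value"})
        ef["metric"] = "reverse_elimination_fraction"
        for df in (ff, ef):
            df["day"] = use[target]
            out.append(df)
    return pd.concat(out, ignore_index=True)


def check_conservation(pm: PresenceMatrix, baseline_day: int, t: int) -> None:
    """Exact bookkeeping identity at day t.

    present(t) = baseline - (baseline spines absent at t)
               + (post-baseline cohorts present at t).
    Raises AssertionError if any dendrite violates it (an observation was
    lost or double-counted during tracking).
    """
    _check_days(pm, baseline_day, t)
    for did, idx in pm.meta.groupby("dendrite_id").groups.items():
        p = pm.presence.loc[idx]
        m = pm.meta.loc[idx]
        present_t = int(p[t].sum())
        n_base = int(p[baseline_day].sum())
        base_absent = int(((p[baseline_day] == 1) & (p[t] == 0)).sum())
        new_present = int(((m["cohort_day"] > baseline_day) & (p[t] == 1)).sum())
        if present_t != n_base - base_absent + new_present:
            raise AssertionError(
                f"conservation violated for {did} at day {t}: "
                f"{present_t} != {n_base} - {base_absent} + {new_present}"
            )


def aggregate_by_mouse(per_dendrite: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Dendrite-level values -> per-mouse means (the statistical unit)."""
    return (
        per_dendrite.groupby(["group", "mouse_id"], sort=True)[metric]
        .mean()
        .reset_index()
    )


def group_mean(per_dendrite: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-mouse means -> per-group mean, SEM and n (mice)."""
    by_mouse = aggregate_by_mouse(per_dendrite, metric)
    g = by_mouse.groupby("group")[metric]
    return pd.DataFrame(
        {
            "mean": g.mean(),
            "sem": g.sem(),
            "n_mice": g.count(),
        }
    ).reset_index()


def compute_metric_table(pm: PresenceMatrix, baseline_day: int | None = None) -> pd.DataFrame:
    """Tidy per-mouse metric table across all post-baseline sessions."""
    days = pm.session_days
    if baseline_day is None:
        baseline_day = days[0]
    pieces = []
    for t in days:
        if t == baseline_day:
            continue
        for metric, df in (
            ("formation_fraction", formation_fraction(pm, baseline_day, t)),
            ("elimination_fraction", elimination_fraction(pm, baseline_day, t)),
            ("newborn_count", newborn_count_per_segment(pm, t) if t > days[0] else None),
        ):
            if df is None:
                continue
            by_mouse = aggregate_by_mouse(df, metric).rename(columns={metric: "value"})
            by_mouse["metric"] = metric
            by_mouse["day"] = t
            pieces.append(by_mouse)
        for cohort_day in days[1:]:
            if t <= cohort_day:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                si = survival_index(pm, cohort_day, t)
            if len(si):
                by_mouse = aggregate_by_mouse(si, "survival_index").rename(
                    columns={"survival_index": "value"}
                )
                by_mouse["metric"] = f"survival_index_S{cohort_day}"
                by_mouse["day"] = t
                pieces.append(by_mouse)
        dens = spine_density(pm, t)
        by_mouse = aggregate_by_mouse(dens, "density_per_um").rename(
            columns={"density_per_um": "value"}
        )
        by_mouse["metric"] = "density_per_um"
        by_mouse["day"] = t
        pieces.append(by_mouse)
    return pd.concat(pieces, ignore_index=True)[
        ["group", "mouse_id", "day", "metric", "value"]
    ]
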