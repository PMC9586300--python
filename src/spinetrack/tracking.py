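"""Cross-session spine identity assignment.

Observations from consecutive sessions are chained per dendrite by greedy
mutual-nearest-neighbour matching in the baseline coordinate frame (session
coordinates corrected by the recovered registration translation).  A spine
that vanishes for exactly one session and returns at the same location is
merged back into its original identity (a "reappearance"); longer gaps start
a new identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .detection import SpineObservation
from .registration import RegistrationResult

__all__ = [
    "MatchingParams",
    "SpineTrack",
    "match_spines",
    "resolve_reappearances",
    "brute_force_assignment",
]


@dataclass(frozen=True)
class MatchingParams:
    tolerance_um: float = 1.0
    max_merge_gap_sessions: int = 1


@dataclass
class SpineTrack:
    """One spine identity across the session calendar.

    ``presence`` is binary over ``session_days``; ``positions`` holds the
    baseline-frame tip position for each present session; the cohort label
    (S11/S13/...) is the session of first observation.
    """

    spine_id: str
    dendrite_id: str
    session_days: tuple[int, ...]
    presence: np.ndarray
    positions: dict[int, tuple[float, float, float]]
    lengths: dict[int, float] = field(default_factory=dict)
    reappearance_events: int = 0

    @property
    def cohort_index(self) -> int:
        return int(np.argmax(self.presence))

    @property
    def cohort_day(self) -> int:
        return self.session_days[self.cohort_index]

    @property
    def cohort(self) -> str:
        return f"S{self.cohort_day}"

    @property
    def last_present_index(self) -> int:
        return int(np.max(np.nonzero(self.presence)[0]))


def _corrected(obs: SpineObservation, reg: RegistrationResult | None) -> np.ndarray:
    p = np.asarray(obs.position, dtype=float)
    if reg is None:
        return p
    return p - reg.offset_xyz


def _greedy_mutual_nn(
    prev_pos: np.ndarray, new_pos: np.ndarray, tolerance: float
) -> list[tuple[int, int]]:
    """Repeatedly pair the globally closest (track, observation) couple.

    The globally closest remaining pair is by construction mutually nearest;
    ties are broken lexicographically so the result is independent of input
    order up to coordinate identity.
    """
    if len(prev_pos) == 0 or len(new_pos) == 0:
        return []
    d = np.linalg.norm(prev_pos[:, None, :] - new_pos[None, :, :], axis=2)
    pairs: list[tuple[int, int]] = []
    cand = [
        (d[i, j], i, j)
        for i in range(d.shape[0])
        for j in range(d.shape[1])
        if d[i, j] <= tolerance
    ]
    cand.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    for _, i, j in cand:
        if i in used_i or j in used_j:
            continue
        pairs.append((i, j))
        used_i.add(i)
        used_j.add(j)
    return pairs


def brute_force_assignment(
    prev_pos: np.ndarray, new_pos: np.ndarray, tolerance: float
) -> list[tuple[int, int]]:
    """Exhaustive minimum-total-distance assignment (test oracle, tiny n).

    Enumerates every injective pairing within tolerance and returns the one
    maximizing pair count then minimizing summed distance.
    """
    n, m = len(prev_pos), len(new_pos)
    d = np.linalg.norm(prev_pos[:, None, :] - new_pos[None, :, :], axis=2) if n and m else np.zeros((n, m))
    best: tuple[int, float, list[tuple[int, int]]] | None = None
    idx_i = list(range(n))
    for k in range(min(n, m), -1, -1):
        for subset in itertools.combinations(idx_i, k):
            for perm in itertools.permutations(range(m), k):
                if any(d[i, j] > tolerance for i, j in zip(subset, perm)):
                    continue
                cost = float(sum(d[i, j] for i, j in zip(subset, perm)))
                key = (-k, cost)
                if best is None or key < (-best[0], best[1]):
                    best = (k, cost, list(zip(subset, perm)))
        if best is not None and best[0] == k:
            break
    return best[2] if best else []


def match_spines(
    observations_by_session: list[list[SpineObservation]],
    registrations: list[RegistrationResult | None],
    params: MatchingParams = MatchingParams(),
    session_days: tuple[int, ...] | None = None,
    dendrite_id: str | None = None,
) -> list[SpineTrack]:
    """Chain per-session observations of one dendrite into spine tracks.

    ``observations_by_session`` and ``registrations`` are aligned with the
    session calendar (``registrations[0]`` is None for the baseline).
    Tracks are chained between consecutive sessions only; gap handling is
    done afterwards by :func:`resolve_reappearances`.

    Raises ``ValueError`` on duplicate identical coordinates in one session.
    """
    n_sessions = len(observations_by_session)
    if len(registrations) != n_sessions:
        raise ValueError("registrations must align with observations_by_session")
    if session_days is None:
        days: list[int] = []
        for i, obs in enumerate(observations_by_session):
            days.append(obs[0].session_day if obs else (registrations[i].session_day if registrations[i] else -1))
        session_days = tuple(days)
    if dendrite_id is None:
        dendrite_id = next(
            (o.dendrite_id for obs in observations_by_session for o in obs), "dendrite"
        )

    corrected: list[list[np.ndarray]] = []
    for i, obs in enumerate(observations_by_session):
        pos = [_corrected(o, registrations[i]) for o in obs]
        if len(pos) > 1:
            arr = np.array(pos)
            dd = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=2)
            np.fill_diagonal(dd, np.inf)
            if dd.min() == 0.0:
                raise ValueError(
                    f"duplicate observations at identical coordinates in session {session_days[i]}"
                )
        corrected.append(pos)

    tracks: list[SpineTrack] = []

    def _new_track(i_session: int, obs: SpineObservation, pos: np.ndarray) -> SpineTrack:
        presence = np.zeros(n_sessions, dtype=np.int8)
        presence[i_session] = 1
        return SpineTrack(
            spine_id="",  # assigned after matching, deterministically
            dendrite_id=dendrite_id,
            session_days=session_days,
            presence=presence,
            positions={i_session: tuple(float(v) for v in pos)},
            lengths={i_session: obs.length_um},
        )

    for obs, pos in zip(observations_by_session[0], corrected[0]):
        tracks.append(_new_track(0, obs, pos))

    for i in range(1, n_sessions):
        active = [t for t in tracks if t.presence[i - 1]]
        prev_pos = np.array([t.positions[i - 1] for t in active]) if active else np.zeros((0, 3))
        new_pos = np.array(corrected[i]) if corrected[i] else np.zeros((0, 3))
        pairs = _greedy_mutual_nn(prev_pos, new_pos, params.tolerance_um)
        matched_j = set()
        for ti, j in pairs:
            t = active[ti]
            t.presence[i] = 1
            t.positions[i] = tuple(float(v) for v in new_pos[j])
            t.lengths[i] = observations_by_session[i][j].length_um
            matched_j.add(j)
        for j, (obs, pos) in enumerate(zip(observations_by_session[i], corrected[i])):
            if j not in matched_j:
                tracks.append(_new_track(i, obs, pos))

    tracks.sort(key=lambda t: (t.cohort_index, t.positions[t.cohort_index]))
    for k, t in enumerate(tracks):
        t.spine_id = f"{dendrite_id}:T{k:04d}"
    return tracks


def resolve_reappearances(
    tracks: list[SpineTrack], params: MatchingParams = MatchingParams()
) -> list[SpineTrack]:
    """Merge gap-then-return identities at the same location.

    A track ending at session i and a track first observed at session
    i + gap + 1 (gap <= ``max_merge_gap_sessions``, default one missed
    session) within the matching tolerance are one spine: the later
    observations are a reappearance of the original, never a new formation.
    Longer absences start a new identity.  Iterates until no merge applies,
    so serial reappearances accumulate in ``reappearance_events``.
    """
    tracks = list(tracks)
    merged = True
    while merged:
        merged = False
        ends: dict[int, list[SpineTrack]] = {}
        for t in tracks:
            ends.setdefault(t.last_present_index, []).append(t)
        candidates: list[tuple[float, SpineTrack, SpineTrack]] = []
        for t in tracks:
            start = t.cohort_index
            for g in range(1, params.max_merge_gap_sessions + 1):
                j = start - g - 1
                if j < 0:
                    continue
                for a in ends.get(j, []):
                    if a is t or a.dendrite_id != t.dendrite_id:
                        continue
                    da = np.linalg.norm(
                        np.asarray(a.positions[j]) - np.asarray(t.positions[start])
                    )
                    if da <= params.tolerance_um:
                        candidates.append((float(da), a, t))
        candidates.sort(key=lambda c: (c[0], c[1].spine_id, c[2].spine_id))
        absorbed: set[str] = set()
        busy: set[str] = set()
        for _, a, b in candidates:
            if a.spine_id in busy or a.spine_id in absorbed or b.spine_id in busy or b.spine_id in absorbed:
                continue
            a.presence = np.maximum(a.presence, b.presence)
            a.positions.update(b.positions)
            a.lengths.update(b.lengths)
            a.reappearance_events += b.reappearance_events + 1
            absorbed.add(b.spine_id)
            busy.add(a.spine_id)  # one merge per surviving track per pass
            merged = True
        if merged:
            tracks = [t for t in tracks if t.spine_id not in absorbed]
    return tracks


def reappearance_fraction(tracks: list[SpineTrack]) -> float:
    """Fraction of tracks with at least one gap-then-return event."""
    if not tracks:
        return 0.0
    return sum(1 for t in tracks if t.reappearance_events > 0) / len(tracks)
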