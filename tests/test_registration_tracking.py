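"""Registration recovery of known jitter and cross-session identity
assignment, including the reappearance rules."""

import numpy as np
import pytest

from spinetrack.detection import SpineObservation
from spinetrack.registration import (
    RegistrationError,
    RegistrationResult,
    register_to_baseline,
)
from spinetrack.synthetic import ImageStack, ImagingParams, render_stack, sham_config, simulate_cohort
from spinetrack.tracking import (
    MatchingParams,
    brute_force_assignment,
    match_spines,
    resolve_reappearances,
)


def obs(x, y=0.0, z=0.0, day=11, L=1.0):
    return SpineObservation("d0", day, (x, y, z), (x, 0.0, 0.0), L, 1.0)


def obs_sessions(list_of_lists, days=None):
    days = days or tuple(11 + 2 * i for i in range(len(list_of_lists)))
    out = []
    for day, coords in zip(days, list_of_lists):
        out.append([obs(*c, day=day) for c in coords])
    return out, days


@pytest.fixture(scope="module")
def scene():
    cfg = sham_config(
        n_mice_per_group=1, dendrites_per_mouse=1,
        segment_length_um=(60.0, 60.0), session_days=(11, 13), seed=2,
    )
    return simulate_cohort(cfg)[0]


class TestRegistration:
    def test_identical_stacks_zero_shift_unit_score(self, scene):
        st = render_stack(scene.timelines, scene.geometry, 11, ImagingParams(), rng=np.random.default_rng(0))
        r = register_to_baseline(st, st)
        assert np.allclose(r.translation_um, (0.0, 0.0, 0.0), atol=1e-9)
        assert r.score > 0.999

    def test_known_jitter_recovered(self, scene):
        im = ImagingParams()
        s0 = render_stack(scene.timelines, scene.geometry, 11, im, rng=np.random.default_rng(3), jitter_um=(0, 0, 0))
        s1 = render_stack(scene.timelines, scene.geometry, 13, im, rng=np.random.default_rng(4), jitter_um=(1.2, -0.6, 1.0))
        r = register_to_baseline(s1, s0)
        assert abs(r.translation_um[0] - 1.2) <= 0.16
        assert abs(r.translation_um[1] + 0.6) <= 0.16
        assert abs(r.translation_um[2] - 1.0) <= 1.0

    def test_pure_noise_pair_fails(self, rng):
        a = ImageStack(rng.poisson(5.0, (7, 40, 200)).astype(np.float32))
        b = ImageStack(rng.poisson(5.0, (7, 40, 200)).astype(np.float32))
        with pytest.raises(RegistrationError):
            register_to_baseline(a, b)

    def test_mismatched_geometry_rejected(self):
        a = ImageStack(np.ones((5, 10, 10), dtype=np.float32))
        b = ImageStack(np.ones((5, 10, 12), dtype=np.float32))
        with pytest.raises(ValueError):
            register_to_baseline(a, b)


class TestMatchSpines:
    def test_single_spine_full_presence(self):
        sessions, days = obs_sessions([[(5.0,)]] * 5)
        tracks = match_spines(sessions, [None] * 5, session_days=days)
        assert len(tracks) == 1
        t = tracks[0]
        assert t.presence.tolist() == [1, 1, 1, 1, 1]
        assert t.cohort == "S11"

    def test_crossed_pair_matches_brute_force(self):
        # two spines whose positions approach within tolerance: greedy
        # mutual-NN must agree with the exhaustive minimum-cost assignment
        prev = np.array([[0.0, 0, 0], [0.9, 0, 0]])
        new = np.array([[0.3, 0, 0], [1.0, 0, 0]])
        sessions, days = obs_sessions([[tuple(p) for p in prev], [tuple(p) for p in new]])
        tracks = match_spines(sessions, [None, None], session_days=days)
        oracle = brute_force_assignment(prev, new, 1.0)
        n_cont = sum(1 for t in tracks if t.presence.sum() == 2)
        assert n_cont == len(oracle) == 2

    def test_mutual_nn_equals_brute_force_when_spaced(self, rng):
        # random <=6-spine instances with nearest spacing >= 2 * tolerance
        tol = 1.0
        for trial in range(30):
            n = int(rng.integers(1, 7))
            base = np.sort(rng.uniform(0, 60, n))
            while len(base) > 1 and np.diff(base).min() < 2 * tol:
                base = np.sort(rng.uniform(0, 60, n))
            prev = np.column_stack([base, np.zeros(n), np.zeros(n)])
            new = prev + rng.uniform(-0.4, 0.4, size=prev.shape)
            sessions, days = obs_sessions(
                [[tuple(p) for p in prev], [tuple(p) for p in new]]
            )
            tracks = match_spines(sessions, [None, None], session_days=days)
            oracle = brute_force_assignment(prev, new, tol)
            assert sum(1 for t in tracks if t.presence.sum() == 2) == len(oracle) == n

    def test_order_invariance(self, rng):
        coords0 = [(1.0,), (5.0,), (9.0,)]
        coords1 = [(1.2,), (5.1,), (12.0,)]
        sessions, days = obs_sessions([coords0, coords1])
        ref = match_spines(sessions, [None, None], session_days=days)
        sessions2, _ = obs_sessions([coords0[::-1], coords1[::-1]])
        perm = match_spines(sessions2, [None, None], session_days=days)
        key = lambda t: (tuple(t.presence), tuple(sorted(t.positions.items())))
        assert sorted(map(key, ref)) == sorted(map(key, perm))

    def test_no_observation_lost_or_duplicated(self, rng):
        sessions, days = obs_sessions(
            [[(1.0,), (4.0,), (9.0,)], [(1.1,), (9.2,)], [(1.0,), (4.4,), (9.1,), (15.0,)]]
        )
        tracks = match_spines(sessions, [None] * 3, session_days=days)
        for i, sess in enumerate(sessions):
            assert sum(int(t.presence[i]) for t in tracks) == len(sess)

    def test_duplicate_coordinates_rejected(self):
        sessions, days = obs_sessions([[(2.0,), (2.0,)]])
        with pytest.raises(ValueError, match="duplicate"):
            match_spines(sessions, [None], session_days=days)

    def test_registration_offsets_applied(self):
        # session-2 positions shifted by a known translation chain back up
        sessions, days = obs_sessions([[(5.0, 1.0, 0.0)], [(6.0, 0.5, 0.0)]])
        reg = RegistrationResult(days[1], (1.0, -0.5, 0.0), 0.9)
        tracks = match_spines(sessions, [None, reg], session_days=days)
        assert len(tracks) == 1
        assert tracks[0].presence.tolist() == [1, 1]


class TestReappearances:
    def test_gap_then_return_merges_to_original(self):
        sessions, days = obs_sessions([[(5.0,)], [], [(5.1,)], [(5.0,)], [(5.05,)]])
        tracks = resolve_reappearances(match_spines(sessions, [None] * 5, session_days=days))
        assert len(tracks) == 1
        t = tracks[0]
        assert t.presence.tolist() == [1, 0, 1, 1, 1]
        assert t.cohort == "S11"  # not a new formation at session 3
        assert t.reappearance_events == 1

    def test_two_session_gap_starts_new_identity(self):
        sessions, days = obs_sessions([[(5.0,)], [], [], [(5.0,)], [(5.0,)]])
        tracks = resolve_reappearances(match_spines(sessions, [None] * 5, session_days=days))
        assert len(tracks) == 2

    def test_no_gaps_leaves_tracks_unchanged(self):
        sessions, days = obs_sessions([[(3.0,), (8.0,)]] * 4)
        tracks = match_spines(sessions, [None] * 4, session_days=days)
        before = [(t.spine_id, t.presence.copy()) for t in tracks]
        after = resolve_reappearances(tracks)
        assert [(t.spine_id, t.presence.tolist()) for t in after] == [
            (sid, p.tolist()) for sid, p in before
        ]

    def test_distant_return_not_merged(self):
        sessions, days = obs_sessions([[(5.0,)], [], [(8.0,)]])
        tracks = resolve_reappearances(match_spines(sessions, [None] * 3, session_days=days))
        assert len(tracks) == 2

    def test_track_identity_agreement_with_ground_truth(self):
        # presence-level pipeline vs generator truth when spacing is
        # comfortably above 1.5x the matching tolerance
        from spinetrack.pipeline import run_presence_cohort
        from spinetrack.synthetic import SimConfig

        cfg = SimConfig(
            n_mice_per_group=1, dendrites_per_mouse=20,
            segment_length_um=(60.0, 60.0), session_days=(11, 13, 15),
            formation_rate_per_spine_per_day=0.15,
            newborn_daily_survival_prob=0.8,
            preexisting_daily_survival_prob=0.99,
            reappearance_prob=0.0,
            min_spacing_um=1.6, min_spacing_same_side_um=2.0,
            baseline_density_per_um=0.25, seed=8,
        )
        res = run_presence_cohort(cfg)
        agree = total = 0
        from spinetrack.synthetic import simulate_cohort

        truth = {
            (tl.dendrite_id, tuple(np.round(tl.position, 3))): tl.presence
            for den in simulate_cohort(cfg)
            for tl in den.timelines
        }
        for dres in res.per_dendrite:
            pm = dres.presence
            # tracks store positions; compare presence rows against the truth
            for sid in pm.presence.index:
                row = pm.presence.loc[sid].to_numpy()
                ok = any(
                    np.array_equal(row, p)
                    for (did, _), p in truth.items()
                    if did == dres.dendrite_id
                )
                agree += int(ok)
                total += 1
        assert total > 50
        assert agree / total >= 0.95
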