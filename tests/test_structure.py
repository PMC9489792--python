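"""Hydrogen bonds, side-chain orientation, pocket waters, window selection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gevikit import (
    HBondCriteria,
    Trajectory,
    TrajSimSpec,
    classify_side_chain_orientation,
    count_pocket_waters,
    detect_hbonds_frame,
    distance_angle_distribution,
    hbond_probability,
    simulate_trajectory,
    trajectory_tail,
)


def brute_force_hbonds(traj, frame_index, donors, acceptors, criteria):
    """Exhaustive double-loop oracle, dedup applied on the raw pair list."""
    frame = traj.coords[frame_index]
    raw = []
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            d = np.linalg.norm(frame[d_idx] - frame[a_idx])
            v1 = frame[d_idx] - frame[h_idx]
            v2 = frame[a_idx] - frame[h_idx]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if d <= criteria.max_donor_acceptor_distance and \
                    ang >= criteria.min_dha_angle:
                raw.append((d_idx, a_idx, d))
    if not criteria.carboxylate_dedup:
        return sorted((d, a) for d, a, _ in raw)
    carboxyl = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
    grouped = {}
    for d_idx, a_idx, dist in raw:
        if (traj.resname[a_idx], traj.name[a_idx]) in carboxyl:
            key = (d_idx, "cx", traj.chain[a_idx], traj.resid[a_idx])
        else:
            key = (d_idx, "at", a_idx)
        if key not in grouped or dist < grouped[key][1]:
            grouped[key] = (a_idx, dist)
    return sorted((key[0], a) for key, (a, _) in grouped.items())


def _single_frame_traj(names, resnames, resids, coords):
    n = len(names)
    return Trajectory(
        serial=np.arange(1, n + 1),
        name=np.array(names),
        resname=np.array(resnames),
        resid=np.array(resids),
        chain=np.array(["A"] * n),
        coords=np.asarray(coords, dtype=float)[None],
        times=np.array([0.0]),
    )


class TestDetectHbonds:
    def _nh_asp(self, od1, od2):
        return _single_frame_traj(
            ["N", "H", "OD1", "OD2"],
            ["GLY", "GLY", "ASP", "ASP"],
            [1, 1, 2, 2],
            [[0, 0, 0], [1, 0, 0], od1, od2],
        )

    def test_linear_bond_inside_cutoffs(self):
        traj = self._nh_asp([2.8, 0, 0], [6.0, 6.0, 0])
        bonds = detect_hbonds_frame(traj, 0, [(0, 1)], [2, 3])
        assert bonds == [(0, 2)]

    def test_distance_fail(self):
        traj = self._nh_asp([3.5, 0, 0], [6.0, 6.0, 0])
        assert detect_hbonds_frame(traj, 0, [(0, 1)], [2, 3]) == []

    def test_angle_fail(self):
        # acceptor at 90 deg from the N-H axis, within distance
        traj = self._nh_asp([1.0, 2.0, 0.0], [6.0, 6.0, 0])
        assert detect_hbonds_frame(traj, 0, [(0, 1)], [2, 3]) == []

    def test_carboxylate_dedup_counts_once(self):
        """Both oxygens of one aspartate within criteria: one bond with the
        dedup rule on, two with it off."""
        traj = self._nh_asp([2.8, 0, 0], [2.8, 1.0, 0])
        on = detect_hbonds_frame(traj, 0, [(0, 1)], [2, 3])
        off = detect_hbonds_frame(traj, 0, [(0, 1)], [2, 3],
                                  HBondCriteria(carboxylate_dedup=False))
        assert len(on) == 1
        assert len(off) == 2
        assert on[0] == (0, 2)   # the closer oxygen is reported

    def test_dedup_never_increases_count(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        donors = [(scripted_traj.index_of(truth["donor"]),
                   scripted_traj.index_of(truth["hydrogen"]))]
        acceptors = [scripted_traj.index_of(a) for a in truth["acceptors"]]
        for f in range(0, scripted_traj.n_frames, 17):
            n_on = len(detect_hbonds_frame(scripted_traj, f, donors, acceptors))
            n_off = len(detect_hbonds_frame(
                scripted_traj, f, donors, acceptors,
                HBondCriteria(carboxylate_dedup=False)))
            assert n_on <= n_off

    def test_matches_brute_force_oracle(self, rng):
        """Vectorised detector equals the exhaustive double loop on random
        multi-donor/multi-acceptor geometries."""
        names = ["N", "H", "N", "H", "OD1", "OD2", "OE1", "OE2", "O"]
        resnames = ["GLY", "GLY", "ALA", "ALA", "ASP", "ASP", "GLU", "GLU",
                    "SER"]
        resids = [1, 1, 2, 2, 3, 3, 4, 4, 5]
        donors = [(0, 1), (2, 3)]
        acceptors = [4, 5, 6, 7, 8]
        criteria = HBondCriteria()
        for trial in range(30):
            coords = rng.uniform(-2.5, 2.5, size=(9, 3))
            coords[1] = coords[0] + rng.normal(0, 0.5, 3)
            coords[3] = coords[2] + rng.normal(0, 0.5, 3)
            traj = _single_frame_traj(names, resnames, resids, coords)
            got = sorted(detect_hbonds_frame(traj, 0, donors, acceptors,
                                             criteria))
            want = brute_force_hbonds(traj, 0, donors, acceptors, criteria)
            assert got == want

    def test_non_hydrogen_donor_atom_rejected(self):
        traj = self._nh_asp([2.8, 0, 0], [6, 6, 0])
        with pytest.raises(ValueError, match="hydrogen"):
            detect_hbonds_frame(traj, 0, [(0, 2)], [3])


class TestHbondProbability:
    def test_scripted_full_occupancy(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=50,
                                               hbond_occupancy=1.0))
        truth = traj.meta["truth"]
        stats = hbond_probability(traj, truth["donor"], truth["hydrogen"],
                                  list(truth["acceptors"]))
        assert stats.probability == 1.0

    def test_scripted_partial_occupancy_exact(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        stats = hbond_probability(scripted_traj, truth["donor"],
                                  truth["hydrogen"],
                                  list(truth["acceptors"]))
        assert stats.probability == pytest.approx(0.30, abs=1e-12)
        assert np.array_equal(stats.series, truth["bonded"])

    def test_zero_distance_cutoff_gives_zero(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        stats = hbond_probability(
            scripted_traj, truth["donor"], truth["hydrogen"],
            list(truth["acceptors"]),
            HBondCriteria(max_donor_acceptor_distance=0.0),
        )
        assert stats.probability == 0.0


class TestOrientation:
    def test_clear_inward_case(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=10,
                                               inward_fraction=1.0))
        truth = traj.meta["truth"]
        series = classify_side_chain_orientation(
            traj, truth["probe"], list(truth["inward_refs"]),
            list(truth["outward_refs"]))
        assert series.fractions["inward"] == 1.0

    def test_scripted_fifty_fifty(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        series = classify_side_chain_orientation(
            scripted_traj, truth["probe"], list(truth["inward_refs"]),
            list(truth["outward_refs"]))
        assert series.fractions == {"inward": 0.5, "outward": 0.5}

    def test_equidistant_tie_is_outward(self):
        traj = _single_frame_traj(
            ["CZ", "CD", "CD"], ["ARG", "GLU", "GLU"], [1, 2, 3],
            [[0, 0, 0], [0, 4, 0], [0, -4, 0]],
        )
        series = classify_side_chain_orientation(traj, "A:1:CZ", ["A:2:CD"],
                                                 ["A:3:CD"])
        assert series.classes[0] == "outward"

    def test_fractions_sum_to_one(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        series = classify_side_chain_orientation(
            scripted_traj, truth["probe"], list(truth["inward_refs"]),
            list(truth["outward_refs"]))
        assert sum(series.fractions.values()) == pytest.approx(1.0)


class TestDistanceAngleDistribution:
    def test_static_geometry_single_bin(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=20,
                                               hbond_occupancy=1.0))
        hist, _, _ = distance_angle_distribution(traj, "A:1:N", "A:1:H",
                                                 "A:2:OD1")
        assert hist.sum() == 20
        assert (hist > 0).sum() == 1

    def test_mass_conservation(self, scripted_traj):
        hist, _, _ = distance_angle_distribution(scripted_traj, "A:1:N",
                                                 "A:1:H", "A:2:OD1",
                                                 distance_bins=12,
                                                 angle_bins=9)
        assert hist.sum() == scripted_traj.n_frames

    def test_bimodal_alternating_distances(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=100,
                                               hbond_occupancy=0.5))
        hist, d_edges, _ = distance_angle_distribution(
            traj, "A:1:N", "A:1:H", "A:2:OD1", distance_bins=2,
            distance_range=(2.0, 9.0))
        assert hist.sum(axis=1)[0] == 50
        assert hist.sum(axis=1)[1] == 50


class TestPocketWaters:
    def test_scripted_schedule_exact(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        counts = count_pocket_waters(scripted_traj, truth["pocket_center"],
                                     truth["pocket_radius"])
        assert np.array_equal(counts, truth["waters"])

    def test_zero_radius_counts_nothing(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        counts = count_pocket_waters(scripted_traj, truth["pocket_center"], 0.0)
        assert np.all(counts == 0)

    def test_radius_monotonicity(self, scripted_traj):
        truth = scripted_traj.meta["truth"]
        c1 = count_pocket_waters(scripted_traj, truth["pocket_center"], 5.0)
        c2 = count_pocket_waters(scripted_traj, truth["pocket_center"], 10.0)
        assert np.all(c2 >= c1)

    def test_no_waters_warns_and_returns_zeros(self):
        traj = _single_frame_traj(["N"], ["GLY"], [1], [[0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="no water"):
            counts = count_pocket_waters(traj, (0, 0, 0), 5.0)
        assert np.array_equal(counts, [0])


class TestTrajectoryTail:
    def test_last_half_of_a_long_run(self):
        traj = simulate_trajectory(TrajSimSpec(n_frames=200, frame_dt=1.0))
        tail = trajectory_tail(traj, 100.0)
        assert np.all(tail.times >= 99.0)
        assert tail.times[-1] == traj.times[-1]

    def test_full_window_is_identity(self, scripted_traj):
        tail = trajectory_tail(scripted_traj,
                               scripted_traj.times[-1] - scripted_traj.times[0])
        assert tail.n_frames == scripted_traj.n_frames

    def test_zero_window_keeps_final_frame(self, scripted_traj):
        tail = trajectory_tail(scripted_traj, 0.0)
        assert tail.n_frames == 1
        assert tail.times[0] == scripted_traj.times[-1]

    def test_window_longer_than_run_rejected(self, scripted_traj):
        with pytest.raises(ValueError):
            trajectory_tail(scripted_traj, 1e6)


class TestRigidMotionInvariance:
    def test_all_geometry_invariant_under_rigid_transform(self, scripted_traj):
        """H-bond series, orientation classes, water counts and
        distance-angle histograms are unchanged by a global rotation plus
        translation applied to every frame."""
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 112.0],
                                  degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        truth = scripted_traj.meta["truth"]
        moved = Trajectory(
            serial=scripted_traj.serial,
            name=scripted_traj.name,
            resname=scripted_traj.resname,
            resid=scripted_traj.resid,
            chain=scripted_traj.chain,
            coords=scripted_traj.coords @ rot.T + shift,
            times=scripted_traj.times,
            meta=scripted_traj.meta,
        )

        s0 = hbond_probability(scripted_traj, truth["donor"],
                               truth["hydrogen"], list(truth["acceptors"]))
        s1 = hbond_probability(moved, truth["donor"], truth["hydrogen"],
                               list(truth["acceptors"]))
        assert np.array_equal(s0.series, s1.series)

        o0 = classify_side_chain_orientation(
            scripted_traj, truth["probe"], list(truth["inward_refs"]),
            list(truth["outward_refs"]))
        o1 = classify_side_chain_orientation(
            moved, truth["probe"], list(truth["inward_refs"]),
            list(truth["outward_refs"]))
        assert np.array_equal(o0.classes, o1.classes)

        c0 = count_pocket_waters(scripted_traj, truth["pocket_center"],
                                 truth["pocket_radius"])
        c1 = count_pocket_waters(moved, rot @ np.array(truth["pocket_center"])
                                 + shift, truth["pocket_radius"])
        assert np.array_equal(c0, c1)

        h0, _, _ = distance_angle_distribution(
            scripted_traj, "A:1:N", "A:1:H", "A:2:OD1",
            distance_bins=8, angle_bins=6, distance_range=(2.0, 9.0))
        h1, _, _ = distance_angle_distribution(
            moved, "A:1:N", "A:1:H", "A:2:OD1",
            distance_bins=8, angle_bins=6, distance_range=(2.0, 9.0))
        assert np.array_equal(h0, h1)
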