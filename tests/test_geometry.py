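"""Trajectory-statistics operations: H-bonds, host frame, depths, RMSD,
residence; including rigid-motion invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from hostguest.chem_io import AtomRecord, MolecularSystem, Trajectory
from hostguest.geometry import (HbondCriterion, classify_bound, depth_metrics,
                                detect_hbonds, guest_rmsd, hbond_occupancy,
                                host_frame, residence_summary, ResidenceSeries)


def _ring_system():
    """Symmetric 6-ring host: rims at z = -1 and z = +1."""
    atoms = []
    for k in range(3):
        a = 2 * np.pi * k / 3
        atoms.append(AtomRecord(len(atoms), "C", f"N{k}", 1,
                                [np.cos(a), np.sin(a), -1.0]))
    for k in range(3):
        a = 2 * np.pi * k / 3
        atoms.append(AtomRecord(len(atoms), "C", f"W{k}", 1,
                                [np.cos(a), np.sin(a), 1.0]))
    return MolecularSystem(atoms)


class TestHostFrame:
    def test_symmetric_ring_center_and_axis(self):
        system = _ring_system()
        axes = host_frame(system, list(range(6)), [0, 1, 2], [3, 4, 5])
        np.testing.assert_allclose(axes.center, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(axes.axis, [0, 0, 1], atol=1e-12)

    def test_axis_rotates_with_system(self):
        system = _ring_system()
        rot = Rotation.from_euler("xyz", [30, 45, 60], degrees=True)
        rotated = system.with_coords(rot.apply(system.coords))
        axes = host_frame(rotated, list(range(6)), [0, 1, 2], [3, 4, 5])
        np.testing.assert_allclose(axes.axis, rot.apply([0, 0, 1]), atol=1e-12)

    def test_swapping_rims_negates_axis(self):
        system = _ring_system()
        fwd = host_frame(system, list(range(6)), [0, 1, 2], [3, 4, 5])
        rev = host_frame(system, list(range(6)), [3, 4, 5], [0, 1, 2])
        np.testing.assert_allclose(rev.axis, -fwd.axis, atol=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            host_frame(_ring_system(), [], [0], [3])


class TestHbondDetection:
    def _frame(self, d, angle_deg):
        """X at origin, H at (1,0,0), Y placed at distance d from H with
        angle(X-H...Y) = angle_deg."""
        theta = np.radians(180.0 - angle_deg)
        y = np.array([1.0, 0, 0]) + d * np.array([np.cos(theta), np.sin(theta), 0.0])
        return np.array([[0.0, 0, 0], [1.0, 0, 0], y])

    @pytest.mark.parametrize("d,angle,formed", [
        (2.0, 170.0, True),    # well inside both thresholds
        (2.2, 170.0, False),   # boundary distance excluded (strict <)
        (1.8, 85.0, False),    # 95 deg deviation from linearity
        (2.1999, 89.9, False),  # angle <= 90 never qualifies
        (2.1999, 91.0, True),   # just past the 90 deg deviation boundary
    ])
    def test_distance_and_linearity_rule(self, d, angle, formed):
        frame = self._frame(d, angle)
        found = detect_hbonds(frame, [(0, 1)], [2], HbondCriterion())
        assert ((0, 1, 2) in found) is formed

    def test_coincident_donor_pair_rejected(self):
        frame = np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            detect_hbonds(frame, [(0, 1)], [2])

    def test_occupancy_matches_brute_force_recount(self, small_bundle):
        bundle, _ = small_bundle
        traj = bundle.trajectory
        donors = bundle.selections["donors"]
        acceptors = bundle.selections["acceptors"]
        crit = HbondCriterion()
        sub = Trajectory(traj.frames[:50], traj.frame_interval, traj.topology)
        occ = hbond_occupancy(sub, donors, acceptors, crit)
        # independent oracle: explicit double loop over frames and pairs
        count = 0
        for fr in sub.frames:
            hit = False
            for (x, h) in donors:
                for y in acceptors:
                    hy = fr[y] - fr[h]
                    d = np.linalg.norm(hy)
                    xh = fr[x] - fr[h]
                    cosang = np.dot(xh, hy) / (np.linalg.norm(xh) * max(d, 1e-300))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if d < crit.max_h_acceptor_distance and \
                            (180.0 - ang) < crit.max_linearity_deviation:
                        hit = True
            count += hit
        assert occ.percent == pytest.approx(100.0 * count / 50)

    def test_all_frames_bonded_gives_100(self):
        frame = self._frame(2.0, 170.0)
        top = MolecularSystem([AtomRecord(i, e, e, 1, c)
                               for i, (e, c) in enumerate(zip("OHO", frame))])
        traj = Trajectory(np.repeat(frame[None], 7, axis=0), 20.0, top)
        assert hbond_occupancy(traj, [(0, 1)], [2]).percent == 100.0

    @pytest.mark.parametrize("n_bonded,total,expected", [
        (20, 3000, 0.67), (123, 3000, 4.10),
    ])
    def test_occupancy_percentage_normalisation(self, n_bonded, total, expected):
        """Frames-with-bond / total-frame normalisation at study scale."""
        bonded = self._frame(2.0, 170.0)
        apart = self._frame(4.0, 170.0)
        frames = np.repeat(apart[None], total, axis=0)
        frames[:n_bonded] = bonded
        top = MolecularSystem([AtomRecord(i, e, e, 1, c)
                               for i, (e, c) in enumerate(zip("OHO", bonded))])
        occ = hbond_occupancy(Trajectory(frames, 20.0, top), [(0, 1)], [2])
        assert round(occ.percent, 2) == expected


class TestDepthMetrics:
    def test_centroid_at_center_gives_zero(self):
        system = _ring_system()
        axes = host_frame(system, list(range(6)), [0, 1, 2], [3, 4, 5])
        frame = np.vstack([system.coords, [[0.0, 0.0, 0.0]]])
        dm = depth_metrics(frame, axes, [[6], [6], [6]])
        assert dm.d1 == pytest.approx(0.0, abs=1e-12)

    def test_displacement_along_axis_is_signed(self):
        system = _ring_system()
        axes = host_frame(system, list(range(6)), [0, 1, 2], [3, 4, 5])
        frame = np.vstack([system.coords, [[0.5, -0.3, 2.0]], [[0.0, 0.0, -2.0]]])
        dm = depth_metrics(frame, axes, [[6], [7], [6, 7]])
        assert dm.d1 == pytest.approx(2.0)
        assert dm.d2 == pytest.approx(-2.0)
        assert dm.d3 == pytest.approx(0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        """Depths are unchanged when the whole system moves rigidly."""
        rng = np.random.default_rng(seed)
        system = _ring_system()
        guest = rng.uniform(-3, 3, size=(4, 3))
        frame = np.vstack([system.coords, guest])
        axes = host_frame(system, list(range(6)), [0, 1, 2], [3, 4, 5])
        base = depth_metrics(frame, axes, [[6, 7, 8, 9], [6], [7, 8]])
        rot = Rotation.random(random_state=np.random.RandomState(seed))
        shift = rng.uniform(-15, 15, size=3)
        moved = rot.apply(frame) + shift
        axes2 = host_frame(system, list(range(6)), [0, 1, 2], [3, 4, 5],
                           coords=moved[:6])
        dm2 = depth_metrics(moved, axes2, [[6, 7, 8, 9], [6], [7, 8]])
        np.testing.assert_allclose([dm2.d1, dm2.d2, dm2.d3],
                                   [base.d1, base.d2, base.d3], atol=1e-9)


class TestRmsdAndResidence:
    def _toy_traj(self):
        rng = np.random.default_rng(1)
        host = rng.uniform(-4, 4, size=(6, 3))
        guest = rng.uniform(-2, 2, size=(4, 3))
        ref = np.vstack([host, guest])
        top = MolecularSystem([AtomRecord(i, "C", f"C{i}", 1, c)
                               for i, c in enumerate(ref)])
        return ref, top

    def test_identical_frame_gives_zero(self):
        ref, top = self._toy_traj()
        traj = Trajectory(ref[None], 20.0, top)
        r = guest_rmsd(traj, ref, list(range(6)), [6, 7, 8, 9])
        assert r[0] == pytest.approx(0.0, abs=1e-9)

    def test_global_translation_removed_by_superposition(self):
        ref, top = self._toy_traj()
        traj = Trajectory((ref + np.array([3.0, 4.0, 0.0]))[None], 20.0, top)
        r = guest_rmsd(traj, ref, list(range(6)), [6, 7, 8, 9])
        assert r[0] == pytest.approx(0.0, abs=1e-9)

    def test_guest_only_translation_is_measured(self):
        ref, top = self._toy_traj()
        frame = ref.copy()
        frame[6:] += np.array([3.0, 4.0, 0.0])
        r = guest_rmsd(Trajectory(frame[None], 20.0, top), ref,
                       list(range(6)), [6, 7, 8, 9])
        assert r[0] == pytest.approx(5.0, abs=1e-9)

    def test_global_rotation_removed_by_superposition(self):
        ref, top = self._toy_traj()
        rot = Rotation.from_euler("zyx", [17.0, -40.0, 3.0], degrees=True)
        r = guest_rmsd(Trajectory(rot.apply(ref)[None], 20.0, top), ref,
                       list(range(6)), [6, 7, 8, 9])
        assert r[0] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_alignment_atoms_rejected(self):
        ref, top = self._toy_traj()
        with pytest.raises(ValueError, match="3 alignment atoms"):
            guest_rmsd(Trajectory(ref[None], 20.0, top), ref, [0, 1], [6])

    def test_bound_classification_is_strict(self):
        series = classify_bound(np.array([4.9, 5.0, 5.1, 0.0]), threshold=5.0)
        np.testing.assert_array_equal(series.bound_flags, [True, False, False, True])

    def test_residence_summary_direct_count(self):
        series = ResidenceSeries(np.array([True, True, False, False]), 20.0)
        summ = residence_summary(series)
        assert summ.occupancy_percent == pytest.approx(50.0)
        assert summ.max_dwell == pytest.approx(0.04)
        assert len(summ.dwell_times) == 1

    def test_all_unbound_gives_zero_dwell(self):
        summ = residence_summary(ResidenceSeries(np.zeros(10, bool), 20.0))
        assert summ.occupancy_percent == 0.0
        assert summ.max_dwell == 0.0
        assert len(summ.dwell_times) == 0

    def test_study_scale_occupancy(self):
        flags = np.zeros(3000, bool)
        flags[:1047] = True
        summ = residence_summary(ResidenceSeries(flags, 100.0))
        assert summ.occupancy_percent == pytest.approx(34.9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_dwell_frames_partition_bound_frames(self, flags):
        """Occupancy equals mean(flags)*100 exactly and dwell frame counts
        sum to the number of bound frames."""
        series = ResidenceSeries(np.array(flags, dtype=bool), 20.0)
        summ = residence_summary(series)
        assert summ.occupancy_percent == pytest.approx(100.0 * np.mean(flags))
        frame_counts = np.round(np.asarray(summ.dwell_times) * 1000.0 / 20.0)
        assert frame_counts.sum() == np.sum(flags)
        assert summ.max_dwell == (max(summ.dwell_times) if len(summ.dwell_times) else 0.0)
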