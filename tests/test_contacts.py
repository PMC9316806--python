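"""Switching function, contact maps, differences, and flagging."""

import numpy as np
import pytest

from tetrastab.contacts import (
    ContactMap,
    SwitchingParams,
    average_contact_map,
    contact_map_difference,
    flag_divergent_residues,
    frame_contact_map,
    switching_contact,
)
from tetrastab.core import Structure, Trajectory, make_atom
from tetrastab.errors import AlignmentError, RangeError
from tetrastab.synthetic import TrajectorySimConfig, simulate_trajectory

P = SwitchingParams(r0=8.5, n_exp=6, m_exp=10)


class TestSwitchingFunction:
    def test_zero_distance_is_one(self):
        assert switching_contact(0.0, P) == pytest.approx(1.0)

    def test_removable_singularity_limit(self):
        assert switching_contact(P.r0, P) == pytest.approx(0.6)

    def test_two_r0_closed_form(self):
        # (1 - 2^6) / (1 - 2^10) = 63/1023
        assert switching_contact(2 * P.r0, P) == pytest.approx(63 / 1023, rel=1e-12)

    def test_three_r0_closed_form(self):
        assert switching_contact(3 * P.r0, P) == pytest.approx(728 / 59048, rel=1e-12)

    def test_continuity_at_singularity(self):
        for eps in (1e-6, -1e-6):
            assert abs(switching_contact(P.r0 + eps, P) - 0.6) < 1e-4

    def test_strictly_decreasing(self):
        r = np.linspace(1e-3, 5 * P.r0, 500)
        c = switching_contact(r, P)
        assert np.all(np.diff(c) < 0)

    def test_long_range_tail(self):
        assert switching_contact(10 * P.r0, P) < 1e-3

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SwitchingParams(r0=-1.0)
        with pytest.raises(ValueError):
            SwitchingParams(n_exp=10, m_exp=6)


def _chain3(d01, d02):
    """Three single-CA residues on a line at pairwise distances d01, d02
    from residue 1 (residues in two chains so difference tests can vary)."""
    atoms = [
        make_atom(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), "C"),
        make_atom(2, "CA", "GLY", "A", 2, (d01, 0.0, 0.0), "C"),
        make_atom(3, "CA", "GLY", "B", 1, (d02, 0.0, 0.0), "C"),
    ]
    return Structure(atoms)


class TestFrameContactMap:
    def test_zero_distance_entry_one(self):
        s = _chain3(0.0 + 1e-13, 20.0)
        # coincident residues 0 and 1
        m = frame_contact_map(s.coords, s, "ca", P).matrix
        assert m[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_toy_chain_hand_values(self):
        s = _chain3(P.r0, 2 * P.r0)  # pairwise: r0, 2r0, and r0 between res1-res2
        m = frame_contact_map(s.coords, s, "ca", P).matrix
        assert m[0, 1] == pytest.approx(0.6)
        assert m[0, 2] == pytest.approx(63 / 1023)
        assert m[1, 2] == pytest.approx(0.6)

    def test_far_residues_negligible(self):
        # the tail decays as (r/r0)^(n-m) = k^-4, so 20*r0 gives < 1e-5
        s = _chain3(5.0, 20 * P.r0)
        m = frame_contact_map(s.coords, s, "ca", P).matrix
        assert m[0, 2] < 1e-5

    def test_symmetric_unit_diagonal(self, tetramer):
        cm = frame_contact_map(tetramer.coords, tetramer, "ca", P)
        assert np.allclose(cm.matrix, cm.matrix.T)
        assert np.allclose(np.diag(cm.matrix), 1.0)
        assert cm.matrix.min() >= 0.0 and cm.matrix.max() <= 1.0


class TestAverageContactMap:
    def test_single_frame_equals_frame_map(self, tetramer):
        traj = Trajectory(tetramer, tetramer.coords[None])
        avg = average_contact_map(traj, "ca", P)
        single = frame_contact_map(tetramer.coords, tetramer, "ca", P)
        assert np.allclose(avg.matrix, single.matrix)

    def test_two_identical_frames(self, tetramer):
        traj = Trajectory(tetramer, np.repeat(tetramer.coords[None], 2, axis=0))
        avg = average_contact_map(traj, "ca", P)
        assert np.allclose(avg.matrix, frame_contact_map(tetramer.coords, tetramer, "ca", P).matrix)
        assert avg.frames_averaged == 2

    def test_hand_average_r0_then_2r0(self):
        s = _chain3(P.r0, 40.0)
        f1 = s.coords.copy()
        f2 = s.coords.copy()
        f2[1, 0] = 2 * P.r0  # residue pair moves r0 -> 2 r0
        traj = Trajectory(s, np.stack([f1, f2]))
        avg = average_contact_map(traj, "ca", P)
        assert avg.matrix[0, 1] == pytest.approx((0.6 + 63 / 1023) / 2)

    def test_empty_range_rejected(self, tetramer):
        traj = Trajectory(tetramer, tetramer.coords[None])
        with pytest.raises(RangeError):
            average_contact_map(traj, "ca", P, frame_range=(1, 1))

    def test_residue_com_representation(self, tetramer):
        traj = Trajectory(tetramer, tetramer.coords[None])
        cm = average_contact_map(traj, "residue_com", P)
        assert np.allclose(cm.matrix, cm.matrix.T)


class TestDifferenceAndFlagging:
    def test_map_minus_itself_zero_and_unflagged(self, tetramer):
        cm = frame_contact_map(tetramer.coords, tetramer, "ca", P)
        diff = contact_map_difference(cm, cm)
        assert np.allclose(diff.matrix, 0.0)
        for thr in (0.1, 0.25, 0.5):
            assert flag_divergent_residues(diff, thr).flagged_residues == ()

    def test_absolute_difference_arithmetic(self):
        labels = ("A:1", "A:2")
        a = ContactMap(labels=labels, matrix=np.array([[1.0, 0.9], [0.9, 1.0]]), frames_averaged=1)
        b = ContactMap(labels=labels, matrix=np.array([[1.0, 0.6], [0.6, 1.0]]), frames_averaged=1)
        d = contact_map_difference(a, b)
        assert d.matrix[0, 1] == pytest.approx(0.3)
        assert d.matrix[0, 0] == 0.0

    def test_difference_symmetric_in_arguments(self, tetramer, toy_spec, rng):
        cfgs = [TrajectorySimConfig(n_frames=3, sigma=0.8, seed=s) for s in (1, 2)]
        maps = []
        for cfg in cfgs:
            traj, _ = simulate_trajectory(tetramer, cfg, toy_spec)
            maps.append(average_contact_map(traj, "ca", P))
        d_ab = contact_map_difference(maps[0], maps[1])
        d_ba = contact_map_difference(maps[1], maps[0])
        assert np.allclose(d_ab.matrix, d_ba.matrix)

    def test_label_mismatch_reports_first_discrepancy(self):
        a = ContactMap(labels=("A:1", "A:2"), matrix=np.eye(2), frames_averaged=1)
        b = ContactMap(labels=("A:1", "B:2"), matrix=np.eye(2), frames_averaged=1)
        with pytest.raises(AlignmentError, match="position 1"):
            contact_map_difference(a, b)

    def test_single_entry_threshold_band(self):
        labels = ("A:1", "A:2", "B:1")
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.3
        diff = contact_map_difference(
            ContactMap(labels=labels, matrix=np.clip(m + np.eye(3), 0, 1), frames_averaged=1),
            ContactMap(labels=labels, matrix=np.eye(3), frames_averaged=1),
        )
        flagged_low = flag_divergent_residues(diff, 0.25).flagged_residues
        assert set(flagged_low) == {"A:1", "A:2"}
        assert flag_divergent_residues(diff, 0.5).flagged_residues == ()

    def test_flag_report_sorted_descending(self):
        labels = ("A:1", "A:2", "A:3")
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.4
        m[1, 2] = m[2, 1] = 0.6
        from tetrastab.contacts import DifferenceMap

        diff = DifferenceMap(labels=labels, matrix=m, reference_system="r", target_system="t")
        rep = flag_divergent_residues(diff, 0.25)
        assert rep.flagged_residues[0] in ("A:2", "A:3")
        maxes = [rep.max_diff_per_residue[lab] for lab in rep.flagged_residues]
        assert maxes == sorted(maxes, reverse=True)

    def test_displaced_segment_flagging(self, toy_spec, tetramer):
        """A 5-residue segment displaced by >= 2*r0 flags the perturbed
        residues and their contact partners, and nothing farther than one
        position from a truly perturbed contact."""
        seg = ("A", (330, 334), 2 * P.r0 + 1.0)
        base_cfg = TrajectorySimConfig(n_frames=10, sigma=0.2, seed=3)
        pert_cfg = TrajectorySimConfig(n_frames=10, sigma=0.2, seed=4, perturbed_segment=seg)
        t_ref, _ = simulate_trajectory(tetramer, base_cfg, toy_spec)
        t_mut, truth = simulate_trajectory(tetramer, pert_cfg, toy_spec)
        diff = contact_map_difference(
            average_contact_map(t_mut, "ca", P), average_contact_map(t_ref, "ca", P)
        )
        rep = flag_divergent_residues(diff, 0.25)
        displaced = {f"{c}:{s}" for c, s in truth.perturbed_residues}
        assert displaced <= set(rep.flagged_residues)

        # ground truth: residues whose noiseless contact changed >= 0.25
        truly = _truth_partners(tetramer, tetramer.coords, seg, P, thr=0.25)
        allowed = _with_neighbors(truly)
        assert set(rep.flagged_residues) <= allowed


def _truth_partners(structure, ref_coords, seg, params, thr):
    """Residues involved in a contact that the rigid displacement changes
    by >= thr, computed directly from noiseless geometry."""
    ch, (lo, hi), disp = seg
    from tetrastab.contacts import frame_contact_map

    moved = ref_coords.copy()
    idx = [i for i, a in enumerate(structure.atoms) if a.chain_id == ch and lo <= a.residue_seq <= hi]
    # displacement direction used by the generator: radially outward
    from tetrastab.synthetic import _chain_axis_xy, ToyTetramerSpec

    spec = ToyTetramerSpec()
    k = spec.chain_ids.index(ch)
    ax = _chain_axis_xy(spec, k)
    u = np.array([ax[0], ax[1], 0.0])
    u /= np.linalg.norm(u)
    moved[idx] += disp * u
    before = frame_contact_map(ref_coords, structure, "ca", params).matrix
    after = frame_contact_map(moved, structure, "ca", params).matrix
    d = np.abs(after - before)
    np.fill_diagonal(d, 0.0)
    from tetrastab.contacts import residue_labels

    labels = residue_labels(structure)
    hit = set()
    ii, jj = np.nonzero(d >= thr)
    for i, j in zip(ii, jj):
        hit.add(labels[i])
        hit.add(labels[j])
    return hit


def _with_neighbors(labels):
    out = set()
    for lab in labels:
        ch, seq = lab.split(":")
        for ds in (-1, 0, 1):
            out.add(f"{ch}:{int(seq) + ds}")
    return out
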