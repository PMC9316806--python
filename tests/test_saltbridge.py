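"""Inter-chain functional-group distances, occupancy, and arrangements."""

import numpy as np
import pytest

from tetrastab.core import ChainPairing, Structure, Trajectory, make_atom
from tetrastab.errors import SelectionError
from tetrastab.masses import ELEMENT_MASSES
from tetrastab.saltbridge import (
    DEFAULT_GROUP_SPEC,
    Arrangement,
    ArrangementDistanceSeries,
    distance_distribution,
    enumerate_arrangements,
    functional_group_com,
    interchain_distance_series,
    saltbridge_occupancy,
)
from tetrastab.synthetic import TrajectorySimConfig, simulate_trajectory


class TestEnumerateArrangements:
    def test_canonical_four_arrangements(self, pairing):
        labels = [a.label for a in enumerate_arrangements(pairing, 337, 352)]
        assert labels == ["337.A-352.B", "337.B-352.A", "337.C-352.D", "337.D-352.C"]

    def test_single_pair_gives_two(self):
        arrs = enumerate_arrangements(ChainPairing(pairs=(("A", "B"),)), 337, 352)
        assert len(arrs) == 2

    def test_empty_pairing(self):
        assert enumerate_arrangements(ChainPairing(pairs=()), 337, 352) == []

    def test_count_is_twice_pairs(self, pairing):
        assert len(enumerate_arrangements(pairing, 1, 2)) == 2 * len(pairing.pairs)

    def test_missing_residue_error_names_chain(self, pairing, tetramer):
        with pytest.raises(SelectionError, match="999"):
            enumerate_arrangements(pairing, 999, 352, tetramer)


def _arg_structure(coords_by_name, chain="A", seq=337):
    atoms = []
    for i, (name, xyz) in enumerate(coords_by_name.items(), start=1):
        el = "N" if name.startswith("N") else "C"
        atoms.append(make_atom(i, name, "ARG", chain, seq, xyz, el))
    return Structure(atoms)


class TestFunctionalGroupCOM:
    def test_coincident_atoms(self):
        p = (1.5, -2.0, 3.0)
        s = _arg_structure({"NE": p, "CZ": p, "NH1": p, "NH2": p})
        assert np.allclose(functional_group_com(s.coords, s, "A", 337), p)

    def test_equal_mass_midpoint(self):
        atoms = [make_atom(1, "OD1", "ASP", "A", 352, (0, 0, 0), "O"),
                 make_atom(2, "OD2", "ASP", "A", 352, (2, 0, 0), "O")]
        s = Structure(atoms)
        com = functional_group_com(s.coords, s, "A", 352)
        assert np.allclose(com, [1, 0, 0])

    def test_guanidinium_hand_weighted_mean(self):
        """NE/CZ/NH1/NH2 at stated coordinates: COM is the nitrogen/carbon
        mass-weighted mean, checked by independent hand arithmetic."""
        coords = {"NE": (0.0, 0.0, 0.0), "CZ": (1.3, 0.0, 0.0),
                  "NH1": (2.0, 1.1, 0.0), "NH2": (2.0, -1.1, 0.0)}
        s = _arg_structure(coords)
        m_n, m_c = ELEMENT_MASSES["N"], ELEMENT_MASSES["C"]
        total = 3 * m_n + m_c
        expect_x = (m_n * 0.0 + m_c * 1.3 + m_n * 2.0 + m_n * 2.0) / total
        expect_y = (m_n * 0.0 + m_c * 0.0 + m_n * 1.1 + m_n * (-1.1)) / total
        com = functional_group_com(s.coords, s, "A", 337)
        assert com == pytest.approx([expect_x, expect_y, 0.0], abs=1e-12)

    def test_missing_atoms_skipped_but_one_required(self):
        s = _arg_structure({"NE": (1.0, 2.0, 3.0)})  # CZ/NH1/NH2 absent
        com = functional_group_com(s.coords, s, "A", 337)
        assert np.allclose(com, [1.0, 2.0, 3.0])

    def test_no_group_atoms_is_selection_error(self):
        atoms = [make_atom(1, "CA", "ARG", "A", 337, (0, 0, 0), "C")]
        s = Structure(atoms)
        with pytest.raises(SelectionError, match="NE"):
            functional_group_com(s.coords, s, "A", 337)

    def test_hydrogens_excluded(self):
        atoms = [make_atom(1, "SG", "CYS", "A", 337, (1, 0, 0), "S"),
                 make_atom(2, "HG", "CYS", "A", 337, (9, 9, 9), "H")]
        s = Structure(atoms)
        spec_with_h = type(DEFAULT_GROUP_SPEC)(groups={"CYS": ("SG", "HG")})
        com = functional_group_com(s.coords, s, "A", 337, spec_with_h)
        assert np.allclose(com, [1, 0, 0])


class TestDistanceSeries:
    def test_three_four_five(self):
        atoms = [make_atom(1, "SG", "CYS", "A", 1, (0, 0, 0), "S"),
                 make_atom(2, "SG", "CYS", "B", 2, (3, 4, 0), "S")]
        s = Structure(atoms)
        traj = Trajectory(s, s.coords[None])
        series = interchain_distance_series(traj, [Arrangement("A", 1, "B", 2)])
        assert series[0].distances[0] == pytest.approx(5.0)

    def test_coincident_groups_zero(self):
        atoms = [make_atom(1, "SG", "CYS", "A", 1, (1, 1, 1), "S"),
                 make_atom(2, "SG", "CYS", "B", 2, (1, 1, 1), "S")]
        s = Structure(atoms)
        traj = Trajectory(s, s.coords[None])
        series = interchain_distance_series(traj, [Arrangement("A", 1, "B", 2)])
        assert series[0].distances[0] == pytest.approx(0.0)

    def test_global_rigid_motion_invariance(self, tetramer, arrangements):
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("xyz", [31, 57, -12], degrees=True).as_matrix()
        frames = np.stack([tetramer.coords, tetramer.coords @ r.T + np.array([5.0, -3.0, 8.0])])
        traj = Trajectory(tetramer, frames)
        for s in interchain_distance_series(traj, arrangements):
            assert s.distances[0] == pytest.approx(s.distances[1], abs=1e-9)


class TestOccupancy:
    def test_all_below(self):
        s = _series([1.0, 2.0, 3.0])
        assert saltbridge_occupancy(s, 4.5).fraction == 1.0

    def test_all_above(self):
        s = _series([10.0, 12.0])
        assert saltbridge_occupancy(s, 4.5).fraction == 0.0

    def test_counting(self):
        s = _series([3.0, 5.0, 3.0, 6.0])
        assert saltbridge_occupancy(s, 4.5).fraction == pytest.approx(0.5)

    def test_monotone_in_cutoff(self, rng):
        s = _series(rng.uniform(2, 12, 300))
        fracs = [saltbridge_occupancy(s, c).fraction for c in np.linspace(0.5, 14, 40)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_two_state_recovery(self, tetramer, toy_spec, arrangements):
        """Bound probability 0.7 recovered within 3 binomial SEs at 2000 frames."""
        cfg = TrajectorySimConfig(
            n_frames=2000, sigma=0.3, mode="two_state",
            open_pairs=(("A", "B"), ("C", "D")), bound_prob=0.7, open_shift=5.5, seed=21,
        )
        traj, _ = simulate_trajectory(tetramer, cfg, toy_spec)
        for s in interchain_distance_series(traj, arrangements):
            occ = saltbridge_occupancy(s, 6.0)
            assert abs(occ.fraction - 0.7) <= 0.03


def _series(values):
    return ArrangementDistanceSeries(
        arrangement=Arrangement("A", 337, "B", 352),
        distances=np.asarray(values, float),
        times=np.arange(len(values), dtype=float),
    )


class TestDistanceDistribution:
    def test_constant_series_single_bin(self):
        d = distance_distribution(_series([3.5] * 8), n_bins=10)
        assert d.densities.size == 1

    def test_mean_of_two(self):
        d = distance_distribution(_series([3.0, 5.0]), n_bins=2)
        assert d.mean == pytest.approx(4.0)

    def test_bimodal_modes_at_generator_states(self, tetramer, toy_spec, arrangements):
        """Two-state series shows occupied modes at the bound (3.5 Å) and
        unbound (9 Å) state means, within a bin width."""
        cfg = TrajectorySimConfig(
            n_frames=2000, sigma=0.15, mode="two_state",
            open_pairs=(("A", "B"),), bound_prob=0.5, open_shift=5.5, seed=8,
        )
        traj, _ = simulate_trajectory(tetramer, cfg, toy_spec)
        series = interchain_distance_series(traj, arrangements)[0]
        d = distance_distribution(series, n_bins=40, hist_range=(2.0, 11.0))
        width = d.bin_edges[1] - d.bin_edges[0]
        centers = d.bin_centers
        dens = d.densities
        lo_mode = centers[np.argmax(np.where(centers < 6, dens, -1))]
        hi_mode = centers[np.argmax(np.where(centers >= 6, dens, -1))]
        assert abs(lo_mode - 3.5) <= width
        assert abs(hi_mode - 9.0) <= width
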