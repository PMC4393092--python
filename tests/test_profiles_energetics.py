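import math

import numpy as np
import pytest

from porescope import profiles_energetics as pe
from porescope.contacts import ContactRecord
from porescope.model_io import Atom, Frame, MolecularSystem, Trajectory
from porescope.pore_frame import PoreFrame

from conftest import single_particle_traj

PORE = PoreFrame((0,))


class TestOccupancyHistogram:
    def test_fixed_atom_single_bin(self):
        traj = single_particle_traj([7.0] * 10)
        prof = pe.occupancy_histogram(traj, 1, PORE, 1.0)
        vals = np.array(prof.values)
        assert vals.sum() == pytest.approx(1.0)
        i = np.argmax(vals)
        assert prof.bin_edges_A[i] <= 7.0 < prof.bin_edges_A[i + 1]
        assert vals[i] == 1.0

    def test_half_and_half(self):
        traj = single_particle_traj([7.25] * 50 + [-7.25] * 50)
        prof = pe.occupancy_histogram(traj, 1, PORE, 1.0)
        nz = sorted(v for v in prof.values if v > 0)
        assert nz == [0.5, 0.5]

    def test_uniform_within_multinomial_error(self, rng):
        n = 20000
        zs = rng.uniform(-22, 22, n)
        traj = single_particle_traj(zs, dt_ns=0.001)
        prof = pe.occupancy_histogram(traj, 1, PORE, 2.0)
        nbins = len(prof.values)
        p = 1.0 / nbins
        sigma = math.sqrt(p * (1 - p) / n)
        for v in prof.values:
            assert abs(v - p) < 4 * sigma

    def test_sum_at_most_one(self):
        traj = single_particle_traj([0.0] * 5 + [100.0] * 5)  # leaves the grid
        prof = pe.occupancy_histogram(traj, 1, PORE, 1.0)
        assert sum(prof.values) == pytest.approx(0.5)


class TestInteractionProfile:
    def test_always_formed(self):
        traj = single_particle_traj([3.5] * 20)
        recs = [ContactRecord(k, "electrostatic", "lig", "K12", 3.0) for k in range(20)]
        prof = pe.interaction_profile(traj, recs, "K12", 1, PORE, 1.0)
        vals = [v for v in prof.values if v is not None]
        assert vals == [1.0]

    def test_never_formed(self):
        traj = single_particle_traj([3.5] * 20)
        prof = pe.interaction_profile(traj, [], "K12", 1, PORE, 1.0)
        assert [v for v in prof.values if v is not None] == [0.0]

    def test_30_of_100_in_bin(self):
        traj = single_particle_traj([0.5] * 100)
        recs = [ContactRecord(k, "hbond", "lig", "K20", 3.0) for k in range(30)]
        prof = pe.interaction_profile(traj, recs, "K20", 1, PORE, 1.0)
        assert [v for v in prof.values if v is not None] == [pytest.approx(0.3)]

    def test_unvisited_bins_are_none(self):
        traj = single_particle_traj([0.5] * 10)
        prof = pe.interaction_profile(traj, [], "K12", 1, PORE, 1.0)
        assert sum(v is None for v in prof.values) == len(prof.values) - 1

    def test_values_in_unit_interval(self, rng):
        zs = rng.uniform(-10, 10, 200)
        traj = single_particle_traj(zs)
        recs = [ContactRecord(int(k), "electrostatic", "lig", "R15", 3.0)
                for k in rng.choice(200, 80, replace=False)]
        prof = pe.interaction_profile(traj, recs, "R15", 1, PORE, 2.0)
        for v in prof.values:
            assert v is None or 0.0 <= v <= 1.0


class TestPairingProfile:
    def test_constant_two_cations(self):
        traj = single_particle_traj([1.5] * 10)
        recs = []
        for k in range(10):
            recs.append(ContactRecord(k, "cation_pairing", "p", "na1", 3.0))
            recs.append(ContactRecord(k, "cation_pairing", "p", "na2", 3.0))
        prof = pe.pairing_profile(traj, recs, 1, PORE, 1.0)
        assert [v for v in prof.values if v is not None] == [pytest.approx(2.0)]

    def test_no_cations(self):
        traj = single_particle_traj([1.5] * 10)
        prof = pe.pairing_profile(traj, [], 1, PORE, 1.0)
        assert [v for v in prof.values if v is not None] == [0.0]

    def test_alternating_one_three(self):
        traj = single_particle_traj([1.5] * 100)
        recs = []
        for k in range(100):
            recs.append(ContactRecord(k, "cation_pairing", "p", "na1", 3.0))
            if k % 2 == 0:
                recs.append(ContactRecord(k, "cation_pairing", "p", "na2", 3.0))
                recs.append(ContactRecord(k, "cation_pairing", "p", "na3", 3.0))
        prof = pe.pairing_profile(traj, recs, 1, PORE, 1.0)
        assert [v for v in prof.values if v is not None] == [pytest.approx(2.0)]


def ion_trajectory(positions_per_frame, dt_ns=0.1):
    """Center atom + n mobile ions at explicit per-frame positions."""
    n = len(positions_per_frame[0])
    atoms = [Atom(1, "CEN", "C", "CEN", 1)] + [
        Atom(i + 2, "CL", "Cl", "ION", i + 2, role_tags=frozenset({"anion"}))
        for i in range(n)
    ]
    system = MolecularSystem(atoms)
    frames = []
    for k, pos in enumerate(positions_per_frame):
        coords = np.vstack([[0.0, 0.0, 0.0], np.asarray(pos, dtype=float)])
        frames.append(Frame(k * dt_ns, coords))
    return Trajectory(system, frames, dt_ns)


class TestConcentrationProfile:
    def test_single_fixed_ion(self):
        traj = ion_trajectory([[[1.0, 0.0, 3.5]]] * 10)
        prof = pe.concentration_profile(traj, [1], PORE, 1.0, 5.0)
        v_slab = math.pi * 25.0 * 1.0
        nz = [(c, v) for c, v in zip(prof.bin_centers, prof.values) if v > 0]
        assert len(nz) == 1
        assert nz[0][0] == pytest.approx(3.5)
        assert nz[0][1] == pytest.approx(1.0 / v_slab)

    def test_slab_width_preserves_density(self):
        traj = ion_trajectory([[[0.0, 0.0, 3.25]]] * 10)
        p1 = pe.concentration_profile(traj, [1], PORE, 1.0, 5.0)
        p2 = pe.concentration_profile(traj, [1], PORE, 2.0, 5.0)
        assert max(p1.values) == pytest.approx(2 * max(p2.values))
        assert len(p1.values) == 2 * len(p2.values)

    def test_ideal_gas_density(self, rng):
        # iid uniform positions in a cylinder: every bin ~ rho
        n_ions, n_frames, radius = 40, 400, 8.0
        frames_pos = []
        for _ in range(n_frames):
            r = radius * np.sqrt(rng.uniform(0, 1, n_ions))
            th = rng.uniform(0, 2 * math.pi, n_ions)
            z = rng.uniform(-22, 22, n_ions)
            frames_pos.append(np.column_stack([r * np.cos(th), r * np.sin(th), z]))
        traj = ion_trajectory(frames_pos)
        prof = pe.concentration_profile(traj, list(range(1, n_ions + 1)),
                                        PORE, 2.0, radius)
        rho = n_ions / (math.pi * radius**2 * 44.0)
        for v, n in zip(prof.values, prof.n_samples):
            sigma = math.sqrt(max(n, 1)) / (n_frames * math.pi * radius**2 * 2.0)
            assert abs(v - rho) < 4 * sigma + 1e-12


class TestFreeEnergy:
    def test_bulk_gives_zero(self):
        prof = pe.ZProfile([0.0, 1.0], [0.01], None, [100], "concentration")
        fe = pe.free_energy_profile(prof, 0.01, pe.Thermo(300.0))
        assert fe.values[0] == pytest.approx(0.0)

    def test_ratio_e_gives_minus_rt(self):
        prof = pe.ZProfile([0.0, 1.0], [0.01 * math.e], None, [100], "concentration")
        fe = pe.free_energy_profile(prof, 0.01, pe.Thermo(300.0))
        assert fe.values[0] == pytest.approx(-0.5962, abs=5e-5)

    def test_zero_concentration_is_none(self):
        prof = pe.ZProfile([0.0, 1.0, 2.0], [0.0, 0.02], None, [0, 5], "concentration")
        fe = pe.free_energy_profile(prof, 0.01, pe.Thermo())
        assert fe.values[0] is None
        assert fe.values[1] is not None

    def test_nonpositive_bulk_errors(self):
        prof = pe.ZProfile([0.0, 1.0], [0.01], None, [1], "concentration")
        with pytest.raises(ValueError):
            pe.free_energy_profile(prof, 0.0)

    def test_rt_value(self):
        assert pe.Thermo(300.0).RT_kcal == pytest.approx(0.59616, abs=1e-4)


class TestBulkConcentration:
    def test_known_density(self, rng):
        n_ions, n_frames, radius = 30, 300, 6.0
        frames_pos = []
        for _ in range(n_frames):
            r = radius * np.sqrt(rng.uniform(0, 1, n_ions))
            th = rng.uniform(0, 2 * math.pi, n_ions)
            z = rng.uniform(-40, 40, n_ions)
            frames_pos.append(np.column_stack([r * np.cos(th), r * np.sin(th), z]))
        traj = ion_trajectory(frames_pos)
        est = pe.estimate_bulk_concentration(traj, list(range(1, n_ions + 1)),
                                             PORE, (-35.0, -20.0), radius)
        rho = n_ions / (math.pi * radius**2 * 80.0)
        expected_count = rho * math.pi * radius**2 * 15.0 * n_frames
        sigma = math.sqrt(expected_count) / (n_frames * math.pi * radius**2 * 15.0)
        assert abs(est - rho) < 4 * sigma

    def test_zero_ions_gives_zero(self):
        traj = ion_trajectory([[[0.0, 0.0, 0.0]]] * 5)
        est = pe.estimate_bulk_concentration(traj, [1], PORE, (10.0, 20.0), 5.0)
        assert est == 0.0
        prof = pe.ZProfile([0.0, 1.0], [0.01], None, [1], "concentration")
        with pytest.raises(ValueError):
            pe.free_energy_profile(prof, est)

    def test_zero_volume_errors(self):
        traj = ion_trajectory([[[0.0, 0.0, 0.0]]] * 5)
        with pytest.raises(ValueError):
            pe.estimate_bulk_concentration(traj, [1], PORE, (5.0, 5.0), 5.0)


class TestBlockSE:
    def test_constant_series(self):
        mean, se = pe.block_standard_error([2.5] * 100, 4)
        assert mean == pytest.approx(2.5)
        assert se == 0.0

    def test_hand_computed_two_blocks(self):
        mean, se = pe.block_standard_error([1, 1, 1, 2, 2, 2], 2)
        assert mean == pytest.approx(1.5)
        assert se == pytest.approx(0.5)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pe.block_standard_error([1.0, 2.0], 3)
        with pytest.raises(ValueError):
            pe.block_standard_error([1.0] * 10, 1)

    def test_inverse_sqrt_scaling(self, rng):
        # SE of iid noise ~ sigma/sqrt(total n), independent of block count
        n = 40000
        series = rng.normal(0.0, 1.0, n)
        _, se4 = pe.block_standard_error(series, 4)
        expected = 1.0 / math.sqrt(n)
        assert 0.2 * expected < se4 < 5 * expected


class TestSelectivity:
    def test_constructed_three_to_one(self):
        atoms = [Atom(1, "CEN", "C", "CEN", 1)]
        for i in range(3):
            atoms.append(Atom(i + 2, "CL", "Cl", "ION", i + 2,
                              role_tags=frozenset({"anion"})))
        atoms.append(Atom(5, "NA", "Na", "ION", 5, role_tags=frozenset({"cation"})))
        system = MolecularSystem(atoms)
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 5], [2, 0, -3]],
                          dtype=float)
        traj = Trajectory(system, [Frame(0.0, coords), Frame(0.1, coords)], 0.1)
        res = pe.selectivity_ratio(traj, [1, 2, 3], [4], PORE)
        assert res.ratio == pytest.approx(3.0)

    def test_species_swap_inverts(self):
        traj = ion_trajectory([[[0, 0, 1], [0, 0, -1], [0, 0, 2]]] * 3)
        a = pe.selectivity_ratio(traj, [1, 2], [3], PORE)
        b = pe.selectivity_ratio(traj, [3], [1, 2], PORE)
        assert a.ratio * b.ratio == pytest.approx(1.0)

    def test_zero_cation_errors(self):
        traj = ion_trajectory([[[0, 0, 1], [0, 0, 100]]] * 3)
        with pytest.raises(ValueError):
            pe.selectivity_ratio(traj, [1], [2], PORE)
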