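"""Interaction-energy components: pairwise sums against brute-force oracles,
SASA against analytic spheres and an external implementation, PB against the
Born closed form, and the MM-PB/SA aggregation."""

import numpy as np
import pytest

from hostguest.chem_io import AtomRecord, ForceFieldParameters, MolecularSystem
from hostguest.energy import (EnergyDecomposition, coulomb_energy,
                              lennard_jones_energy, mmpbsa_decompose,
                              nonpolar_energy)
from hostguest.pb import (COULOMB_CONSTANT, PBGridSpec, born_energy,
                          pb_solvation_energy)
from hostguest.sasa import SasaSpec, fibonacci_sphere, sasa
from hostguest.synth import make_born_fixture


def _random_sets(rng, na, nb, spread=8.0):
    ca = rng.uniform(-spread, spread, (na, 3))
    cb = rng.uniform(-spread, spread, (nb, 3)) + np.array([2.5 * spread, 0, 0])
    qa, qb = rng.uniform(-1, 1, na), rng.uniform(-1, 1, nb)
    pa = ForceFieldParameters(qa, rng.uniform(0.02, 0.3, na),
                              rng.uniform(0.8, 2.2, na), rng.uniform(1.0, 2.0, na))
    pb_ = ForceFieldParameters(qb, rng.uniform(0.02, 0.3, nb),
                               rng.uniform(0.8, 2.2, nb), rng.uniform(1.0, 2.0, nb))
    return ca, pa, cb, pb_


class TestPairwiseSums:
    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_energy([[0, 0, 0]], [1.0], [[1.0, 0, 0]], [1.0])
        assert e == pytest.approx(COULOMB_CONSTANT)

    def test_opposite_charges_analytic(self):
        e = coulomb_energy([[0, 0, 0]], [1.0], [[3.320637, 0, 0]], [-1.0])
        assert e == pytest.approx(-100.0)

    def test_zero_charges_give_zero(self):
        rng = np.random.default_rng(0)
        e = coulomb_energy(rng.normal(size=(5, 3)), np.zeros(5),
                           rng.normal(size=(4, 3)) + 10, rng.uniform(-1, 1, 4))
        assert e == 0.0

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            coulomb_energy([[0, 0, 0]], [1.0], [[0, 0, 0]], [1.0])

    def test_lj_minimum_and_zero_crossing(self):
        p = ForceFieldParameters([0.0], [0.25], [1.6], [1.5])
        at_min = lennard_jones_energy([[0, 0, 0]], p, [[3.2, 0, 0]], p)
        assert at_min == pytest.approx(-0.25)
        at_sigma = lennard_jones_energy([[0, 0, 0]], p, [[3.2 / 2 ** (1 / 6), 0, 0]], p)
        assert at_sigma == pytest.approx(0.0, abs=1e-12)

    def test_lj_decays(self):
        p = ForceFieldParameters([0.0], [0.25], [1.6], [1.5])
        far = lennard_jones_energy([[0, 0, 0]], p, [[32.0, 0, 0]], p)
        assert abs(far) < 1e-5 * 0.25

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sums_match_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        ca, pa, cb, pb_ = _random_sets(rng, 50, 50)
        e_c = coulomb_energy(ca, pa.charge, cb, pb_.charge)
        e_lj = lennard_jones_energy(ca, pa, cb, pb_)
        ref_c = ref_lj = 0.0
        for i in range(len(ca)):
            for j in range(len(cb)):
                r = np.linalg.norm(ca[i] - cb[j])
                ref_c += COULOMB_CONSTANT * pa.charge[i] * pb_.charge[j] / r
                rmin = pa.lj_rmin_half[i] + pb_.lj_rmin_half[j]
                eps = np.sqrt(pa.lj_epsilon[i] * pb_.lj_epsilon[j])
                ref_lj += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert e_c == pytest.approx(ref_c, rel=1e-10)
        assert e_lj == pytest.approx(ref_lj, rel=1e-10)

    def test_coulomb_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        ca, pa, cb, pb_ = _random_sets(rng, 7, 9)
        assert coulomb_energy(ca, pa.charge, cb, pb_.charge) == pytest.approx(
            coulomb_energy(cb, pb_.charge, ca, pa.charge))


class TestSasa:
    def test_fibonacci_points_are_unit_vectors(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_single_atom_analytic_sphere(self):
        total, per_atom = sasa(np.zeros((1, 3)), np.array([1.5]))
        exact = 4 * np.pi * 2.9 ** 2
        assert total == pytest.approx(exact, rel=0.01)
        assert per_atom[0] == total

    def test_coincident_atoms_keep_union_area(self):
        total_one, _ = sasa(np.zeros((1, 3)), np.array([1.5]))
        total_two, _ = sasa(np.zeros((2, 3)), np.array([1.5, 1.5]))
        assert total_two == pytest.approx(total_one, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        total_one, _ = sasa(np.zeros((1, 3)), np.array([1.5]))
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        total_two, _ = sasa(coords, np.array([1.5, 1.5]))
        assert total_two == pytest.approx(2 * total_one, rel=1e-9)

    def test_point_density_convergence(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 4, (10, 3))
        radii = rng.uniform(1.2, 2.0, 10)
        t1, _ = sasa(coords, radii, SasaSpec(points_per_atom=960))
        t2, _ = sasa(coords, radii, SasaSpec(points_per_atom=1920))
        assert abs(t2 - t1) / t1 < 0.005

    def test_against_external_implementation(self):
        """Cross-check against mdtraj's Shrake-Rupley on a carbon cluster
        (mdtraj fixes carbon radius at 1.7 Å and probe at 1.4 Å)."""
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 6, (8, 3))
        total, _ = sasa(coords, np.full(8, 1.7), SasaSpec(points_per_atom=960))
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(8):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        ref = mdtraj.shrake_rupley(traj, n_sphere_points=960).sum() * 100.0  # nm^2 -> A^2
        assert total == pytest.approx(ref, rel=0.02)

    def test_nonpolar_term_is_linear(self):
        assert nonpolar_energy(0.0) == 0.0
        assert nonpolar_energy(-300.0) == pytest.approx(-2.16)
        assert nonpolar_energy(1234.5, gamma=0.0) == 0.0


class TestPoissonBoltzmann:
    def test_equal_dielectrics_give_zero(self):
        system, params, _ = make_born_fixture()
        e = pb_solvation_energy(system, params,
                                PBGridSpec(spacing=1.0, eps_solvent=1.0))
        assert e == 0.0

    def test_zero_charge_gives_zero(self):
        system, params, _ = make_born_fixture(charge=0.0)
        assert pb_solvation_energy(system, params, PBGridSpec(spacing=1.0)) == 0.0

    def test_born_ion_moderate_grid(self):
        system, params, exact = make_born_fixture(charge=1.0, radius=2.0)
        e = pb_solvation_energy(system, params, PBGridSpec(spacing=0.5))
        assert e == pytest.approx(exact, rel=0.02)

    def test_off_grid_ion_still_accurate(self):
        """Born ion displaced off every grid node (charge spreading +
        boundary handling, not node alignment, carry the accuracy)."""
        system = MolecularSystem(
            [AtomRecord(0, "Na", "ION", 1, [0.137, -0.211, 0.093])])
        params = ForceFieldParameters([1.0], [0.1], [1.5], [2.0])
        e = pb_solvation_energy(system, params, PBGridSpec(spacing=0.5))
        assert e == pytest.approx(born_energy(1.0, 2.0), rel=0.03)

    def test_nonconvergence_reports_residual(self):
        from hostguest.pb import PBConvergenceError
        system, params, _ = make_born_fixture()
        with pytest.raises(PBConvergenceError, match="residual"):
            pb_solvation_energy(system, params,
                                PBGridSpec(spacing=0.5, max_iter=2, tolerance=1e-12))


class TestMmpbsaDecomposition:
    def test_vdw_only_toy_dimer(self):
        atoms = [AtomRecord(0, "C", "C0", 1, [0.0, 0, 0]),
                 AtomRecord(1, "C", "C1", 2, [3.8, 0, 0])]
        system = MolecularSystem(atoms)
        params = ForceFieldParameters([0.0, 0.0], [0.1, 0.1], [1.9, 1.9], [1.7, 1.7])
        dec = mmpbsa_decompose(system, [0], [1], params, PBGridSpec(spacing=1.0))
        assert dec.e_coulomb == 0.0
        assert dec.e_pb == 0.0
        assert dec.e_vdw == pytest.approx(-0.1)  # at the LJ minimum distance
        assert dec.total_enthalpy == pytest.approx(dec.e_vdw + dec.e_np)
        assert dec.e_np < 0  # burial always removes surface

    def test_overlapping_selections_rejected(self):
        atoms = [AtomRecord(i, "C", f"C{i}", 1, [float(i) * 4, 0, 0]) for i in range(3)]
        system = MolecularSystem(atoms)
        params = ForceFieldParameters(np.zeros(3), np.full(3, 0.1),
                                      np.full(3, 1.9), np.full(3, 1.7))
        with pytest.raises(ValueError, match="overlap"):
            mmpbsa_decompose(system, [0, 1], [1, 2], params)

    def test_total_is_component_sum(self):
        dec = EnergyDecomposition(e_coulomb=-7.24, e_pb=17.23, e_np=-2.19,
                                  e_vdw=-23.07)
        assert dec.total_enthalpy == pytest.approx(-15.27, abs=1e-9)
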