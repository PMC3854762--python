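import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ccdock.config import Config
from ccdock.docking import (StartConfiguration, axis_from_angles, dock_pair,
                            energy_map, generate_starts, initial_placement,
                            korobov_angles, minimize_pose, rotation_jacobian,
                            tube_filter)
from ccdock.energy import EnergyParams
from ccdock.reduced import InterfaceSpec
from ccdock.sasa import accessibility
from conftest import bead_protein, rid


def _start(theta=0.0, phi=0.0, quat=(0, 0, 0, 1)):
    return StartConfiguration(theta, phi, np.asarray(quat, dtype=float))


class TestRotationJacobian:
    @pytest.mark.parametrize("omega", [np.zeros(3), np.array([0.3, -0.7, 1.1]),
                                       np.array([1e-5, 0, 0])])
    def test_matches_finite_differences(self, omega):
        J = rotation_jacobian(omega)
        h = 1e-7
        for i in range(3):
            d = np.zeros(3)
            d[i] = h
            num = (Rotation.from_rotvec(omega + d).as_matrix()
                   - Rotation.from_rotvec(omega - d).as_matrix()) / (2 * h)
            np.testing.assert_allclose(J[i], num, atol=1e-6)


class TestStartGeneration:
    def test_korobov_equal_area(self):
        ang = korobov_angles(100, 89)
        assert len(ang) == 100
        assert np.all((ang[:, 0] >= 0) & (ang[:, 0] <= np.pi))
        # equal-area mapping: cos(theta) is uniform on (-1, 1)
        assert abs(np.cos(ang[:, 0]).mean()) < 0.02

    def test_direction_count_follows_density_rule(self, toy_pair,
                                                  default_params):
        rec, _ = toy_pair
        area = accessibility(rec, radius_of=default_params.radius_of).area.sum()
        starts = generate_starts(rec, density=0.01, n_orientations=3, seed=1,
                                 radius_of=default_params.radius_of)
        assert len(starts) == round(area * 0.01) * 3

    def test_explicit_directions_times_orientations(self, toy_pair):
        rec, _ = toy_pair
        starts = generate_starts(rec, n_directions=10, n_orientations=21, seed=0)
        assert len(starts) == 210

    def test_single_start(self, toy_pair):
        rec, _ = toy_pair
        starts = generate_starts(rec, n_directions=1, n_orientations=1, seed=0)
        assert len(starts) == 1

    def test_orientations_deterministic_in_seed(self, toy_pair):
        rec, _ = toy_pair
        a = generate_starts(rec, n_directions=2, n_orientations=5, seed=7)
        b = generate_starts(rec, n_directions=2, n_orientations=5, seed=7)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.orientation, t.orientation)


class TestInitialPlacement:
    def test_point_bodies_exact_clearance(self):
        a = bead_protein("a", [[0, 0, 0]])
        b = bead_protein("b", [[0, 0, 0]])
        xyz, sep = initial_placement(a, b, _start(), clearance=6.0)
        assert sep == pytest.approx(6.0)
        assert np.linalg.norm(xyz[0]) == pytest.approx(6.0)

    def test_chain_minimum_distance_at_clearance(self):
        rng = np.random.default_rng(3)
        a = bead_protein("a", rng.uniform(-5, 5, (10, 3)))
        b = bead_protein("b", rng.uniform(-5, 5, (10, 3)))
        start = _start(theta=1.1, phi=0.4)
        xyz, _ = initial_placement(a, b, start, clearance=6.0)
        d = np.linalg.norm(a.coords[:, None] - xyz[None, :], axis=-1)
        assert d.min() == pytest.approx(6.0, abs=1e-9)

    def test_bad_clearance(self, toy_pair):
        rec, lig = toy_pair
        with pytest.raises(ValueError):
            initial_placement(rec, lig, _start(), clearance=0.0)


class TestMinimizePose:
    def test_recovers_lj_minimum_distance(self, default_params):
        # one attractive bead pair: the minimiser must slide the ligand to r*
        a = bead_protein("a", [[0, 0, 0]])
        b = bead_protein("b", [[0, 0, 0]])
        conf = minimize_pose(a, b, _start(), default_params,
                             compute_interfaces=False)
        assert np.linalg.norm(conf.center) == pytest.approx(5.0, abs=1e-3)
        assert conf.energy == pytest.approx(-0.1, abs=1e-6)
        assert conf.converged

    def test_monotone_descent(self, toy_pair, default_params):
        rec, lig = toy_pair
        for start in generate_starts(rec, n_directions=4, n_orientations=1,
                                     seed=2):
            xyz0, _ = initial_placement(rec, lig, start)
            from ccdock.energy import PairPotential
            e0 = PairPotential(rec, lig, default_params).energy(rec.coords, xyz0)
            conf = minimize_pose(rec, lig, start, default_params,
                                 compute_interfaces=False)
            assert conf.energy <= e0 + 1e-8

    def test_strong_restraint_keeps_center_on_axis(self, toy_pair,
                                                   default_params):
        rec, lig = toy_pair
        cfg = Config(restraint_k=1e6)
        start = _start(theta=0.9, phi=2.2)
        conf = minimize_pose(rec, lig, start, default_params, config=cfg,
                             compute_interfaces=False)
        d = conf.center - rec.center()
        u = start.axis
        perp = d - (d @ u) * u
        assert np.linalg.norm(perp) < 1e-3


class TestDockPair:
    def test_single_start(self, toy_pair, default_params):
        rec, lig = toy_pair
        ds = dock_pair(rec, lig, default_params, n_directions=1,
                       n_orientations=1, seed=0)
        assert len(ds) == 1
        assert ds.receptor_id == "rec" and ds.ligand_id == "lig"

    def test_deterministic_across_runs(self, toy_pair, default_params):
        rec, lig = toy_pair
        a = dock_pair(rec, lig, default_params, n_directions=5,
                      n_orientations=2, seed=9)
        b = dock_pair(rec, lig, default_params, n_directions=5,
                      n_orientations=2, seed=9)
        np.testing.assert_array_equal(a.energies, b.energies)

    def test_keep_best_truncates(self, toy_pair, default_params):
        rec, lig = toy_pair
        ds = dock_pair(rec, lig, default_params, n_directions=5,
                       n_orientations=2, seed=9, keep_best=3)
        assert len(ds) == 3

    def test_best_per_cell(self, toy_pair, default_params):
        rec, lig = toy_pair
        ds = dock_pair(rec, lig, default_params, n_directions=4,
                       n_orientations=3, seed=9, best_per_cell=True)
        assert len(ds) == 4


class TestTubeFilter:
    def _receptor(self):
        # centre of mass at the origin; residue 2 on the +z axis
        return bead_protein("r", [[0, 0, -8], [0, 0, 8], [5, 0, 0], [-5, 0, 0]])

    def test_residue_on_axis_keeps(self):
        rec = self._receptor()
        site = InterfaceSpec("r", {rid(2)})
        assert tube_filter(rec, site, _start(theta=0.0), radius=2.9)

    def test_perpendicular_distance_beyond_radius_drops(self):
        # centre of mass at origin; residue 2 sits 2.91 A off the +z axis
        rec = bead_protein("r", [[0, 0, -8], [2.91, 0, 8], [-2.91, 0, 0]])
        site = InterfaceSpec("r", {rid(2)})
        np.testing.assert_allclose(rec.center(), 0.0, atol=1e-12)
        assert not tube_filter(rec, site, _start(theta=0.0), radius=2.9)
        assert tube_filter(rec, site, _start(theta=0.0), radius=2.92)

    def test_opposite_side_drops(self):
        rec = self._receptor()
        site = InterfaceSpec("r", {rid(2)})
        assert not tube_filter(rec, site, _start(theta=np.pi), radius=2.9)

    def test_empty_site_drops_all(self):
        rec = self._receptor()
        assert not tube_filter(rec, InterfaceSpec("r", frozenset()),
                               _start(), radius=2.9)
        assert not tube_filter(rec, None, _start(), radius=2.9)

    def test_full_surface_site_retains_everything(self, toy_pair):
        rec, _ = toy_pair
        site = InterfaceSpec("r", frozenset(rec.residue_ids))
        starts = generate_starts(rec, n_directions=20, n_orientations=1, seed=0)
        kept = [s for s in starts if tube_filter(rec, site, s, radius=50.0)]
        assert len(kept) == len(starts)


class TestEnergyMap:
    def test_single_conformation_single_cell(self, toy_pair, default_params):
        rec, lig = toy_pair
        ds = dock_pair(rec, lig, default_params, n_directions=1,
                       n_orientations=1, seed=0)
        m = energy_map(ds, n_theta=4, n_phi=4)
        assert np.isfinite(m).sum() == 1
        assert np.nanmin(m) == ds.conformations[0].energy

    def test_map_minimum_equals_decoy_minimum(self, toy_pair, default_params):
        rec, lig = toy_pair
        ds = dock_pair(rec, lig, default_params, n_directions=6,
                       n_orientations=2, seed=1)
        m = energy_map(ds)
        assert np.nanmin(m) == pytest.approx(ds.energies.min())

    def test_flat_map_for_uniform_energies(self, toy_pair, default_params):
        rec, lig = toy_pair
        ds = dock_pair(rec, lig, default_params, n_directions=6,
                       n_orientations=1, seed=1)
        for c in ds.conformations:
            c.energy = -2.5
        m = energy_map(ds)
        assert np.nanmax(m) == np.nanmin(m) == -2.5
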