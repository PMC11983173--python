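import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.optimize import minimize

from bindmodes import geometry
from bindmodes.geometry import (
    GeometryError,
    com_distance_series,
    pairwise_rmsd,
    rmsd_series,
    rmsf,
    sasa,
    superpose,
)
from bindmodes.trajio import Topology, Trajectory


def _point_traj(coords_per_frame, dt=10.0, elements=None, resids=None):
    """Trajectory of bare atoms for geometric unit tests."""
    coords = np.asarray(coords_per_frame, dtype=float)
    n_atoms = coords.shape[1]
    elements = elements or ["C"] * n_atoms
    resids = resids if resids is not None else np.arange(1, n_atoms + 1)
    topo = Topology(
        names=np.array([f"C{i}" for i in range(n_atoms)], dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids),
        resnames=np.array(["ALA"] * n_atoms, dtype=object),
        chains=np.array(["A"] * n_atoms, dtype=object),
        bonds=np.empty((0, 2), dtype=int),
    )
    return Trajectory(topo, coords, dt)


def brute_force_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent superposition oracle: random-rotation search + local
    polish over the rotation-vector parametrization, never using Kabsch."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rots = Rotation.random(20000, random_state=123).as_matrix()
    rotated = np.einsum("rij,aj->rai", rots, mob)
    rmsds = np.sqrt(np.mean(np.sum((rotated - ref) ** 2, axis=2), axis=1))
    best = Rotation.from_matrix(rots[np.argmin(rmsds)]).as_rotvec()

    def objective(v):
        r = Rotation.from_rotvec(v).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1)))

    res = minimize(objective, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    return float(res.fun)


class TestSuperpose:
    def test_identical_coordinates_give_zero_and_identity(self):
        coords = np.random.default_rng(0).normal(size=(6, 3))
        tf, r = superpose(coords, coords)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(tf.translation, 0.0, atol=1e-8)

    def test_recovers_a_planted_rigid_motion(self):
        rng = np.random.default_rng(1)
        mobile = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        reference = mobile @ rot.T + np.array([5.0, 0.0, 0.0])
        tf, r = superpose(mobile, reference)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.apply(mobile), reference, atol=1e-8)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_rotation_search(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            _, r_kabsch = superpose(a, b)
            assert r_kabsch == pytest.approx(brute_force_rmsd(a, b), abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self):
        frame = np.random.default_rng(3).normal(size=(5, 3))
        traj = _point_traj([frame] * 4)
        out = rmsd_series(traj, "all")
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_rigid_ligand_translation_measured_exactly(self):
        rng = np.random.default_rng(4)
        protein = rng.normal(size=(6, 3))
        ligand = rng.normal(size=(3, 3)) + 8.0
        f0 = np.vstack([protein, ligand])
        f1 = np.vstack([protein, ligand + np.array([2.0, 0.0, 0.0])])
        traj = _point_traj([f0, f1, f0],
                           resids=[1, 1, 1, 1, 1, 1, 2, 2, 2])
        out = rmsd_series(traj, fit_selection="resid 1",
                          measure_selection="resid 2")
        assert out.values[0] == pytest.approx(0.0, abs=1e-9)
        assert out.values[1] == pytest.approx(2.0, abs=1e-9)
        assert out.values[2] == pytest.approx(0.0, abs=1e-9)

    def test_reference_frame_value_zero_when_measure_within_fit(self):
        rng = np.random.default_rng(5)
        traj = _point_traj(rng.normal(size=(5, 6, 3)))
        out = rmsd_series(traj, "all", reference_frame=2)
        assert out.values[2] == pytest.approx(0.0, abs=1e-9)
        assert (out.values >= 0).all()


class TestPairwiseRmsd:
    def test_identical_frames_zero_matrix(self):
        frame = np.random.default_rng(6).normal(size=(4, 3))
        out = pairwise_rmsd(_point_traj([frame] * 3), "all")
        assert np.allclose(out.matrix, 0.0, atol=1e-9)

    def test_aab_pattern(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(5, 3))
        b = a + rng.normal(size=(5, 3))
        out = pairwise_rmsd(_point_traj([a, a, b]), "all")
        _, d = superpose(b, a)
        assert out.matrix[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert out.matrix[0, 2] == pytest.approx(d, abs=1e-9)
        assert out.matrix[1, 2] == pytest.approx(d, abs=1e-9)

    def test_matches_individual_superpositions_and_symmetry(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(size=(6, 5, 3))
        out = pairwise_rmsd(_point_traj(frames), "all")
        assert np.allclose(out.matrix, out.matrix.T, atol=1e-6)
        assert np.allclose(np.diag(out.matrix), 0.0)
        for i in range(6):
            for j in range(i + 1, 6):
                _, d = superpose(frames[j], frames[i])
                assert out.matrix[i, j] == pytest.approx(d, abs=1e-9)


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        frame = np.random.default_rng(9).normal(size=(5, 3))
        out = rmsf(_point_traj([frame] * 5))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_single_oscillating_atom_closed_form(self):
        # fit on the four fixed atoms so the alignment is exactly the
        # identity; the fifth atom alternates +-a about its mean
        base = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                         [10, 10, 0]])
        a = 0.5
        frames = []
        for i in range(10):
            f = base.copy()
            f[4, 0] += a if i % 2 == 0 else -a
            frames.append(f)
        out = rmsf(_point_traj(frames), fit_selection=[0, 1, 2, 3])
        assert np.allclose(out.values[:4], 0.0, atol=1e-9)
        assert out.values[4] == pytest.approx(a, abs=1e-9)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        # enough atoms that the 6 rigid-body degrees of freedom absorbed by
        # the fit are a small correction (factor sqrt(1 - 2/N))
        rng = np.random.default_rng(10)
        sigma = 0.2
        n_atoms = 40
        base = rng.normal(scale=5.0, size=(n_atoms, 3))
        frames = base[None] + rng.normal(scale=sigma, size=(10000, n_atoms, 3))
        out = rmsf(_point_traj(frames))
        assert np.allclose(out.values, sigma * np.sqrt(3), rtol=0.05)

    def test_single_frame_rejected(self):
        with pytest.raises(GeometryError):
            rmsf(_point_traj([np.random.default_rng(11).normal(size=(4, 3))]))


def analytic_two_sphere_sasa(r1, r2, d, probe):
    """Exact accessible area of two intersecting spheres (spherical caps)."""
    e1, e2 = r1 + probe, r2 + probe
    if d >= e1 + e2:
        return 4 * np.pi * (e1 ** 2 + e2 ** 2)
    if d <= abs(e1 - e2):
        big = max(e1, e2)
        return 4 * np.pi * big ** 2
    h1 = e1 - (d ** 2 + e1 ** 2 - e2 ** 2) / (2 * d)
    h2 = e2 - (d ** 2 + e2 ** 2 - e1 ** 2) / (2 * d)
    return 4 * np.pi * (e1 ** 2 + e2 ** 2) - 2 * np.pi * (e1 * h1 + e2 * h2)


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        area = sasa(np.zeros((1, 3)), ["C"], probe_radius=1.4, n_points=960)
        assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.02)

    def test_fully_overlapping_atoms_count_once(self):
        one = sasa(np.zeros((1, 3)), ["C"])
        two = sasa(np.zeros((2, 3)), ["C", "C"])
        assert two == pytest.approx(one, rel=0.01)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5, 7.0])
    def test_dimer_matches_analytic_cap_area(self, d):
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        est = sasa(coords, ["C", "N"], probe_radius=1.4, n_points=960)
        exact = analytic_two_sphere_sasa(1.70, 1.55, d, 1.4)
        assert est == pytest.approx(exact, rel=0.03)

    def test_monotone_decrease_on_approach(self):
        areas = [sasa(np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"])
                 for d in [6.0, 4.0, 3.0, 2.0, 1.0, 0.5]]
        assert all(a >= b - 1e-6 for a, b in zip(areas, areas[1:]))

    def test_matches_mdtraj_on_random_cluster(self):
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=2.0, size=(8, 3))
        mine = sasa(coords, ["C"] * 8, probe_radius=1.4, n_points=960)
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("ALA", chain)
        for i in range(8):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        # mdtraj uses its own radius table; force Bondi carbon
        ref = mdtraj.shrake_rupley(
            t, probe_radius=0.14, n_sphere_points=960,
            change_radii={"C": 0.170}).sum() * 100.0  # nm^2 -> A^2
        assert mine == pytest.approx(float(ref), rel=0.02)

    def test_unknown_element_rejected(self):
        with pytest.raises(GeometryError, match="Xx"):
            sasa(np.zeros((1, 3)), ["Xx"])


class TestComDistance:
    def test_two_single_atoms(self):
        traj = _point_traj([np.array([[0.0, 0, 0], [3.0, 4.0, 0]])])
        out = com_distance_series(traj, [0], [1])
        assert out.values[0] == pytest.approx(5.0, abs=1e-12)

    def test_geometric_center_cancels(self):
        traj = _point_traj([np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 0, 0]])])
        out = com_distance_series(traj, [0, 1], [2], mass_weighted=False)
        assert out.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_mass_weighting_matches_hand_calculation(self):
        # O at origin (15.999), H at (1,0,0): COM_x = 1.008/17.007
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]]])
        topo = Topology(
            names=np.array(["O1", "H1", "C1"], dtype=object),
            elements=np.array(["O", "H", "C"], dtype=object),
            resids=np.array([1, 1, 2]),
            resnames=np.array(["HOH", "HOH", "LIG"], dtype=object),
            chains=np.array(["A", "A", "A"], dtype=object),
            bonds=np.array([[0, 1]]),
        )
        traj = Trajectory(topo, coords, 1.0)
        out = com_distance_series(traj, [0, 1], [2], mass_weighted=True)
        com_x = 1.008 / (15.999 + 1.008)
        assert out.values[0] == pytest.approx(5.0 - com_x, abs=1e-9)


class TestRigidInvariance:
    def test_descriptors_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(13)
        frames = rng.normal(size=(5, 6, 3))
        rot = Rotation.from_euler("xyz", [30, -60, 45], degrees=True).as_matrix()
        moved = frames @ rot.T + np.array([3.0, -2.0, 7.0])
        t1, t2 = _point_traj(frames), _point_traj(moved)
        assert np.allclose(rmsd_series(t1, "all").values,
                           rmsd_series(t2, "all").values, atol=1e-6)
        assert np.allclose(pairwise_rmsd(t1, "all").matrix,
                           pairwise_rmsd(t2, "all").matrix, atol=1e-6)
        assert np.allclose(rmsf(t1).values, rmsf(t2).values, atol=1e-6)
        assert np.allclose(com_distance_series(t1, [0, 1], [2]).values,
                           com_distance_series(t2, [0, 1], [2]).values,
                           atol=1e-6)
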