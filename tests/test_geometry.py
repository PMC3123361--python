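"""Superposition, virtual C-beta and internal-coordinate geometry."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from camotif.geometry import (
    GeometryError,
    PointSet,
    RigidTransform,
    dihedral,
    distance,
    angle,
    kabsch_superpose,
    phi_psi,
    superposed_rmsd,
    virtual_cbeta,
)
from camotif.peptide import ResidueSpec, build_peptide


def random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return RigidTransform(rot, rng.uniform(-20, 20, size=3))


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        tf, value = kabsch_superpose(pts, pts)
        assert value == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(tf.translation, 0.0, atol=1e-6)

    def test_pure_translation_recovered(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        shifted = pts + np.array([5.0, 0.0, 0.0])
        tf, value = kabsch_superpose(pts, shifted)
        assert value == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tf.translation, [5.0, 0.0, 0.0], atol=1e-6)

    def test_random_rigid_motion_zero_noise(self, rng):
        pts = rng.normal(size=(30, 3)) * 6
        moved = random_rigid(rng).apply(pts)
        assert superposed_rmsd(pts, moved) <= 1e-6

    def test_noisy_rmsd_matches_monte_carlo_oracle(self, rng):
        """Mean fitted RMSD under iid Gaussian noise agrees with simulation."""
        sigma = 0.3
        base = rng.normal(size=(30, 3)) * 6

        def one_trial(r):
            noisy = base + r.normal(0.0, sigma, size=base.shape)
            return superposed_rmsd(noisy, base)

        oracle_rng = np.random.default_rng(7)
        oracle = np.mean([one_trial(oracle_rng) for _ in range(300)])
        observed = np.mean([one_trial(rng) for _ in range(50)])
        assert observed == pytest.approx(oracle, rel=0.1)

    def test_small_instance_matches_rotation_grid_oracle(self, rng):
        """Kabsch equals an exhaustive rotation search on a 4-point set."""
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        _, kabsch_value = kabsch_superpose(a, b)

        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)

        def rmsd_for_euler(euler):
            rot = Rotation.from_euler("zyx", euler).as_matrix()
            return float(np.sqrt(np.mean(np.sum((a0 @ rot.T - b0) ** 2, axis=1))))

        candidates = []
        step = math.radians(20)
        grid = np.arange(-math.pi, math.pi, step)
        for ez in grid:
            for ey in np.arange(-math.pi / 2, math.pi / 2, step):
                for ex in grid:
                    candidates.append((rmsd_for_euler((ez, ey, ex)), (ez, ey, ex)))
        candidates.sort(key=lambda t: t[0])
        best_refined = math.inf
        for _, euler in candidates[:5]:  # multi-start local refinement
            refined = minimize(
                rmsd_for_euler, euler, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 2000},
            )
            best_refined = min(best_refined, float(refined.fun))
        assert kabsch_value == pytest.approx(best_refined, abs=1e-4)
        assert kabsch_value <= best_refined + 1e-4  # optimality

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(GeometryError, match="size"):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(line, line)

    def test_rmsd_symmetry_and_rigid_invariance(self, rng):
        a = rng.normal(size=(12, 3)) * 4
        b = a + rng.normal(0, 0.5, size=a.shape)
        forward = superposed_rmsd(a, b)
        assert forward == pytest.approx(superposed_rmsd(b, a), abs=1e-9)
        moved = random_rigid(rng).apply(a)
        assert superposed_rmsd(moved, b) == pytest.approx(forward, abs=1e-7)

    def test_kabsch_beats_random_probe_transforms(self, rng):
        a = rng.normal(size=(9, 3)) * 4
        b = a + rng.normal(0, 0.8, size=a.shape)
        _, best = kabsch_superpose(a, b)
        for _ in range(50):
            probe = random_rigid(rng)
            probed = probe.apply(a)
            value = float(np.sqrt(np.mean(np.sum((probed - b) ** 2, axis=1))))
            assert best <= value + 1e-9


class TestVirtualCbeta:
    N = np.array([1.458, 0.0, 0.0])
    CA = np.zeros(3)
    C = np.array([-0.55, 1.42, 0.0])

    def test_ideal_internal_coordinates(self):
        cb = virtual_cbeta(self.N, self.CA, self.C)
        assert distance(cb, self.CA) == pytest.approx(1.522, abs=1e-6)
        assert angle(self.N, self.CA, cb) == pytest.approx(110.4, abs=0.5)
        assert angle(self.C, self.CA, cb) == pytest.approx(110.6, abs=0.5)

    def test_l_configuration_matches_standard_formula(self, rng):
        """Agrees with the widely used fixed-coefficient virtual-CB formula,
        which encodes the L-amino-acid side of the backbone plane."""
        n0 = np.array([1.458, 0.0, 0.0])
        ca0 = np.zeros(3)
        ang = math.radians(111.0)  # ideal N-CA-C, assumed by the formula
        c0 = np.array([1.525 * math.cos(ang), 1.525 * math.sin(ang), 0.0])
        for _ in range(20):
            tf = random_rigid(rng)
            n, ca, c = tf.apply(n0), tf.apply(ca0), tf.apply(c0)
            b = ca - n
            cvec = c - ca
            a = np.cross(b, cvec)
            standard = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca
            ours = virtual_cbeta(n, ca, c)
            assert distance(ours, standard) < 0.1

    def test_matches_real_cb_of_template_residue(self, motif_window):
        res = motif_window[0]  # Asp with an explicitly built CB
        cb = virtual_cbeta(
            res.atom("N").coord, res.atom("CA").coord, res.atom("C").coord
        )
        assert distance(cb, res.atom("CB").coord) <= 0.25

    def test_rigid_equivariance(self, rng):
        tf = random_rigid(rng)
        direct = tf.apply(virtual_cbeta(self.N, self.CA, self.C))
        transformed = virtual_cbeta(
            tf.apply(self.N), tf.apply(self.CA), tf.apply(self.C)
        )
        assert np.allclose(direct, transformed, atol=1e-6)

    def test_collinear_backbone_rejected(self):
        with pytest.raises(GeometryError):
            virtual_cbeta(
                np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0])
            )

    def test_internal_coordinates_constant_over_random_backbones(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.normal(size=3) * 5
            ca = n + _random_unit(rng) * 1.458
            # keep the N-CA-C angle in a physical range
            c = ca + _random_unit(rng) * 1.525
            if abs(np.dot((n - ca) / 1.458, (c - ca) / 1.525)) > 0.6:
                continue
            cb = virtual_cbeta(n, ca, c)
            assert distance(cb, ca) == pytest.approx(1.522, abs=1e-9)
            assert angle(n, ca, cb) == pytest.approx(110.4, abs=1e-6)
            assert angle(c, ca, cb) == pytest.approx(110.6, abs=1e-6)


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestInternalCoordinates:
    def test_distance_identical_points(self):
        assert distance(np.zeros(3), np.zeros(3)) == 0.0

    def test_distance_unit_cube_diagonal(self):
        assert distance(np.zeros(3), np.ones(3)) == pytest.approx(
            math.sqrt(3), abs=1e-4
        )

    def test_trans_peptide_omega(self):
        specs = [ResidueSpec("A", -57.0, -47.0) for _ in range(3)]
        residues = build_peptide(specs)
        omega = dihedral(
            residues[0].atom("CA").coord,
            residues[0].atom("C").coord,
            residues[1].atom("N").coord,
            residues[1].atom("CA").coord,
        )
        assert abs(omega) == pytest.approx(180.0, abs=1.0)

    def test_phi_psi_round_trip_and_termini(self):
        targets = [(-57.0, -47.0), (-120.0, 120.0), (60.0, 40.0)]
        specs = [ResidueSpec("A", phi, psi) for phi, psi in targets]
        residues = build_peptide(specs)
        bb = [
            {n: r.atom(n).coord for n in ("N", "CA", "C")} for r in residues
        ]
        out = phi_psi(bb)
        assert out[0][0] is None and out[-1][1] is None
        for i in (1, 2):
            assert out[i][0] == pytest.approx(targets[i][0], abs=1e-5)
        for i in (0, 1):
            assert out[i][1] == pytest.approx(targets[i][1], abs=1e-5)

    def test_dihedral_range(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            value = dihedral(*pts)
            assert -180.0 < value <= 180.0


class TestContainers:
    def test_pointset_rejects_duplicate_labels(self):
        with pytest.raises(GeometryError):
            PointSet(labels=["a", "a"], coords=np.zeros((2, 3)))

    def test_rigid_transform_rejects_reflection(self):
        reflection = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(GeometryError):
            RigidTransform(reflection, np.zeros(3))

    def test_rigid_transform_json_round_trip(self, rng):
        tf = random_rigid(rng)
        back = RigidTransform.from_json_dict(tf.to_json_dict())
        assert np.allclose(back.rotation, tf.rotation)
        assert np.allclose(back.translation, tf.translation)
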