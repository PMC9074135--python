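"""Superposition, RMSD/RMSF, gyration shape descriptors, dihedrals, ring
geometry, and harmonic metal-site energies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpkit.geometry import (
    PT_PHEN_PARAMETERS,
    dihedral,
    gyration,
    gyration_of,
    harmonic_energy,
    kabsch_superpose,
    ring_geometry,
    rmsd_series,
    rmsf,
    shape_series,
)
from idpkit.structure_io import Frame, Trajectory
from idpkit.synthetic import EnsembleSpec, compose_ensemble
from conftest import AB16, single_frame_traj


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _quaternion_rmsd(P, Q):
    """Independent oracle: Horn's quaternion method for optimal RMSD."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx = P.T @ Q
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    n = P.shape[0]
    msd = ((P ** 2).sum() + (Q ** 2).sum() - 2 * lam) / n
    return np.sqrt(max(msd, 0.0))


class TestKabsch:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_gives_zero_rmsd(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        th = np.deg2rad(37.0)
        Rz = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
        assert kabsch_superpose(Q, P).rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(kabsch_superpose(Q, P).rotation) == pytest.approx(1.0, abs=1e-9)

    def test_against_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            P = rng.normal(size=(5, 3))
            Q = rng.normal(size=(5, 3))
            assert kabsch_superpose(P, Q).rmsd == pytest.approx(
                _quaternion_rmsd(P, Q), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        P, Q = rng.normal(size=(2, 8, 3))
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(
            kabsch_superpose(Q, P).rmsd, abs=1e-12)

    def test_rejects_reflection(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1.0          # mirror image
        assert np.linalg.det(kabsch_superpose(Q, P).rotation) == pytest.approx(1.0, abs=1e-9)


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, ab16_helix):
        top, frame = ab16_helix
        traj = Trajectory(top, [frame] * 4)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_nofit_single_displaced_atom(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(25, 3))
        moved = base.copy()
        d = 1.7
        moved[0, 2] += d
        traj = Trajectory.__new__(Trajectory)
        # minimal trajectory over raw coordinates (no topology selection)
        from idpkit.structure_io import AtomRecord, Residue, Topology
        atoms = [AtomRecord(i + 1, "CA", "C", i + 1, "GLY", "A", 12.011)
                 for i in range(25)]
        res = [Residue(i + 1, "GLY", "A", i, i + 1) for i in range(25)]
        top = Topology(atoms, res)
        traj = Trajectory(top, [Frame(moved)])
        out = rmsd_series(traj, reference=base, selection="calpha", fit=False)
        assert out[0] == pytest.approx(d / np.sqrt(25), abs=1e-12)


class TestRmsf:
    def test_static_trajectory_is_zero(self, ab16_helix):
        top, frame = ab16_helix
        traj = Trajectory(top, [frame] * 3)
        assert rmsf(traj)["rmsf"].max() == pytest.approx(0.0, abs=1e-9)

    def test_single_frame_rejected(self, ab16_helix):
        top, frame = ab16_helix
        with pytest.raises(ValueError):
            rmsf(Trajectory(top, [frame]))

    def test_oscillating_atom_closed_form(self, ab16_helix):
        """±d oscillation about the mean in pre-aligned frames → RMSF = d."""
        top, frame = ab16_helix
        d = 0.8
        up, down = frame.coordinates.copy(), frame.coordinates.copy()
        up[0, 0] += d
        down[0, 0] -= d
        traj = Trajectory(top, [Frame(up), Frame(down)])
        table = rmsf(traj, selection=None, align=False)
        assert table["rmsf"].iloc[0] == pytest.approx(d, abs=1e-12)
        assert table["rmsf"].iloc[1:].max() == pytest.approx(0.0, abs=1e-12)

    def test_monotonic_in_ensemble_noise(self):
        means = []
        for sigma in (0.05, 0.35):
            spec = EnsembleSpec(sequence=AB16[:8], n_frames=15,
                                class_fractions={"alpha": 1.0},
                                noise_sigma=sigma, seed=2)
            traj, _ = compose_ensemble(spec)
            means.append(rmsf(traj)["rmsf"].mean())
        assert means[1] > means[0]


class TestGyration:
    def test_single_atom(self):
        g = gyration(np.zeros((1, 3)), mass_weighted=False)
        assert g.rg == 0.0

    def test_two_equal_masses(self):
        g = gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                     masses=np.array([12.0, 12.0]))
        assert g.rg == pytest.approx(1.0, abs=1e-12)
        assert g.anisotropy == pytest.approx(0.0, abs=1e-12)

    def test_tetrahedron_fully_symmetric(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        g = gyration(pts, mass_weighted=False)
        assert g.anisotropy == pytest.approx(1.0, abs=1e-12)
        assert g.kappa2 == pytest.approx(0.0, abs=1e-12)

    def test_planar_symmetric_ring_is_half(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.stack([np.cos(th), np.sin(th), np.zeros(6)], axis=1)
        g = gyration(pts, mass_weighted=False)
        assert g.anisotropy == pytest.approx(0.5, abs=1e-12)

    def test_trace_identity_and_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        m = rng.uniform(1, 16, size=30)
        g = gyration(X, m)
        assert g.eigenvalues.sum() == pytest.approx(g.rg ** 2, rel=1e-12)
        R = _random_rotation(rng)
        g2 = gyration(X @ R.T + 5.0, m)
        assert g2.rg == pytest.approx(g.rg, rel=1e-9)
        np.testing.assert_allclose(g2.eigenvalues, g.eigenvalues, rtol=1e-9)
        g3 = gyration(2.5 * X, m)
        assert g3.rg == pytest.approx(2.5 * g.rg, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_anisotropy_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(2, 20), 3))
        g = gyration(X, mass_weighted=False)
        assert -1e-12 <= g.anisotropy <= 1.0 + 1e-12

    def test_phen_rg_with_platinum(self, phen_pt):
        top, frame = phen_pt
        assert gyration_of(frame, top).rg == pytest.approx(2.3, abs=0.1)


class TestShapeSeries:
    def test_rod_like_chain_anisotropy_near_zero(self, ab16_extended):
        top, frame = ab16_extended
        _, summary = shape_series(single_frame_traj(top, frame),
                                  selection="backbone")
        assert summary.loc["mean", "anisotropy"] < 0.05

    def test_summary_statistics_present(self, helix_coil_ensemble):
        traj, _ = helix_coil_ensemble
        per_frame, summary = shape_series(traj, selection="calpha")
        assert len(per_frame) == traj.n_frames
        assert set(summary.index) == {"mean", "std", "min", "max"}


class TestDihedral:
    def test_hand_case(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == \
            pytest.approx(-90.0, abs=1e-12)

    def test_rigid_invariance_and_mirror_flip(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3))
        ref = dihedral(*pts)
        R = _random_rotation(rng)
        moved = pts @ R.T + 3.0
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)
        mirror = pts.copy()
        mirror[:, 0] *= -1
        assert dihedral(*mirror) == pytest.approx(-ref, abs=1e-9)

    def test_extended_build_is_180(self, ab16_extended):
        from idpkit.geometry import dihedrals
        tab = dihedrals(single_frame_traj(*ab16_extended))
        interior = tab.dropna()
        d = np.abs(interior[["phi", "psi"]].to_numpy()) % 360
        assert np.allclose(np.minimum(d, 360 - d), 180.0, atol=1e-6)


class TestRingGeometry:
    def test_translated_ring_along_normal(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ring = np.stack([1.4 * np.cos(th), 1.4 * np.sin(th), np.zeros(6)], 1)
        stacked = ring + np.array([0, 0, 3.5])
        X = np.vstack([ring, stacked])
        d, ang = ring_geometry(X, range(6), range(6, 12))
        assert d == pytest.approx(3.5, abs=1e-12)
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings_common_centroid(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        a = np.stack([np.cos(th), np.sin(th), np.zeros(6)], 1)
        b = np.stack([np.cos(th), np.zeros(6), np.sin(th)], 1)
        d, ang = ring_geometry(np.vstack([a, b]), range(6), range(6, 12))
        assert d == pytest.approx(0.0, abs=1e-12)
        assert ang == pytest.approx(90.0, abs=1e-9)

    def test_collinear_ring_rejected(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            ring_geometry(np.vstack([X, X + [0, 0, 3]]), range(4), range(4, 8))


class TestHarmonicEnergy:
    def test_zero_at_minimum(self):
        out = harmonic_energy(PT_PHEN_PARAMETERS,
                              bonds={"Pt-N_phen": 2.06, "Pt-N_His": 2.05},
                              angles={"N_phen-Pt-N_phen": 81.0})
        assert out["total"] == pytest.approx(0.0, abs=1e-12)

    def test_pt_nhis_stretch(self):
        out = harmonic_energy(PT_PHEN_PARAMETERS, bonds={"Pt-N_His": 2.15})
        assert out["Pt-N_His"] == pytest.approx(1.27, abs=1e-9)

    def test_nonnegative_and_missing_term(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            r = rng.uniform(1.5, 2.6)
            out = harmonic_energy(PT_PHEN_PARAMETERS, bonds={"Pt-N_phen": r})
            assert out["total"] >= 0.0
        with pytest.raises(KeyError):
            harmonic_energy(PT_PHEN_PARAMETERS, bonds={"Pt-S": 2.3})

    def test_angle_units_per_radian(self):
        out = harmonic_energy(PT_PHEN_PARAMETERS,
                              angles={"N_His-Pt-N_His": 99.0})
        expected = 150.0 * np.deg2rad(10.0) ** 2
        assert out["N_His-Pt-N_His"] == pytest.approx(expected, rel=1e-12)
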