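"""Hydrogen bonds, salt bridges, ligand contacts, stacking, contact maps."""

import numpy as np
import pytest

from idpkit.interactions import (
    classify_hbonds,
    contact_map,
    hbond_occupancy,
    hydrogen_bonds,
    ligand_contacts,
    salt_bridges,
    stacking_occupancy,
    stacking_search,
)
from idpkit.structure_io import Frame, Trajectory
from idpkit.synthetic import (
    EnsembleSpec,
    Injection,
    build_peptide,
    compose_ensemble,
    pose_ligand_stack,
)
from conftest import AB16, ALPHA_CLASSIC, single_frame_traj


class TestHydrogenBonds:
    def test_classic_helix_has_interior_i4_bonds(self, ab16_helix_classic):
        traj = single_frame_traj(*ab16_helix_classic)
        records, _ = hydrogen_bonds(traj)
        bb = records[records["backbone_backbone"]]
        donors = set(bb[bb["sequence_offset"] == 4]["donor_residue"])
        # every donor from residue 5 on reaches its i−4 carbonyl
        assert donors >= set(range(5, 17))

    def test_classification_by_helix_type(self, ab16_helix_classic,
                                          ab16_three_ten):
        rec_a, _ = hydrogen_bonds(single_frame_traj(*ab16_helix_classic))
        cats_a = classify_hbonds(rec_a)
        assert cats_a["i+4->i"] > 0 and cats_a["i+3->i"] == 0
        rec_g, _ = hydrogen_bonds(single_frame_traj(*ab16_three_ten))
        cats_g = classify_hbonds(rec_g)
        assert cats_g["i+3->i"] > 0 and cats_g["i+4->i"] == 0

    def test_pair_beyond_cutoff_absent(self, ab16_extended):
        records, _ = hydrogen_bonds(single_frame_traj(*ab16_extended))
        if not records.empty:
            assert (records["distance"] <= 3.0).all()

    def test_static_frames_constant_count(self, ab16_helix_classic):
        top, frame = ab16_helix_classic
        traj = Trajectory(top, [frame] * 10)
        _, per_frame = hydrogen_bonds(traj)
        assert per_frame["count"].std(ddof=0) == 0.0

    def test_cutoff_monotonicity(self, ab16_helix_classic):
        traj = single_frame_traj(*ab16_helix_classic)
        counts = [hydrogen_bonds(traj, dist_cutoff=c)[1]["count"].iloc[0]
                  for c in (2.6, 3.0, 3.4)]
        assert counts[0] <= counts[1] <= counts[2]


class TestOccupancy:
    def test_arithmetic(self):
        import pandas as pd
        rec = pd.DataFrame({
            "frame": list(range(34)), "donor": 5, "acceptor": 9,
            "donor_residue": 14, "acceptor_residue": 11,
            "donor_name": "ND1", "acceptor_name": "O",
            "distance": 2.9, "angle": 170.0,
            "backbone_backbone": False, "sequence_offset": 3,
        })
        out = hbond_occupancy(rec, 100)
        assert out["occupancy"].iloc[0] == pytest.approx(0.34)

    def test_empty_records(self):
        import pandas as pd
        assert hbond_occupancy(pd.DataFrame(), 10).empty

    def test_injected_hbond_recovered_exactly(self):
        spec = EnsembleSpec(
            sequence=AB16, n_frames=40, class_fractions={"extended": 1.0},
            noise_sigma=0.0, seed=5,
            injections=[Injection("hbond", 14, 11, distance=2.9,
                                  occupancy=0.34, donor_atom="ND1",
                                  acceptor_atom="O")])
        traj, truth = compose_ensemble(spec)
        records, _ = hydrogen_bonds(traj)
        occ = hbond_occupancy(records, traj.n_frames)
        row = occ[occ["key"] == "14ND1->11O"]
        expected = truth.injected["hbond:14-11"].mean()
        assert row["occupancy"].item() == pytest.approx(expected, abs=1e-12)


class TestSaltBridges:
    def _two_frame_pair(self, d1, d2=None):
        """EAR tripeptide with the Glu side chain translated so the minimum
        Glu-O ... Arg-N distance equals the requested value."""
        from idpkit.interactions import acidic_oxygens, basic_nitrogens
        top, frame = build_peptide("EAR", [(180.0, 180.0)] * 3)
        o_idx = [i for i in acidic_oxygens(top)
                 if top.atoms[i].residue_index == 1]
        n_idx = [i for i in basic_nitrogens(top)
                 if top.atoms[i].residue_index == 3]
        side = [i for r in top.residues if r.index == 1
                for i in r.atom_indices()
                if top.atoms[i].name not in ("N", "CA", "C", "O")]
        frames = []
        for d in ([d1] if d2 is None else [d1, d2]):
            X = frame.coordinates.copy()
            dm = np.linalg.norm(X[o_idx][:, None] - X[n_idx][None], axis=2)
            ii, jj = np.unravel_index(np.argmin(dm), dm.shape)
            o, n = o_idx[ii], n_idx[jj]
            u = X[o] - X[n]
            u /= np.linalg.norm(u)
            X[side] += (X[n] + d * u) - X[o]
            dm = np.linalg.norm(X[o_idx][:, None] - X[n_idx][None], axis=2)
            assert dm.min() == pytest.approx(d, abs=1e-9)
            frames.append(Frame(X))
        return Trajectory(top, frames)

    def test_below_threshold_counted(self):
        out = salt_bridges(self._two_frame_pair(3.0))
        row = out[out["key"] == "GLU1-ARG3"]
        assert row["occupancy"].item() == 1.0

    def test_above_threshold_not_counted(self):
        out = salt_bridges(self._two_frame_pair(3.3))
        row = out[out["key"] == "GLU1-ARG3"]
        assert row["occupancy"].item() == 0.0

    def test_injected_occupancy_noise_free_exact(self):
        spec = EnsembleSpec(
            sequence=AB16, n_frames=100, class_fractions={"extended": 1.0},
            noise_sigma=0.0, seed=3,
            injections=[Injection("salt_bridge", 3, 5, distance=3.0,
                                  occupancy=0.5)])
        traj, truth = compose_ensemble(spec)
        out = salt_bridges(traj)
        assert out[out["key"] == "GLU3-ARG5"]["occupancy"].item() == \
            pytest.approx(0.5, abs=1e-12)

    def test_injected_occupancy_with_noise_within_binomial_bounds(self):
        q, n = 0.4, 60
        spec = EnsembleSpec(
            sequence=AB16, n_frames=n, class_fractions={"extended": 1.0},
            noise_sigma=0.15, seed=11,
            injections=[Injection("salt_bridge", 3, 5, distance=3.0,
                                  occupancy=q)])
        traj, truth = compose_ensemble(spec)
        out = salt_bridges(traj)
        got = out[out["key"] == "GLU3-ARG5"]["occupancy"].item()
        sigma = np.sqrt(q * (1 - q) / n)
        assert abs(got - q) <= 3 * sigma

    def test_no_charged_residues_warns_empty(self):
        top, frame = build_peptide("AAAAAA", [(180.0, 180.0)] * 6)
        # strip the termini contributions by selecting interior atoms only:
        # an all-Ala chain still has its terminal amine/carboxylate, which
        # by construction sit ~18 Å apart, so the table exists but is empty
        out = salt_bridges(single_frame_traj(top, frame))
        assert (out["occupancy"] == 0.0).all()

    def test_symmetry_under_rigid_motion(self):
        traj = self._two_frame_pair(3.0)
        X = traj.frames[0].coordinates
        th = np.deg2rad(33)
        R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        moved = Trajectory(traj.topology, [Frame(X @ R.T + 7.0)])
        a = salt_bridges(traj.__class__(traj.topology, [traj.frames[0]]))
        b = salt_bridges(moved)
        np.testing.assert_allclose(a["occupancy"], b["occupancy"])


class TestLigandContacts:
    def test_posed_ligand_counts_as_contact(self, ab16_extended):
        top, frame = ab16_extended
        ctop, cframe = pose_ligand_stack(top, frame, "ring(TYR10)", 4.0, 0.0)
        out = ligand_contacts(single_frame_traj(ctop, cframe), 10)
        assert out["contact_fraction"] == 1.0

    def test_distant_ligand_fraction_zero(self, ab16_extended):
        top, frame = ab16_extended
        ctop, cframe = pose_ligand_stack(top, frame, "ring(TYR10)", 25.0, 0.0)
        out = ligand_contacts(single_frame_traj(ctop, cframe), 10)
        assert out["contact_fraction"] == 0.0
        assert out["monitor_mean"] > 20.0

    def test_no_ligand_raises(self, ab16_extended):
        with pytest.raises(ValueError, match="ligand"):
            ligand_contacts(single_frame_traj(*ab16_extended), 10)


class TestStacking:
    def test_posed_stack_recovered(self, ab16_extended):
        top, frame = ab16_extended
        ctop, cframe = pose_ligand_stack(top, frame, "ring(TYR10)", 3.5, 0.0)
        best, _ = stacking_search(single_frame_traj(ctop, cframe), "TYR10")
        assert best.centroid_distance == pytest.approx(3.5, abs=1e-3)
        assert best.interplanar_angle == pytest.approx(0.0, abs=1e-3)

    def test_tilted_pose_recovered(self, ab16_extended):
        top, frame = ab16_extended
        ctop, cframe = pose_ligand_stack(top, frame, "ring(HIS13)", 3.81, 12.7)
        best, _ = stacking_search(single_frame_traj(ctop, cframe), "HIS13")
        assert best.centroid_distance == pytest.approx(3.81, abs=1e-3)
        assert best.interplanar_angle == pytest.approx(12.7, abs=1e-3)

    def test_closest_frame_identified(self, ab16_extended):
        top, frame = ab16_extended
        frames = []
        for k, d in enumerate([12.0, 3.5, 9.0]):
            _, cf = pose_ligand_stack(top, frame, "ring(TYR10)", d, 0.0)
            frames.append(Frame(cf.coordinates, frame_index=k))
        ctop, _ = pose_ligand_stack(top, frame, "ring(TYR10)", 12.0, 0.0)
        traj = Trajectory(ctop, frames)
        best, table = stacking_search(traj, "TYR10")
        assert best.frame == 1
        assert table["min_centroid_distance"].idxmin() == 1

    def test_injected_stacking_occupancy_recovery(self):
        q, n = 0.5, 30
        spec = EnsembleSpec(
            sequence=AB16, n_frames=n, class_fractions={"extended": 1.0},
            noise_sigma=0.05, seed=9,
            injections=[Injection("stacking", 10, distance=3.5, angle=0.0,
                                  occupancy=q)])
        traj, truth = compose_ensemble(spec)
        got = stacking_occupancy(traj, "TYR10")
        assert got == pytest.approx(truth.injected["stacking:10"].mean(),
                                    abs=1e-12)


class TestContactMap:
    def test_two_residue_distance(self):
        top, frame = build_peptide("GG", [(180.0, 180.0)] * 2)
        m = contact_map(single_frame_traj(top, frame))
        X = frame.coordinates
        d = np.linalg.norm(X[top.find_atom(1, "CA")] - X[top.find_atom(2, "CA")])
        assert m.loc[1, 2] == pytest.approx(d)

    def test_symmetric_zero_diagonal(self, helix_coil_ensemble):
        traj, _ = helix_coil_ensemble
        m = contact_map(traj).to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)

    def test_two_frame_mean(self, ab16_helix, ab16_extended):
        top, fh = ab16_helix
        _, fe = ab16_extended
        mh = contact_map(single_frame_traj(top, fh))
        me = contact_map(single_frame_traj(top, fe))
        both = contact_map(Trajectory(top, [fh, fe]))
        np.testing.assert_allclose(both, (mh + me) / 2.0, atol=1e-9)

    def test_triangle_inequality_per_frame(self, ab16_helix):
        m = contact_map(single_frame_traj(*ab16_helix)).to_numpy()
        n = m.shape[0]
        for i in range(0, n, 3):
            for j in range(i + 1, n, 3):
                for k in range(j + 1, n, 3):
                    assert m[i, k] <= m[i, j] + m[j, k] + 1e-9
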