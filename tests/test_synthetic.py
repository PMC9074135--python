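"""Conformer builders: dihedral fidelity, chirality, ligand geometry,
stacked poses, ensemble composition, and exchange-log synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpkit.geometry import dihedral, dihedrals, gyration_of, ring_geometry
from idpkit.structure_io import Trajectory, ligand_rings_from_frame, ring_groups
from idpkit.synthetic import (
    EnsembleSpec,
    Injection,
    PhiPsiTemplate,
    build_peptide,
    build_phenanthroline,
    compose_ensemble,
    pose_ligand_stack,
    synth_exchange_log,
)
from idpkit.remd import exchange_frequency
from conftest import AB16, single_frame_traj


def _measured_phipsi(top, frame):
    table = dihedrals(single_frame_traj(top, frame))
    return table.set_index("residue_index")[["phi", "psi"]]


def _wrap_close(a, b, tol):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.all(np.minimum(d, 360.0 - d) < tol)


class TestBuildPeptide:
    @pytest.mark.parametrize("phi,psi", [(-60.0, -40.0), (180.0, 180.0),
                                         (-75.0, 150.0), (70.0, -120.0)])
    def test_dihedral_round_trip(self, phi, psi):
        top, frame = build_peptide("AAAAAA", [(phi, psi)] * 6)
        tab = _measured_phipsi(top, frame)
        interior = tab.loc[2:5]
        assert _wrap_close(interior["phi"], phi, 1e-6)
        assert _wrap_close(interior["psi"], psi, 1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(phi=st.floats(-179.9, 180.0), psi=st.floats(-179.9, 180.0))
    def test_dihedral_round_trip_property(self, phi, psi):
        top, frame = build_peptide("GAG", [(phi, psi)] * 3)
        tab = _measured_phipsi(top, frame)
        assert _wrap_close([tab.loc[2, "phi"]], phi, 1e-6)
        assert _wrap_close([tab.loc[2, "psi"]], psi, 1e-6)

    def test_all_residues_are_l_amino_acids(self, ab16_helix):
        """The N→C→CA→CB improper is negative for L residues (CCD oracle
        value for ideal L-alanine: −120°)."""
        top, frame = ab16_helix
        X = frame.coordinates
        for r in top.peptide_residues:
            cb = top.find_atom(r.index, "CB")
            if cb < 0:      # glycine
                continue
            imp = dihedral(X[top.find_atom(r.index, "N")],
                           X[top.find_atom(r.index, "C")],
                           X[top.find_atom(r.index, "CA")],
                           X[cb])
            assert -150.0 < imp < -90.0

    def test_helix_i4_oxygen_nitrogen_distances(self, ab16_helix):
        """The basin-centre helix sits at the top edge of the i+4→i
        hydrogen-bonding window (≈3.2 Å with tetrahedral Cα geometry)."""
        top, frame = ab16_helix
        X = frame.coordinates
        for i in range(2, 12):
            d = np.linalg.norm(X[top.find_atom(i + 4, "N")] -
                               X[top.find_atom(i, "O")])
            assert 2.8 <= d <= 3.2 + 0.01

    def test_extended_rg_matches_extended_chain(self, ab16_extended):
        top, frame = ab16_extended
        assert gyration_of(frame, top).rg == pytest.approx(17.0, abs=1.0)

    def test_unknown_residue_letter(self):
        with pytest.raises(ValueError, match="unknown residue"):
            build_peptide("AXA", [(180.0, 180.0)] * 3)

    def test_template_angle_validation(self):
        with pytest.raises(ValueError):
            PhiPsiTemplate("bad", -200.0, 0.0)


class TestPhenanthroline:
    def test_formula_and_planarity(self, phen):
        top, frame = phen
        assert top.n_atoms == 14
        elements = sorted(a.element for a in top.atoms)
        assert elements.count("C") == 12 and elements.count("N") == 2
        # exact planarity
        z = frame.coordinates[:, 2]
        assert np.abs(z - z.mean()).max() < 1e-6

    def test_three_fused_six_membered_rings(self, phen):
        top, frame = phen
        rings = ligand_rings_from_frame(top, frame.coordinates)
        assert len(rings) == 3
        assert all(len(r) == 6 for r in rings)

    def test_aromatic_bond_lengths(self, phen):
        top, frame = phen
        X = frame.coordinates
        d = np.linalg.norm(X[:, None] - X[None], axis=2)
        bonded = (d > 0) & (d < 1.75)
        assert np.all((d[bonded] > 1.35) & (d[bonded] < 1.45))

    def test_pt_fragment_rg(self, phen_pt):
        """Mass-weighted Rg of the Pt-containing ligand fragment is the
        2.3 Å 'ligand size' figure; Pt sits 2.06 Å from both N."""
        top, frame = phen_pt
        assert gyration_of(frame, top).rg == pytest.approx(2.3, abs=0.1)
        X = frame.coordinates
        pt = [i for i, a in enumerate(top.atoms) if a.element == "PT"]
        ns = [i for i, a in enumerate(top.atoms) if a.element == "N"]
        for n in ns:
            assert np.linalg.norm(X[pt[0]] - X[n]) == pytest.approx(2.06, abs=1e-6)


class TestPoseLigandStack:
    @pytest.mark.parametrize("dist,angle", [(3.5, 0.0), (4.0, 90.0),
                                            (3.55, 0.18), (3.81, 12.7)])
    def test_constructive_round_trip(self, ab16_extended, dist, angle):
        top, frame = ab16_extended
        ctop, cframe = pose_ligand_stack(top, frame, "ring(TYR10)", dist, angle)
        ring = ring_groups(ctop, "TYR10")[0]
        lrings = ligand_rings_from_frame(ctop, cframe.coordinates)
        # the pose is defined on the ligand's central ring (the one fused
        # to both others)
        central = max(lrings, key=lambda r: sum(len(set(r) & set(o))
                                                for o in lrings if o is not r))
        measured = ring_geometry(cframe.coordinates, ring, central)
        assert measured[0] == pytest.approx(dist, abs=1e-3)
        assert measured[1] == pytest.approx(angle, abs=1e-3)

    def test_invalid_distance(self, ab16_extended):
        top, frame = ab16_extended
        with pytest.raises(ValueError):
            pose_ligand_stack(top, frame, "ring(TYR10)", -1.0, 0.0)


class TestComposeEnsemble:
    def test_class_fractions_exact(self, helix_coil_ensemble):
        traj, truth = helix_coil_ensemble
        assert truth.classes.count("alpha") == 24
        assert truth.classes.count("coil") == 36
        assert traj.n_frames == 60

    def test_same_seed_identical(self):
        spec = EnsembleSpec(sequence=AB16[:8], n_frames=10,
                            class_fractions={"alpha": 0.5, "beta": 0.5},
                            noise_sigma=0.1, seed=13)
        t1, g1 = compose_ensemble(spec)
        t2, g2 = compose_ensemble(spec)
        np.testing.assert_array_equal(t1.coords(), t2.coords())
        assert g1.classes == g2.classes

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleSpec(sequence="AAAA", n_frames=5,
                         class_fractions={"alpha": 0.7})

    def test_infeasible_injection(self):
        # no basic residue in an all-Ala peptide
        spec = EnsembleSpec(sequence="AAEAAA", n_frames=4,
                            class_fractions={"extended": 1.0},
                            injections=[Injection("salt_bridge", 3, 5)])
        with pytest.raises(ValueError, match="infeasible"):
            compose_ensemble(spec)


class TestExchangeLogSynthesis:
    def test_full_acceptance(self):
        log = synth_exchange_log(4, 50, 1.0, seed=0)
        assert all(r.accepted for r in log.records)

    def test_exact_acceptance_count(self):
        log = synth_exchange_log(10, 1000, 0.146, seed=1)
        assert sum(r.accepted for r in log.records) == 146

    def test_closure_with_exchange_frequency(self):
        for seed in (0, 5):
            log = synth_exchange_log(6, 500, 0.2, seed=seed)
            assert exchange_frequency(log)["overall"] == pytest.approx(0.2)

    def test_too_few_replicas(self):
        with pytest.raises(ValueError):
            synth_exchange_log(1, 10, 0.5)
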