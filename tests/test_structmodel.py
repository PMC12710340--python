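"""Structure parsing, secondary structure, fold grammar, contacts, RMSD."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from rrescout import fixtures as fx
from rrescout import geometry
from rrescout import structmodel as sm
from rrescout.structmodel import FailureReason


def _ss(labels: str) -> sm.SecondaryStructureString:
    return sm.SecondaryStructureString(chain_id="A", labels=labels)


def _labels_from_spans(length, strands=(), helices=()):
    lab = ["C"] * length
    for a, b in strands:
        lab[a - 1:b] = "E" * (b - a + 1)
    for a, b in helices:
        lab[a - 1:b] = "H" * (b - a + 1)
    return "".join(lab)


# ---------------------------------------------------------------------------
# parsing

class TestParseStructure:
    def test_round_trip_fold_panel_member(self, tmp_path, fold_panel):
        name, structure, truth = fold_panel[0]
        path = tmp_path / "model.pdb"
        fx.write_pdb(structure, path)
        parsed = sm.parse_structure(path)
        assert len(parsed.chains) == 1
        assert len(parsed.chains[0]) == truth["length"]
        assert parsed.ptm == structure.ptm  # REMARK metadata round-trips
        orig = structure.chains[0].residues[3].atom("CA").coord
        back = parsed.chains[0].residues[3].atom("CA").coord
        assert np.allclose(orig, back, atol=1e-3)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      3  C   ALA A   1       2.009   1.423   0.000  1.00  0.00           C",
            "ATOM      4  CB AALA A   1       9.000   9.000   9.000  0.30  0.00           C",
            "ATOM      5  CB BALA A   1       5.000   5.000   5.000  0.70  0.00           C",
            "END",
        ])
        path = tmp_path / "alt.pdb"
        path.write_text(pdb + "\n")
        parsed = sm.parse_structure(path)
        cb = parsed.chains[0].residues[0].atom("CB")
        assert np.allclose(cb.coord, [5.0, 5.0, 5.0])

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError, match="no polymer chain"):
            sm.parse_structure(path)

    def test_waters_routed_to_ligands(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      3  C   ALA A   1       2.009   1.423   0.000  1.00  0.00           C",
            "HETATM    4  O   HOH A 101      8.000   8.000   8.000  1.00  0.00           O",
            "END",
        ])
        path = tmp_path / "wat.pdb"
        path.write_text(pdb + "\n")
        parsed = sm.parse_structure(path)
        assert len(parsed.chains[0]) == 1
        assert [r.name for r in parsed.ligands] == ["HOH"]


# ---------------------------------------------------------------------------
# secondary structure

class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self):
        helix = fx.make_ideal_helix(12)
        labels = sm.assign_secondary_structure(helix, "A").labels
        assert set(labels[2:10]) == {"H"}

    def test_helix_hbond_oracle(self):
        """The n->n+4 Kabsch-Sander energies on ideal helix geometry must
        all clear the bonding threshold (independent of the labeling code)."""
        bb = geometry.build_backbone([geometry.HELIX_PHI_PSI] * 12)
        for i in range(12 - 4):
            acc, don, dprev = bb[i], bb[i + 4], bb[i + 3]
            h = don["N"] + (dprev["C"] - dprev["O"]) / np.linalg.norm(dprev["C"] - dprev["O"])
            e = sm._ks_hbond_energy(acc["C"], acc["O"], don["N"], h)
            assert e < sm.DEFAULT_HBOND_ENERGY

    def test_antiparallel_sheet_ladder(self):
        """Two-chain ideal sheet: paired residues labeled E, and the H-bond
        set contains the symmetric antiparallel ladder pairs."""
        sheet = fx.make_sheet_complex(8)
        for cid in "AB":
            labels = sm.assign_secondary_structure(sheet, cid).labels
            assert set(labels[1:]) == {"E"}
        frames = {c.chain_id: sm._backbone_frames(c) for c in sheet.chains}
        chains = {c.chain_id: c for c in sheet.chains}
        bonds = sm._hbond_set(frames, chains, sm.DEFAULT_HBOND_ENERGY)
        inter = {(a, d) for a, d in bonds if a[0] != d[0]}
        # symmetric ladder: acceptor A_i / donor B_j and the reverse, i+j=8
        for i in (1, 3, 5, 7):
            assert (("A", i), ("B", 8 - i)) in inter
            assert (("B", i), ("A", 8 - i)) in inter

    def test_coil_stays_coil(self):
        coil = fx.make_coil(6)
        assert sm.assign_secondary_structure(coil, "A").labels == "CCCCCC"

    def test_too_short_chain_raises(self):
        tiny = fx.make_coil(3)
        with pytest.raises(ValueError, match="fewer than 5"):
            sm.assign_secondary_structure(tiny, "A")

    def test_missing_chain_raises(self):
        helix = fx.make_ideal_helix(12)
        with pytest.raises(KeyError):
            sm.assign_secondary_structure(helix, "Z")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_body_invariance(self, seed):
        """Labels depend only on internal geometry, not on the frame."""
        rng = np.random.default_rng(seed)
        torsions = geometry.torsions_for_elements(
            [("C", 2), ("E", 6), ("C", 4), ("H", 10), ("C", 2)])
        bb = geometry.build_backbone(torsions)
        chain = fx._poly_ala(bb, "A")
        before = sm.assign_secondary_structure(
            sm.ProteinStructure(chains=[chain]), "A").labels
        R = geometry.rotation_about_axis(rng.normal(size=3), float(rng.uniform(0, 360)))
        t = rng.uniform(-100, 100, size=3)
        moved = [{k: R @ v + t for k, v in r.items()} for r in bb]
        chain2 = fx._poly_ala(moved, "A")
        after = sm.assign_secondary_structure(
            sm.ProteinStructure(chains=[chain2]), "A").labels
        assert before == after


# ---------------------------------------------------------------------------
# fold grammar

class TestDetectRreFold:
    def test_canonical_positive(self):
        labels = _labels_from_spans(95, strands=[(5, 10), (15, 20), (25, 30)],
                                    helices=[(35, 50), (55, 70), (75, 90)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert cls.is_rre
        assert cls.failure_reason is FailureReason.NONE
        assert [e.ordinal for e in cls.matched_elements] == \
            ["beta1", "beta2", "beta3", "alpha1", "alpha2", "alpha3"]
        assert cls.domain_span == (5, 90)

    def test_reversed_order_rejected(self):
        labels = _labels_from_spans(95, strands=[(55, 60), (65, 70), (75, 80)],
                                    helices=[(5, 20), (25, 35), (40, 50)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert not cls.is_rre
        assert cls.failure_reason is FailureReason.WRONG_ORDER

    def test_undersized_rejected(self):
        labels = _labels_from_spans(60, strands=[(3, 6), (9, 12), (15, 18)],
                                    helices=[(21, 30), (33, 42), (45, 56)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert not cls.is_rre
        assert cls.failure_reason is FailureReason.TOO_SHORT

    def test_span_exceeded(self):
        labels = _labels_from_spans(200, strands=[(5, 10), (15, 20), (25, 30)],
                                    helices=[(120, 135), (145, 160), (170, 190)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert not cls.is_rre
        assert cls.failure_reason is FailureReason.SPAN_EXCEEDED

    def test_missing_elements(self):
        labels = _labels_from_spans(80, helices=[(5, 20), (25, 40), (45, 60), (63, 75)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert cls.failure_reason is FailureReason.MISSING_ELEMENTS

    def test_extra_elements_tolerated_and_recorded(self):
        # an extra strand between alpha1 and alpha2 does not break the grammar
        labels = _labels_from_spans(110, strands=[(5, 10), (15, 20), (25, 30), (50, 55)],
                                    helices=[(35, 45), (60, 70), (75, 85)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert cls.is_rre
        assert cls.domain_span == (5, 85)
        assert [(e.kind, e.start) for e in cls.extra_elements] == [("strand", 50)]

    def test_min_element_len_filters_short_runs(self):
        labels = _labels_from_spans(95, strands=[(5, 6), (15, 20), (25, 30)],
                                    helices=[(35, 50), (55, 70), (75, 90)])
        # 2-residue strand run does not count as beta1 -> only 2 strands
        cls = sm.detect_rre_fold(_ss(labels))
        assert cls.failure_reason is FailureReason.MISSING_ELEMENTS

    def test_earliest_match_reported(self):
        labels = _labels_from_spans(
            130,
            strands=[(5, 10), (15, 20), (25, 30), (35, 40)],
            helices=[(45, 55), (60, 70), (75, 85), (95, 105)])
        cls = sm.detect_rre_fold(_ss(labels))
        assert cls.is_rre
        assert cls.matched_elements[0].start == 5
        assert cls.matched_elements[-1].end == 85  # earliest helices, not the last one


# ---------------------------------------------------------------------------
# panel-level sensitivity/specificity

class TestFoldPanel:
    def test_perfect_separation(self, panel_classifications):
        for name, (truth, cls) in panel_classifications.items():
            assert cls.is_rre == truth["is_rre"], (name, cls.failure_reason)

    def test_decoy_failure_reasons(self, panel_classifications):
        for name, (truth, cls) in panel_classifications.items():
            if truth["class"] == "reversed":
                assert cls.failure_reason is FailureReason.WRONG_ORDER
            elif truth["class"] == "undersized":
                assert cls.failure_reason is FailureReason.TOO_SHORT


# ---------------------------------------------------------------------------
# contacts

def _one_atom_complex(distance):
    """Hand-built chain of well-separated CA-only residues, with an
    annotated element assignment, plus a one-atom peptide at exactly
    `distance` from the alpha3-start residue's CA."""
    res_a = [sm.Residue(i + 1, "ALA", [sm.Atom("CA", "C", [10.0 * i, 0.0, 0.0])])
             for i in range(10)]
    rre = sm.Chain("A", res_a)
    cls = sm.RREClassification(
        True, FailureReason.NONE,
        matched_elements=[
            sm.SSElement("strand", 1, 1, "beta1"), sm.SSElement("strand", 2, 2, "beta2"),
            sm.SSElement("strand", 3, 3, "beta3"), sm.SSElement("helix", 4, 5, "alpha1"),
            sm.SSElement("helix", 6, 7, "alpha2"), sm.SSElement("helix", 8, 9, "alpha3"),
        ], domain_span=(1, 9))
    target = res_a[7].atom("CA").coord  # alpha3 start (seq index 8)
    pep = sm.Chain("B", [sm.Residue(1, "LEU", [
        sm.Atom("CA", "C", target + np.array([0.0, distance, 0.0]))])])
    return sm.ProteinStructure(chains=[rre, pep]), cls


class TestContacts:
    def test_boundary_inside_cutoff(self):
        complex_, cls = _one_atom_complex(3.9)
        contacts = sm.map_recognition_contacts(complex_, "B", "A", cls)
        assert len(contacts) >= 1
        assert any(c.protein_element == "alpha3" and abs(c.distance - 3.9) < 1e-6
                   for c in contacts)

    def test_boundary_outside_cutoff(self):
        complex_, cls = _one_atom_complex(4.1)
        contacts = sm.map_recognition_contacts(complex_, "B", "A", cls)
        assert not any(abs(c.distance - 4.1) < 1e-6 for c in contacts)

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(7)
        res_a = [sm.Residue(i + 1, "ALA",
                            [sm.Atom("CA", "C", rng.uniform(0, 10, 3)) for _ in range(4)])
                 for i in range(5)]
        res_b = [sm.Residue(i + 1, "GLY",
                            [sm.Atom("CA", "C", rng.uniform(0, 10, 3)) for _ in range(3)])
                 for i in range(4)]
        complex_ = sm.ProteinStructure(chains=[sm.Chain("A", res_a), sm.Chain("B", res_b)])
        cls = sm.RREClassification(False, FailureReason.MISSING_ELEMENTS)
        contacts = sm.map_recognition_contacts(complex_, "B", "A", cls, cutoff=6.0)
        got = {(c.peptide_index, c.protein_index): c.distance for c in contacts}
        for pb in res_b:
            for pa in res_a:
                dmin = min(float(np.linalg.norm(x.coord - y.coord))
                           for x in pb.atoms for y in pa.atoms)
                if dmin <= 6.0:
                    assert math.isclose(got[(pb.index, pa.index)], dmin, rel_tol=1e-9)
                else:
                    assert (pb.index, pa.index) not in got

    def test_cutoff_monotonicity(self):
        complex_, cls = _one_atom_complex(3.0)
        keys = lambda cs: {(c.peptide_index, c.protein_index) for c in cs}
        small = keys(sm.map_recognition_contacts(complex_, "B", "A", cls, cutoff=3.5))
        large = keys(sm.map_recognition_contacts(complex_, "B", "A", cls, cutoff=4.5))
        assert small <= large

    def test_engages_cleft(self):
        mk = lambda el: sm.ContactRecord("B", 1, "LEU", "A", 10, "ALA", 3.5, el)
        assert not sm.peptide_engages_cleft([mk("alpha1")])
        assert sm.peptide_engages_cleft([mk("beta3")])
        assert sm.peptide_engages_cleft([mk("alpha3")])
        assert not sm.peptide_engages_cleft([])


# ---------------------------------------------------------------------------
# Kabsch

class TestKabschRmsd:
    def test_identity_is_zero(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (10, 3))
        assert sm.kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_motion_invariance_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, (8, 3))
        R = geometry.rotation_about_axis(rng.normal(size=3), float(rng.uniform(0, 360)))
        moved = pts @ R.T + rng.uniform(-20, 20, 3)
        assert sm.kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-6)
        a, b = rng.uniform(-5, 5, (6, 3)), rng.uniform(-5, 5, (6, 3))
        assert sm.kabsch_rmsd(a, b) == pytest.approx(sm.kabsch_rmsd(b, a), abs=1e-9)

    def test_matches_numerical_minimization(self):
        """4-point asymmetric fixture: direct optimization over rotations
        (axis-angle parameterization) must agree to 1e-6."""
        a = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 2]])
        b = np.array([[0.2, 0.1, 0], [2.7, 0.4, 0.2], [0.3, 2.2, -0.1], [0.8, 1.2, 2.3]])

        ac = a - a.mean(0)
        bc = b - b.mean(0)

        def objective(w):
            R = geometry.rotation_about_axis(w[:3] / np.linalg.norm(w[:3]),
                                             math.degrees(np.linalg.norm(w[:3]) * w[3]))
            d = ac @ R.T - bc
            return np.sqrt((d ** 2).sum() / len(a))

        best = min(minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
                   for x0 in ([1, 0, 0, 0.1], [0, 1, 0, 1.0], [0, 0, 1, 2.0], [1, 1, 1, 3.0]))
        assert sm.kabsch_rmsd(a, b) == pytest.approx(best, abs=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError):
            sm.kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            sm.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# confidence filter

class TestConfidenceFilter:
    def test_boundaries_and_missing(self):
        mk = lambda ptm: sm.ProteinStructure(
            chains=[fx.make_coil(5).chains[0]], ptm=ptm)
        at, below, nothing = mk(0.60), mk(0.59), mk(None)
        out = sm.model_confidence_filter([at, below, nothing])
        assert out["retained"] == [at]
        assert out["removed"] == [below]
        assert out["needs_review"] == [nothing]
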