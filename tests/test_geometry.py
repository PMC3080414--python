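"""Distances, dihedrals, omega/chi classification, contacts, B-factors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cnbdkit import (Atom, Chain, Residue, StructureModel, bfactor_profile,
                     build_dipeptide, build_polyalanine, build_purine_nucleotide,
                     classify_omega, collapse_leu_cd, dihedral, distance,
                     find_contacts, find_disulfide_candidates, glycosidic_chi,
                     peptide_omega_scan)


def oracle_dihedral(p1, p2, p3, p4):
    """Two-plane normal-vector formula: arccos of the normals' cosine with
    the sign taken from the first normal against the third bond."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosv = np.clip(np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2)), -1, 1)
    ang = np.degrees(np.arccos(cosv))
    return -ang if np.dot(n1, b3) < 0 else ang


class TestDistance:
    def test_identity_and_pythagoras(self):
        assert distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)

    def test_symmetry_and_finite_check(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert distance(a, b) == pytest.approx(distance(b, a))
        with pytest.raises(ValueError):
            distance([np.nan, 0, 0], [0, 0, 0])


class TestDihedral:
    def test_cis_and_trans_limits(self):
        # planar zig-zag, all four atoms eclipsed on one side -> 0
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)
        # ideal extended arrangement -> 180
        assert abs(dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])) == pytest.approx(180.0)

    def test_against_plane_normal_oracle(self, rng):
        for _ in range(1000):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                got = dihedral(*pts)
            except ValueError:
                continue
            assert got == pytest.approx(oracle_dihedral(*pts), abs=1e-9)

    def test_rigid_invariance_and_mirror_negation(self, rng):
        pts = rng.normal(scale=3.0, size=(4, 3))
        ref = dihedral(*pts)
        for _ in range(100):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(scale=10.0, size=3)
            moved = pts @ R.T + t
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-ref, abs=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 1, 0])
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestOmegaScan:
    @pytest.mark.parametrize("omega,expected", [
        (0.0, "cis"), (180.0, "trans"), (29.9, "cis"), (30.1, "ambiguous"),
        (-29.9, "cis"), (150.1, "trans"), (149.9, "ambiguous"),
    ])
    def test_window_classification(self, omega, expected):
        model = build_dipeptide(omega)
        links = peptide_omega_scan(model.chains[0])
        assert len(links) == 1
        assert links[0].classification == expected
        assert links[0].omega == pytest.approx(omega, abs=1e-6)

    def test_proline_flagged(self):
        model = build_dipeptide(0.0, residue_names=("LEU", "PRO"))
        assert peptide_omega_scan(model.chains[0])[0].involves_proline

    def test_trans_helix_has_no_cis_links(self, helix):
        links = peptide_omega_scan(helix.chains[0])
        assert len(links) == 29
        assert not any(l.is_cis for l in links)

    def test_incomplete_backbone_skipped(self, helix):
        chain = helix.chains[0]
        chain.residues[5].atoms = [a for a in chain.residues[5].atoms if a.name != "CA"]
        links = peptide_omega_scan(chain)
        assert len(links) == 27  # links (5,6) and (6,7) gone

    def test_classify_omega_wraps(self):
        assert classify_omega(-179.0) == "trans"
        assert classify_omega(359.0) == "cis"


class TestGlycosidicChi:
    @pytest.mark.parametrize("chi,base,expected", [
        (45.0, "guanine", "syn"), (-150.0, "adenine", "anti"),
        (90.0, "guanine", "syn"), (-90.0, "guanine", "syn"),
        (90.0001, "guanine", "anti"), (-90.0001, "guanine", "anti"),
        (0.0, "adenine", "syn"), (180.0, "adenine", "anti"),
    ])
    def test_classification_including_boundary(self, chi, base, expected):
        rec = glycosidic_chi(build_purine_nucleotide(chi, base=base))
        assert rec.classification == expected
        assert rec.angle == pytest.approx(chi, abs=1e-6)

    def test_missing_atom_named_in_error(self):
        lig = build_purine_nucleotide(45.0)
        lig.atoms = [a for a in lig.atoms if a.name != "N9"]
        with pytest.raises(KeyError, match="N9"):
            glycosidic_chi(lig)


class TestContacts:
    def test_out_of_range_is_empty(self):
        far = Residue(name="GLY", seq_number=1, atoms=[
            Atom(name="N", element="N", position=[10.0, 0, 0])])
        lig = Residue(name="PCG", seq_number=2, is_hetero=True, atoms=[
            Atom(name="O6", element="O", position=[0.0, 0, 0])])
        model = StructureModel(chains=[Chain("A", [far]), Chain("L", [lig])])
        assert find_contacts(model, lig, 3.5, 4.0) == []

    def test_matches_brute_force_all_pairs_oracle(self, nucleotide_pocket):
        model, lig = nucleotide_pocket
        got = {(r.residue, r.protein_atom, r.ligand_atom,
                round(r.distance, 9), r.contact_class)
               for r in find_contacts(model, lig)}
        expect = set()
        lig_atoms = lig.preferred_atoms()
        for ch in model.chains:
            for res in ch.residues:
                if res.is_hetero or res is lig:
                    continue
                for pa in res.preferred_atoms():
                    for la in lig_atoms:
                        d = distance(pa.position, la.position)
                        if d <= 4.0:
                            cls = ("hydrogen_bond"
                                   if d <= 3.5 and pa.element in "NO" and la.element in "NO"
                                   else "vdw")
                            expect.add((f"{res.name}{res.seq_number}", pa.key,
                                        la.key, round(d, 9), cls))
        assert got == expect

    def test_classification_partition_and_flags(self, nucleotide_pocket):
        model, lig = nucleotide_pocket
        recs = find_contacts(model, lig)
        assert recs, "pocket fixture must produce contacts"
        assert all(r.contact_class in ("hydrogen_bond", "vdw") for r in recs)
        n7 = [r for r in recs if r.residue == "THR193" and r.ligand_atom == "N7"]
        assert n7 and n7[0].contact_class == "hydrogen_bond"
        assert n7[0].site_label == "site2"
        sg = [r for r in recs if r.protein_atom == "SG" and r.ligand_atom == "N7"]
        assert sg and sg[0].contact_class == "vdw" and sg[0].extended
        assert sg[0].site_label == "site3"

    def test_ligand_not_in_model_raises(self, nucleotide_pocket):
        model, _ = nucleotide_pocket
        stray = build_purine_nucleotide(0.0)
        with pytest.raises(LookupError):
            find_contacts(model, stray)

    def test_bad_cutoffs_rejected(self, nucleotide_pocket):
        model, lig = nucleotide_pocket
        with pytest.raises(ValueError):
            find_contacts(model, lig, hbond_cutoff=4.0, vdw_cutoff=3.5)

    def test_leucine_cd_minimum_collapse(self):
        lig = Residue(name="PCG", seq_number=9, is_hetero=True, atoms=[
            Atom(name="O6", element="O", position=[0.0, 0, 0])])
        leu = Residue(name="LEU", seq_number=172, atoms=[
            Atom(name="CD1", element="C", position=[3.1, 0, 0]),
            Atom(name="CD2", element="C", position=[3.8, 0, 0]),
        ])
        model = StructureModel(chains=[Chain("A", [leu]), Chain("L", [lig])])
        collapsed = collapse_leu_cd(find_contacts(model, lig))
        assert len(collapsed) == 1
        assert collapsed[0].protein_atom == "CD(min)"
        assert collapsed[0].distance == pytest.approx(3.1)


class TestDisulfide:
    def _cys(self, seq, pos):
        return Residue(name="CYS", seq_number=seq, atoms=[
            Atom(name="SG", element="S", position=pos)])

    def test_single_cysteine_empty(self):
        model = StructureModel(chains=[Chain("A", [self._cys(133, [0, 0, 0])])])
        assert find_disulfide_candidates(model) == []

    def test_bonded_distance_pair_reported(self):
        model = StructureModel(chains=[Chain("A", [
            self._cys(133, [0, 0, 0]), self._cys(211, [2.05, 0, 0])])])
        pairs = find_disulfide_candidates(model)
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(2.05)

    def test_cross_chain_pairs_and_cutoff(self):
        model = StructureModel(chains=[
            Chain("A", [self._cys(133, [0, 0, 0])]),
            Chain("B", [self._cys(133, [4.4, 0, 0])]),
        ])
        assert len(find_disulfide_candidates(model, 4.5)) == 1
        assert find_disulfide_candidates(model, 4.0) == []


class TestBFactorProfile:
    def _chain(self, bvals):
        residues = []
        for i, b in enumerate(bvals, start=1):
            residues.append(Residue(name="ALA", seq_number=i, atoms=[
                Atom(name="CA", element="C", position=[float(i), 0, 0], b_factor=b)]))
        return Chain("A", residues)

    def test_constant_chain(self):
        prof = bfactor_profile(self._chain([50.0] * 10), {"all": (1, 10)})
        assert all(b == 50.0 for _, b in prof.entries)
        assert prof.region_means["all"] == pytest.approx(50.0)
        assert prof.chain_mean == pytest.approx(50.0)

    def test_region_mean_closed_form(self):
        prof = bfactor_profile(self._chain([float(i) for i in range(1, 21)]),
                               {"mid": (5, 10)})
        assert prof.region_means["mid"] == pytest.approx(np.mean([5, 6, 7, 8, 9, 10]))

    def test_span_outside_chain_flagged_none(self):
        prof = bfactor_profile(self._chain([1.0, 2.0]), {"ghost": (100, 110)})
        assert prof.region_means["ghost"] is None

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            bfactor_profile(Chain("A", []))
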