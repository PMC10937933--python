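"""Interface geometry: planes, torsions, contacts, bonds, stacking, pucker.

Independent oracles used here: an eigen-decomposition plane fit, a
sign-from-triple-product dihedral, a grid-search pseudorotation phase fit,
and brute-force all-pairs contact enumeration.
"""

import itertools
import math

import numpy as np
import pytest

from conftest import apply_rigid, rigid_transform
from xlink3d import fixtures as fx
from xlink3d.geometry import (ContactConfig, DegeneratePlaneError,
                              GeometryConfig, PUCKER_CLASSES, base_orientation,
                              detect_hbonds, detect_pseudo_pairs,
                              detect_stacking, dihedral, fit_plane,
                              heavy_atom_contacts, pucker_from_torsions,
                              residue_min_distance, rna_pairing_context,
                              sugar_pucker)
from xlink3d.structure import Atom, Chain, ComplexStructure, Residue


# --- independent oracles ----------------------------------------------------

def dihedral_oracle(p0, p1, p2, p3):
    """Four-point torsion via normals + triple-product sign."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


def plane_normal_oracle(coords):
    """Smallest principal axis of the centered covariance matrix."""
    coords = np.asarray(coords, float)
    centered = coords - coords.mean(axis=0)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    return evecs[:, 0]


def phase_oracle(residue):
    """Grid-search fit of nu_j = tau_m cos(P + 144 (j - 2)) to the five ring
    torsions, torsions computed with the independent dihedral."""
    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    c = {n: residue.atom(n).xyz for n in names}
    quads = [("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
             ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
             ("C3'", "C4'", "O4'", "C1'")]
    nu = np.array([dihedral_oracle(*(c[n] for n in q)) for q in quads])
    best_p, best_sse = None, np.inf
    for p in np.arange(0.0, 360.0, 0.02):
        cj = np.cos(np.radians(p + 144.0 * (np.arange(5) - 2)))
        tau = float(nu @ cj) / float(cj @ cj)
        if tau < 0:
            continue
        sse = float(((nu - tau * cj) ** 2).sum())
        if sse < best_sse:
            best_p, best_sse = p, sse
    return best_p


# --- fit_plane --------------------------------------------------------------

def test_three_points_define_exact_plane():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
    _, _, rmsd = fit_plane(pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_hexagon_in_z_plane():
    ang = np.radians(np.arange(6) * 60.0)
    pts = np.column_stack([np.cos(ang), np.sin(ang), np.ones(6)])
    centroid, normal, rmsd = fit_plane(pts)
    assert centroid[2] == pytest.approx(1.0)
    assert np.allclose(normal, [0, 0, 1])
    assert rmsd == pytest.approx(0.0, abs=1e-12)


def test_perturbed_plane_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(4)
    pts = np.column_stack([rng.normal(size=(10, 2)),
                           np.zeros(10)]) + rng.normal(scale=0.05, size=(10, 3))
    _, normal, _ = fit_plane(pts)
    oracle = plane_normal_oracle(pts)
    assert min(np.linalg.norm(normal - oracle),
               np.linalg.norm(normal + oracle)) < 1e-9


def test_collinear_points_rejected():
    pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], float)
    with pytest.raises(DegeneratePlaneError):
        fit_plane(pts)


def test_dihedral_agrees_with_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        pts = rng.normal(size=(4, 3))
        assert dihedral(*pts) == pytest.approx(dihedral_oracle(*pts), abs=1e-9)


# --- contacts ---------------------------------------------------------------

def _pair_structure(d, extra_h=False):
    """Minimal controlled pair: guanine N7 at exactly d from an alanine CB."""
    nt = Residue("R", 1, "G", atoms=[Atom("N7", "N", [0.0, 0.0, 0.0]),
                                     Atom("C8", "C", [-1.3, 0.6, 0.0])])
    atoms = [Atom("CB", "C", [d, 0.0, 0.0]),
             Atom("CA", "C", [d + 1.5, 0.0, 0.0]),
             Atom("N", "N", [d + 2.4, 1.1, 0.0])]
    if extra_h:
        atoms.append(Atom("HB1", "H", [1.0, 0.0, 0.0]))
    aa = Residue("P", 1, "ALA", atoms=atoms)
    return ComplexStructure("pair", [Chain("R", [nt]), Chain("P", [aa])]), nt, aa


@pytest.mark.parametrize("d,expected", [(4.5, 1), (4.51, 0), (3.0, 1)])
def test_contact_cutoff_is_inclusive(d, expected):
    st, _, _ = _pair_structure(d)
    recs = heavy_atom_contacts(st, ContactConfig(4.5))
    assert len(recs) == expected
    if expected:
        assert recs[0].min_distance == pytest.approx(d, abs=1e-9)


def test_hydrogens_excluded_from_min_distance():
    st, nt, aa = _pair_structure(3.0, extra_h=True)
    recs = heavy_atom_contacts(st)
    assert recs[0].min_distance == pytest.approx(3.0, abs=1e-9)


def test_contacts_match_brute_force_all_pairs(stack_fixture):
    structures = [stack_fixture, fx.make_demo_complex()]
    for st in structures:
        recs = heavy_atom_contacts(st)
        got = {(r.nt.key, r.aa.key): r.min_distance for r in recs}
        expected = {}
        for nt in st.rna_residues():
            for aa in st.protein_residues():
                best = np.inf
                for a in nt.heavy_atoms():
                    for b in aa.heavy_atoms():
                        best = min(best, float(np.linalg.norm(a.xyz - b.xyz)))
                if best <= 4.5:
                    expected[(nt.key, aa.key)] = best
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)


# --- hydrogen bonds ---------------------------------------------------------

def test_arg_phosphate_hbond_typed_sidechain():
    st = fx.make_hbond_fixture("ARG", "NH1", "G", "OP1", 2.9)
    bonds = [b for b in detect_hbonds(st) if b.rna_atom == "OP1"]
    assert len(bonds) == 1
    b = bonds[0]
    assert (b.rna_moiety, b.protein_moiety) == ("phosphate", "sidechain")
    assert b.distance == pytest.approx(2.9, abs=1e-6)


def test_hbond_beyond_cutoff_absent():
    st = fx.make_hbond_fixture("ARG", "NH1", "G", "OP1", 3.8)
    assert detect_hbonds(st) == []


def test_backbone_to_base_hbond_typed():
    st = fx.make_hbond_fixture("GLY", "N", "U", "O2", 3.0)
    bonds = [b for b in detect_hbonds(st) if b.rna_atom == "O2"
             and b.protein_atom == "N"]
    assert len(bonds) == 1
    assert (bonds[0].rna_moiety, bonds[0].protein_moiety) == ("base", "backbone")


# --- sugar pucker -----------------------------------------------------------

@pytest.mark.parametrize("P,klass,family",
                         [(162.0, "C2'-endo", "S"), (18.0, "C3'-endo", "N")])
def test_pucker_from_synthesized_torsions(P, klass, family):
    tau = 38.0
    nu = tuple(tau * math.cos(math.radians(P + 144.0 * (j - 2)))
               for j in range(5))
    pk = pucker_from_torsions(nu)
    assert pk.P == pytest.approx(P, abs=0.01)
    assert pk.tau_m == pytest.approx(tau, abs=0.01)
    assert pk.pucker_class == klass
    assert pk.family == family


def test_ribose_fixture_phase_matches_grid_oracle():
    for target in (10.0, 100.0, 250.0):
        res = fx.make_ribose(target)
        pk = sugar_pucker(res)
        oracle = phase_oracle(res)
        diff = abs((pk.P - oracle + 180.0) % 360.0 - 180.0)
        assert diff < 1.0
        assert abs((pk.P - target + 180.0) % 360.0 - 180.0) < 1.0


def test_pucker_classes_partition_the_circle():
    for P in np.arange(0.0, 360.0, 3.6):
        nu = tuple(38.0 * math.cos(math.radians(P + 144.0 * (j - 2)))
                   for j in range(5))
        pk = pucker_from_torsions(nu)
        assert pk.pucker_class == PUCKER_CLASSES[int(P // 36) % 10]
        assert pk.family == ("N" if (P >= 270 or P < 90) else "S")


def test_missing_ring_atom_marks_pucker_missing():
    res = fx.make_ribose(18.0)
    res.atoms = [a for a in res.atoms if a.name != "C3'"]
    assert sugar_pucker(res) is None


# --- base orientation -------------------------------------------------------

@pytest.mark.parametrize("chi,orientation",
                         [(-160.0, "anti"), (45.0, "syn"), (180.0, "anti")])
def test_chi_recovery_and_orientation(chi, orientation):
    for base in ("G", "C"):
        nt = fx.make_nucleotide(base, chi=chi)
        bo = base_orientation(nt)
        assert bo.orientation == orientation
        names = {"G": ("O4'", "C1'", "N9", "C4"),
                 "C": ("O4'", "C1'", "N1", "C2")}[base]
        oracle = dihedral_oracle(*(nt.atom(n).xyz for n in names))
        assert bo.chi == pytest.approx(oracle, abs=1e-6)
        assert abs(abs(bo.chi) - abs(chi)) < 1e-6


# --- stacking & pseudo pairs ------------------------------------------------

def test_stack_fixture_detected_with_recovered_geometry(stack_fixture):
    stacks = [s for s in detect_stacking(stack_fixture)
              if s.partner_kind != "nucleotide-base"]
    assert len(stacks) == 1
    s = stacks[0]
    assert s.partner_kind == "aromatic-sidechain"
    assert s.interplane_angle == pytest.approx(0.0, abs=1.0)
    assert s.vertical_sep == pytest.approx(3.4, abs=0.05)
    assert s.lateral_offset == pytest.approx(0.5, abs=0.05)


@pytest.mark.parametrize("angle,vertical,lateral,expected", [
    (80.0, 3.4, 0.5, 0),    # too tilted
    (0.0, 5.2, 0.5, 0),     # too far
    (0.0, 1.2, 0.5, 0),     # clash region / below vertical window
    (0.0, 3.4, 3.5, 0),     # slid off
    (20.0, 3.0, 1.0, 1),    # inside all gates
])
def test_stacking_thresholds(angle, vertical, lateral, expected):
    try:
        st = fx.make_stack_fixture(fx.StackFixtureSpec(
            "G", "PHE", interplane_angle=angle, vertical_sep=vertical,
            lateral_offset=lateral))
    except ValueError:
        assert expected == 0  # unrealizable geometry (clash) cannot stack
        return
    stacks = [s for s in detect_stacking(st)
              if s.partner_kind != "nucleotide-base"]
    assert len(stacks) == expected


def test_peptide_bond_stacking_partner_kind():
    st = fx.make_stack_fixture(fx.StackFixtureSpec(
        "U", "peptide", peptide_residues=("GLY", "ALA"),
        interplane_angle=0.0, vertical_sep=3.5, lateral_offset=0.5))
    stacks = [s for s in detect_stacking(st)
              if s.partner_kind != "nucleotide-base"]
    assert len(stacks) == 1
    assert stacks[0].partner_kind == "peptide-bond"
    assert len(stacks[0].partners) == 2


def test_guanidinium_stacking_partner_kind():
    st = fx.make_stack_fixture(fx.StackFixtureSpec(
        "U", "ARG", interplane_angle=0.0, vertical_sep=3.4,
        lateral_offset=0.3))
    kinds = {s.partner_kind for s in detect_stacking(st)}
    assert "guanidinium" in kinds


def test_pseudo_pair_coplanar_detected():
    st = fx.make_pseudo_pair_fixture(vertical=0.0)
    pairs = detect_pseudo_pairs(st)
    assert len(pairs) == 1
    assert pairs[0].n_hbonds >= 2
    assert pairs[0].vertical_sep < 0.1


def test_lifted_group_is_stack_not_pseudo_pair():
    st = fx.make_pseudo_pair_fixture(vertical=3.4)
    assert detect_pseudo_pairs(st) == []
    assert any(s.partner_kind == "guanidinium" for s in detect_stacking(st))


def test_single_hbond_is_not_a_pseudo_pair():
    # coplanar Ser OG near G O6: one bond only, no planar multi-bond group
    nt_lay = fx._with_c1("G", fx.base_layout("G"))
    nt = fx._residue("R", 1, "G", nt_lay)
    og = nt_lay["O6"] + np.array([2.9, 0.0, 0.0])
    aa = Residue("P", 1, "ASN", atoms=[Atom("CG", "C", og + [1.4, 1.2, 0]),
                                 Atom("OD1", "O", og + [2.0, 2.2, 0]),
                                 Atom("ND2", "N", og)])
    st = ComplexStructure("onehb", [Chain("R", [nt]), Chain("P", [aa])])
    bonds = detect_hbonds(st)
    assert len(bonds) == 1
    assert detect_pseudo_pairs(st) == []


# --- RNA pairing context ----------------------------------------------------

def test_single_strand_is_unpaired_ss():
    nts = []
    for i, b in enumerate("ACGUACG"):
        nt = fx.make_nucleotide(b, seq_id=i + 1)
        for a in nt.atoms:
            a.xyz = a.xyz + np.array([9.0 * i, 0.0, 0.0])
        nts.append(nt)
    st = ComplexStructure("ss7", [Chain("R", nts)])
    sec = rna_pairing_context(st)
    assert len(sec) == 7
    assert all(not v.paired for v in sec.values())
    assert all(v.element == "isolated-ss" for v in sec.values())


def test_hairpin_pairing_hand_enumerated(hairpin):
    sec = rna_pairing_context(hairpin)
    by_seq = {key[1]: v for key, v in sec.items()}
    # stem: 1..4 pair 12..9; loop: 5..8
    for i in (1, 2, 3, 4, 9, 10, 11, 12):
        assert by_seq[i].paired
    for i in (5, 6, 7, 8):
        assert not by_seq[i].paired
        assert by_seq[i].element == "hairpin-loop"
    assert sum(v.paired for v in sec.values()) == 8
    # pairs at the helix boundary are ends, inner ones internal
    assert by_seq[1].element == "helix-end"
    assert by_seq[4].element == "helix-end"
    assert by_seq[2].element == "helix-internal"
    assert by_seq[3].element == "helix-internal"
    # untwisted ladder: stem neighbors stack
    assert by_seq[2].stacked_5p and by_seq[2].stacked_3p


# --- rigid-body invariance --------------------------------------------------

def test_rigid_body_invariance(stack_fixture):
    rng = np.random.default_rng(123)
    st = stack_fixture
    moved = apply_rigid(st, rigid_transform(rng))
    c0 = heavy_atom_contacts(st)
    c1 = heavy_atom_contacts(moved)
    assert len(c0) == len(c1)
    for a, b in zip(c0, c1):
        assert a.min_distance == pytest.approx(b.min_distance, abs=1e-6)
    s0 = [s for s in detect_stacking(st) if s.partner_kind != "nucleotide-base"]
    s1 = [s for s in detect_stacking(moved) if s.partner_kind != "nucleotide-base"]
    assert len(s0) == len(s1) == 1
    assert s0[0].interplane_angle == pytest.approx(s1[0].interplane_angle, abs=1e-6)
    assert s0[0].vertical_sep == pytest.approx(s1[0].vertical_sep, abs=1e-6)

    nt = fx.make_nucleotide("G", P=162.0, chi=-120.0)
    moved_nt = apply_rigid(
        ComplexStructure("x", [Chain("R", [nt])]), rigid_transform(rng)
    ).chains[0].residues[0]
    assert sugar_pucker(nt).P == pytest.approx(sugar_pucker(moved_nt).P, abs=1e-6)
    assert base_orientation(nt).chi == pytest.approx(
        base_orientation(moved_nt).chi, abs=1e-6)
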