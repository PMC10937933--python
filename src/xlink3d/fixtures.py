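"""Synthetic structures and simulated feature tables.

Everything needed to exercise the package without downloading coordinates:

* idealized planar base / side-chain layouts posed at requested stacking
  geometry (:func:`make_stack_fixture`),
* riboses built at a target pseudorotation phase (:func:`make_ribose`),
* full nucleotides with a posed glycosidic torsion (:func:`make_nucleotide`),
* donor-acceptor pairs at a requested distance (:func:`make_hbond_fixture`),
* a Watson-Crick hairpin with a known pairing table (:func:`make_hairpin`),
* labeled feature tables with injected logistic signal
  (:func:`simulate_feature_table`).

Ring geometry uses standard small-molecule bond lengths (aromatic C-C/C-N
~1.39 A, glycosidic C1'-N 1.47 A, C=O 1.23 A); fixtures are idealized, not
force-field relaxed. The closing loop is that the geometry module must
recover each fixture's constructed parameters within its stated tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import chem
from .geometry import dihedral, pucker_from_torsions, sugar_pucker
from .structure import Atom, Chain, ComplexStructure, Residue

RING_BOND = 1.39          # aromatic ring bond, Angstrom
GLYCOSIDIC_BOND = 1.47
EXOCYCLIC_BOND = 1.30     # ring-substituent N/O bond (averaged)


# --- elementary constructors ------------------------------------------------

def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom X bonded to c.

    |cX| = bond, angle(b, c, X) = angle_deg, torsion(a, b, c, X) = torsion_deg.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _polygon(n: int, side: float, start_angle_deg: float = 90.0) -> np.ndarray:
    """Regular n-gon in the z=0 plane, centered at origin."""
    radius = side / (2.0 * math.sin(math.pi / n))
    angles = np.radians(start_angle_deg + 360.0 * np.arange(n) / n)
    return np.column_stack([radius * np.cos(angles), radius * np.sin(angles),
                            np.zeros(n)])


def _fused_ring(p1: np.ndarray, p2: np.ndarray, hexagon_centroid: np.ndarray,
                n: int, n_new: int, side: float) -> np.ndarray:
    """Vertices of an n-gon fused on edge p1-p2, on the far side of the
    existing ring; returns the n_new new vertices walking from p1 away
    from p2."""
    mid = 0.5 * (p1 + p2)
    u = mid - hexagon_centroid
    u = u / np.linalg.norm(u)
    apothem = side / (2.0 * math.tan(math.pi / n))
    center = mid + u * apothem
    radius = side / (2.0 * math.sin(math.pi / n))
    t1 = math.atan2(p1[1] - center[1], p1[0] - center[0])
    t2 = math.atan2(p2[1] - center[1], p2[0] - center[0])
    step = 2.0 * math.pi / n
    # walk from p1 in the direction away from p2
    diff = (t2 - t1 + math.pi) % (2 * math.pi) - math.pi
    sgn = -1.0 if diff > 0 else 1.0
    out = []
    for k in range(1, n_new + 1):
        t = t1 + sgn * step * k
        out.append(center + radius * np.array([math.cos(t), math.sin(t), 0.0]))
    return np.array(out)


def base_layout(base: str) -> dict[str, np.ndarray]:
    """Idealized planar heavy-atom layout of one base, z = 0.

    Regular-polygon ring geometry with radial exocyclic substituents; ring
    atom names follow PDB convention.
    """
    base = chem.canonical_residue_name(base)
    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    hexagon = _polygon(6, RING_BOND)
    coords = {n: hexagon[i] for i, n in enumerate(hex_names)}
    centroid = hexagon.mean(axis=0)

    def radial(anchor: str, r: float) -> np.ndarray:
        u = coords[anchor] - centroid
        return coords[anchor] + r * u / np.linalg.norm(u)

    if base in chem.PURINES:
        newv = _fused_ring(coords["C4"], coords["C5"], centroid, 5, 3, RING_BOND)
        coords["N9"], coords["C8"], coords["N7"] = newv
        if base == "A":
            coords["N6"] = radial("C6", EXOCYCLIC_BOND)
        else:  # G
            coords["O6"] = radial("C6", EXOCYCLIC_BOND)
            coords["N2"] = radial("C2", EXOCYCLIC_BOND)
    elif base == "C":
        coords["O2"] = radial("C2", EXOCYCLIC_BOND)
        coords["N4"] = radial("C4", EXOCYCLIC_BOND)
    elif base == "U":
        coords["O2"] = radial("C2", EXOCYCLIC_BOND)
        coords["O4"] = radial("C4", EXOCYCLIC_BOND)
    else:
        raise ValueError(f"unknown base {base!r}")
    return coords


_AA_ELEMENT = {"C": "C", "N": "N", "O": "O", "S": "S", "P": "P"}


def _element_of(atom_name: str) -> str:
    return _AA_ELEMENT.get(atom_name[0], "C")


def _residue(chain_id: str, seq_id: int, name: str,
             coords: dict[str, np.ndarray]) -> Residue:
    atoms = [Atom(name=k, element=_element_of(k), xyz=np.asarray(v, float))
             for k, v in coords.items()]
    return Residue(chain_id=chain_id, seq_id=seq_id, name=name, atoms=atoms)


def sidechain_layout(resname: str) -> dict[str, np.ndarray]:
    """Planar side-chain moiety layout (z = 0) for stacking/pairing fixtures."""
    resname = resname.upper()
    if resname in ("PHE", "TYR"):
        ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        hexagon = _polygon(6, RING_BOND)
        coords = {n: hexagon[i] for i, n in enumerate(ring_names)}
        centroid = hexagon.mean(axis=0)
        u = coords["CG"] - centroid
        coords["CB"] = coords["CG"] + 1.51 * u / np.linalg.norm(u)
        if resname == "TYR":
            u = coords["CZ"] - centroid
            coords["OH"] = coords["CZ"] + 1.36 * u / np.linalg.norm(u)
        return coords
    if resname == "HIS":
        names = ["CG", "ND1", "CE1", "NE2", "CD2"]
        pent = _polygon(5, RING_BOND)
        coords = {n: pent[i] for i, n in enumerate(names)}
        centroid = pent.mean(axis=0)
        u = coords["CG"] - centroid
        coords["CB"] = coords["CG"] + 1.51 * u / np.linalg.norm(u)
        return coords
    if resname == "TRP":
        pent_names = ["CG", "CD1", "NE1", "CE2", "CD2"]
        pent = _polygon(5, RING_BOND)
        coords = {n: pent[i] for i, n in enumerate(pent_names)}
        centroid = pent.mean(axis=0)
        newv = _fused_ring(coords["CE2"], coords["CD2"], centroid, 6, 4, RING_BOND)
        coords["CZ2"], coords["CH2"], coords["CZ3"], coords["CE3"] = newv
        u = coords["CG"] - centroid
        coords["CB"] = coords["CG"] + 1.51 * u / np.linalg.norm(u)
        return coords
    if resname == "ARG":
        coords = {"CZ": np.zeros(3)}
        for name, ang in (("NE", 90.0), ("NH1", 210.0), ("NH2", 330.0)):
            coords[name] = 1.33 * np.array([math.cos(math.radians(ang)),
                                            math.sin(math.radians(ang)), 0.0])
        u = coords["NE"] / np.linalg.norm(coords["NE"])
        coords["CD"] = coords["NE"] + 1.46 * u
        return coords
    raise ValueError(f"no planar layout for {resname!r}")


def peptide_layout() -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Two consecutive backbone units forming a planar peptide bond (z = 0)."""
    res1 = {
        "N":  np.array([-2.75, 0.85, 0.0]),
        "CA": np.array([-1.52, 0.00, 0.0]),
        "C":  np.array([0.00, 0.00, 0.0]),
        "O":  np.array([0.47, 1.14, 0.0]),
    }
    res2 = {
        "N":  np.array([1.33, 0.00, 0.0]),
        "CA": np.array([2.06, -1.20, 0.0]),
        "C":  np.array([3.52, -1.05, 0.0]),
        "O":  np.array([4.10, 0.02, 0.0]),
    }
    return res1, res2


# --- ribose at a target pseudorotation --------------------------------------

_RING_ORDER = ["C1'", "C2'", "C3'", "C4'", "O4'"]


def _ribose_ring_coords(phase_rad: float, q: float) -> dict[str, np.ndarray]:
    """Pentagon ring with Cremer-Pople-style out-of-plane displacements."""
    ring = _polygon(5, 1.43)
    coords = {}
    for j, name in enumerate(_RING_ORDER):
        z = q * math.sqrt(2.0 / 5.0) * math.cos(phase_rad + 4.0 * math.pi * j / 5.0)
        coords[name] = ring[j] + np.array([0.0, 0.0, z])
    return coords


def _ring_pucker(coords: dict[str, np.ndarray]):
    nu = tuple(dihedral(coords[a], coords[b], coords[c], coords[d])
               for a, b, c, d in (("C4'", "O4'", "C1'", "C2'"),
                                  ("O4'", "C1'", "C2'", "C3'"),
                                  ("C1'", "C2'", "C3'", "C4'"),
                                  ("C2'", "C3'", "C4'", "O4'"),
                                  ("C3'", "C4'", "O4'", "C1'")))
    return pucker_from_torsions(nu)


def make_ribose(P: float, tau_m: float = 38.0, chain_id: str = "R",
                seq_id: int = 1, name: str = "U") -> Residue:
    """Build a ribose ring whose recovered pseudorotation phase is P (deg).

    tau_m must lie in (20, 50) degrees. The ring is found by least-squares
    adjustment of an out-of-plane displacement model until the analyzer's
    Altona-Sundaralingam phase matches the target (closing the generator /
    analyzer loop to well under a degree).
    """
    if not (20.0 < tau_m < 50.0):
        raise ValueError("tau_m must be in (20, 50) degrees")
    target_P = P % 360.0

    def residuals(params):
        phase, q = params
        pk = _ring_pucker(_ribose_ring_coords(phase, abs(q)))
        dP = (pk.P - target_P + 180.0) % 360.0 - 180.0
        return [dP / 10.0, (pk.tau_m - tau_m) / 10.0]

    best = None
    for offset in (0.0, 90.0, 180.0, 270.0):
        x0 = [math.radians(target_P + offset), tau_m / 102.5]
        sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    coords = _ribose_ring_coords(best.x[0], abs(best.x[1]))
    # exocyclic O2' so the residue classifies as a ribonucleotide
    coords["O2'"] = place_atom(coords["C3'"], coords["C1'"], coords["C2'"],
                               1.41, 113.0, -120.0)
    return _residue(chain_id, seq_id, name, coords)


def make_nucleotide(base: str = "G", P: float = 18.0, tau_m: float = 38.0,
                    chi: float = -120.0, chain_id: str = "R", seq_id: int = 1,
                    with_phosphate: bool = True) -> Residue:
    """Full idealized ribonucleotide: ribose at phase P, base posed at chi.

    chi is the glycosidic torsion O4'-C1'-N9-C4 (purines) or O4'-C1'-N1-C2
    (pyrimidines), in degrees.
    """
    base = chem.canonical_residue_name(base)
    sugar = {a.name: a.xyz for a in make_ribose(P, tau_m).atoms}
    coords = dict(sugar)
    if with_phosphate:
        coords["C5'"] = place_atom(coords["C2'"], coords["C3'"], coords["C4'"],
                                   1.51, 116.0, -65.0)
        coords["O5'"] = place_atom(coords["C3'"], coords["C4'"], coords["C5'"],
                                   1.42, 111.0, 180.0)
        coords["P"] = place_atom(coords["C4'"], coords["C5'"], coords["O5'"],
                                 1.60, 120.0, 180.0)
        coords["OP1"] = place_atom(coords["C5'"], coords["O5'"], coords["P"],
                                   1.48, 108.0, 60.0)
        coords["OP2"] = place_atom(coords["C5'"], coords["O5'"], coords["P"],
                                   1.48, 108.0, -60.0)
        coords["O3'"] = place_atom(coords["C1'"], coords["C2'"], coords["C3'"],
                                   1.42, 110.0, -100.0)

    local = base_layout(base)
    n_name = chem.GLYCOSIDIC_N[base]
    chi_atom = chem.CHI_ATOMS[base][3]
    next_atom = "C8" if base in chem.PURINES else "C6"
    interior = 108.0 if base in chem.PURINES else 120.0
    half = (360.0 - interior) / 2.0

    t_n = place_atom(coords["C2'"], coords["O4'"], coords["C1'"],
                     GLYCOSIDIC_BOND, 108.0, -120.0)
    r_chi = float(np.linalg.norm(local[chi_atom] - local[n_name]))
    r_next = float(np.linalg.norm(local[next_atom] - local[n_name]))
    t_chi = place_atom(coords["O4'"], coords["C1'"], t_n, r_chi, half, chi)
    t_next = place_atom(coords["O4'"], coords["C1'"], t_n, r_next, half,
                        chi + 180.0)
    # rigid map of the base layout onto the three anchor targets
    src = np.stack([local[n_name], local[chi_atom], local[next_atom]])
    dst = np.stack([t_n, t_chi, t_next])
    src_c, dst_c = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - dst_c, src - src_c)
    for name, xyz in local.items():
        coords[name] = rot.apply(xyz - src_c) + dst_c
    return _residue(chain_id, seq_id, base, coords)


# --- posed fixtures ---------------------------------------------------------

@dataclass
class StackFixtureSpec:
    base: str = "G"
    partner: str = "PHE"          # PHE/TYR/TRP/HIS/ARG or "peptide"
    peptide_residues: tuple[str, str] = ("GLY", "ALA")
    interplane_angle: float = 0.0  # degrees
    vertical_sep: float = 3.4      # Angstrom
    lateral_offset: float = 0.5


def _clash_check(structure: ComplexStructure, min_dist: float = 1.5):
    from .geometry import residue_min_distance
    res = structure.residues()
    for i, a in enumerate(res):
        for b in res[i + 1:]:
            if a.chain_id != b.chain_id and residue_min_distance(a, b) < min_dist:
                raise ValueError(
                    f"fixture geometry not realizable: clash {a.label}~{b.label}")


def make_stack_fixture(spec: StackFixtureSpec) -> ComplexStructure:
    """Nucleotide base and planar partner posed at the requested geometry.

    The base ring sits in the z = 0 plane centered at the origin (sugar below
    the plane); the partner plane's centroid sits at (lateral_offset, 0,
    vertical_sep), tilted by interplane_angle about the x axis.
    """
    nt = make_nucleotide(spec.base, chi=-120.0, with_phosphate=False)
    ring_names = chem.BASE_RING_ATOMS[chem.canonical_residue_name(spec.base)]
    ring = np.stack([nt.atom(n).xyz for n in ring_names])
    centroid = ring.mean(axis=0)
    # rotate base plane onto z = 0 with the sugar below
    centered = ring - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    sugar_atoms = [a for a in nt.atoms if a.name not in ring_names]
    sugar_dir = np.mean([a.xyz for a in sugar_atoms], axis=0) - centroid
    if float(np.dot(normal, sugar_dir)) > 0:
        normal = -normal  # sugar goes to negative z, partner stacks above
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), normal[None, :])
    for a in nt.atoms:
        a.xyz = rot.apply(a.xyz - centroid)

    tilt = Rotation.from_euler("x", spec.interplane_angle, degrees=True)
    shift = np.array([spec.lateral_offset, 0.0, spec.vertical_sep])

    if spec.partner.lower() == "peptide":
        lay1, lay2 = peptide_layout()
        plane_atoms = [lay1["CA"], lay1["C"], lay1["O"], lay2["N"], lay2["CA"]]
        pcen = np.mean(plane_atoms, axis=0)
        res1 = _residue("P", 1, spec.peptide_residues[0],
                        {k: tilt.apply(v - pcen) + shift for k, v in lay1.items()})
        res2 = _residue("P", 2, spec.peptide_residues[1],
                        {k: tilt.apply(v - pcen) + shift for k, v in lay2.items()})
        protein = Chain("P", [res1, res2])
    else:
        resname = spec.partner.upper()
        lay = sidechain_layout(resname)
        plane_names = (chem.AA_STACK_PLANES[resname][1]
                       if resname in chem.AA_STACK_PLANES else list(lay))
        pcen = np.mean([lay[n] for n in plane_names], axis=0)
        res = _residue("P", 1, resname,
                       {k: tilt.apply(v - pcen) + shift for k, v in lay.items()})
        protein = Chain("P", [res])

    structure = ComplexStructure(
        accession=f"stack-{spec.base}-{spec.partner}".lower(),
        chains=[Chain("R", [nt]), protein])
    _clash_check(structure)
    return structure


def make_hbond_fixture(aa_name: str, aa_atom: str, base: str, nt_atom: str,
                       distance: float) -> ComplexStructure:
    """One nucleotide and one amino acid with a named atom pair at a set distance.

    The amino acid carries a full backbone plus the planar side-chain layout
    when one exists; the two named atoms end up exactly ``distance`` apart
    along x, with the remaining atoms pointing away from each other.
    """
    nt = make_nucleotide(base, with_phosphate=True)
    anchor = nt.atom(nt_atom)
    if anchor is None:
        raise ValueError(f"nucleotide has no atom {nt_atom!r}")
    # amino acid: backbone strip + optional planar side chain, along -x
    aa_coords: dict[str, np.ndarray] = {
        "N": np.array([-2.5, 1.2, 0.0]),
        "CA": np.array([-1.2, 0.6, 0.0]),
        "C": np.array([-1.3, -0.9, 0.0]),
        "O": np.array([-0.4, -1.7, 0.2]),
    }
    try:
        side = sidechain_layout(aa_name)
        target = np.array([2.2, 0.8, 0.0])
        off = target - side.get("CB", side.get("CD", np.zeros(3)))
        for k, v in side.items():
            aa_coords[k] = v + off
    except ValueError:
        pass
    if aa_atom not in aa_coords:
        raise ValueError(f"{aa_name} template has no atom {aa_atom!r}")
    # translate the whole amino acid so the named pair is at `distance`
    shift = (anchor.xyz + np.array([distance, 0.0, 0.0])) - aa_coords[aa_atom]
    aa = _residue("P", 1, aa_name.upper(), {k: v + shift for k, v in aa_coords.items()})
    structure = ComplexStructure(
        accession=f"hb-{aa_name}-{base}".lower(),
        chains=[Chain("R", [nt]), Chain("P", [aa])])
    return structure


def make_pseudo_pair_fixture(vertical: float = 0.0,
                             base: str = "G") -> ComplexStructure:
    """Arginine guanidinium hydrogen-bonded to a base's Hoogsteen face.

    At ``vertical`` = 0 the group is coplanar with the base (pseudo pairing);
    lifting it to ~3.4 A turns the same partners into stacking geometry.
    """
    nt_lay = _with_c1(base, base_layout(base))
    targets = {"G": [("NH1", "O6"), ("NH2", "N7")],
               "U": [("NH1", "O4"), ("NH2", "O2")]}[base]
    arg_lay = sidechain_layout("ARG")

    def residuals(params):
        theta, tx, ty = params
        c, s = math.cos(theta), math.sin(theta)
        out = []
        for ga, ba in targets:
            v = arg_lay[ga]
            x = c * v[0] - s * v[1] + tx
            y = s * v[0] + c * v[1] + ty
            out.append(math.hypot(x - nt_lay[ba][0], y - nt_lay[ba][1]) - 2.9)
        return out

    best = None
    for theta0 in np.linspace(0, 2 * math.pi, 8, endpoint=False):
        sol = least_squares(residuals, [theta0, 6.0, 3.0])
        if best is None or sol.cost < best.cost:
            best = sol
    theta, tx, ty = best.x
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([tx, ty, vertical])
    arg = _residue("P", 1, "ARG",
                   {k: rot @ v + shift for k, v in arg_lay.items()})
    return ComplexStructure(
        accession=f"pseudo-{base}".lower(),
        chains=[Chain("R", [_residue("R", 1, base, nt_lay)]),
                Chain("P", [arg])])


# --- hairpin ----------------------------------------------------------------

def _paired_layout(base1: str, base2: str) -> dict[str, np.ndarray]:
    """In-plane placement of base2 forming Watson-Crick hydrogen bonds to a
    base1 layout held fixed at the origin. Returns base2's coordinates."""
    wc = {("G", "C"): [("N1", "N3"), ("N2", "O2"), ("O6", "N4")],
          ("A", "U"): [("N1", "N3"), ("N6", "O4")]}
    pairs = wc.get((base1, base2))
    if pairs is None:
        pairs = wc.get((base2, base1))
        if pairs is None:
            raise ValueError(f"no Watson-Crick table for {base1}-{base2}")
        pairs = [(b, a) for a, b in pairs]
    lay1 = base_layout(base1)
    lay2 = base_layout(base2)
    # mirror base2 (faces flipped) then fit rotation+translation in-plane
    mirrored = {k: v * np.array([1.0, -1.0, 1.0]) for k, v in lay2.items()}

    def residuals(params):
        theta, tx, ty = params
        c, s = math.cos(theta), math.sin(theta)
        out = []
        for a1, a2 in pairs:
            v = mirrored[a2]
            x = c * v[0] - s * v[1] + tx
            y = s * v[0] + c * v[1] + ty
            d = math.hypot(x - lay1[a1][0], y - lay1[a1][1])
            out.append(d - 2.9)
        return out

    best = None
    for theta0 in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
        sol = least_squares(residuals, [theta0, 8.0, 0.0])
        if best is None or sol.cost < best.cost:
            best = sol
    theta, tx, ty = best.x
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return {k: rot @ v + np.array([tx, ty, 0.0]) for k, v in mirrored.items()}


def _with_c1(base: str, coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Attach a C1'/O2' stub so the residue classifies as a ribonucleotide."""
    ring_names = chem.BASE_RING_ATOMS[base]
    centroid = np.mean([coords[n] for n in ring_names], axis=0)
    n_name = chem.GLYCOSIDIC_N[base]
    u = coords[n_name] - centroid
    u = u / np.linalg.norm(u)
    out = dict(coords)
    out["C1'"] = coords[n_name] + GLYCOSIDIC_BOND * u
    out["O2'"] = out["C1'"] + np.array([0.0, 0.0, -1.4]) + 0.3 * u
    return out


def make_hairpin(stem: int = 4, loop: int = 4, rise: float = 3.4,
                 accession: str = "hairpin") -> ComplexStructure:
    """Single RNA chain folding into an (untwisted) stem-loop.

    5' side: G * stem, loop: U * loop, 3' side: C * stem; nucleotide i pairs
    nucleotide (2*stem + loop + 1 - i) in author numbering. Stem levels stack
    at ``rise`` A so covalent neighbors in the stem satisfy the base-stacking
    criteria; loop residues sit isolated above the stem.
    """
    gc = _paired_layout("G", "C")
    g_lay = base_layout("G")
    residues = []
    n_total = 2 * stem + loop
    for k in range(stem):  # 5' strand, bottom-up
        z = np.array([0.0, 0.0, rise * k])
        residues.append(_residue("R", k + 1, "G",
                                 {n: v + z for n, v in _with_c1("G", g_lay).items()}))
    for j in range(loop):
        shift = np.array([j * 7.0 - 8.0, 9.5, rise * stem + 3.0 + 2.0 * (j % 2)])
        residues.append(_residue("R", stem + j + 1, "U",
                                 {n: v + shift
                                  for n, v in _with_c1("U", base_layout("U")).items()}))
    for k in range(stem):  # 3' strand, top-down
        level = stem - 1 - k
        z = np.array([0.0, 0.0, rise * level])
        residues.append(_residue("R", stem + loop + k + 1, "C",
                                 {n: v + z for n, v in _with_c1("C", gc).items()}))
    assert residues[-1].seq_id == n_total
    return ComplexStructure(accession=accession, chains=[Chain("R", residues)])


# --- simulated feature tables ------------------------------------------------

@dataclass
class TableSimSpec:
    """Generative model for labeled feature tables with injected signal.

    Count features are Poisson at ``baseline_rate``; in positive rows the
    informative features' rates are multiplied by exp(beta). For Poisson
    class-conditionals with log rate-ratio beta the posterior label
    probability is exactly Bernoulli(sigmoid(beta . x + intercept)) with

        intercept = log(n_pos / n_neg)
                    - n_informative * baseline_rate * (exp(beta) - 1),

    so the class-shifted-rate and logistic-label descriptions of this
    generator are the same model. Exactly ``n_pos`` positive and ``n_neg``
    negative rows are drawn, reproducing the dataset imbalance. Defaults
    mirror the nucleotide classification regime: 214 sites at 43:171 (~20%
    positive), 246 features, 5 informative columns at beta = 1.5 (rate ratio
    ~4.5, a strong injected signal).
    """
    n_pos: int = 43
    n_neg: int = 171
    n_features: int = 246
    informative: tuple[int, ...] = (0, 10, 50, 120, 200)
    beta: float = 1.5
    baseline_rate: float = 0.5
    seed: int = 0
    feature_names: tuple[str, ...] | None = None

    @property
    def target_rate(self) -> float:
        return self.n_pos / (self.n_pos + self.n_neg)

    def betas(self) -> np.ndarray:
        b = np.zeros(self.n_features)
        b[list(self.informative)] = self.beta
        return b

    @property
    def intercept(self) -> float:
        """Intercept of the implied logistic label model (closed form)."""
        return (math.log(self.n_pos / self.n_neg)
                - len(self.informative) * self.baseline_rate
                * (math.exp(self.beta) - 1.0))


def simulate_feature_table(spec: TableSimSpec):
    """Draw a labeled Dataset under the class-conditional Poisson model."""
    from .classify import Dataset
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    y = rng.permutation(np.concatenate([np.ones(spec.n_pos, dtype=int),
                                        np.zeros(spec.n_neg, dtype=int)]))
    X = rng.poisson(spec.baseline_rate, size=(n, spec.n_features)).astype(float)
    pos = y == 1
    shifted = spec.baseline_rate * math.exp(spec.beta)
    for j in spec.informative:
        X[pos, j] = rng.poisson(shifted, size=int(pos.sum()))
    names = (list(spec.feature_names) if spec.feature_names
             else [f"f{i:03d}" for i in range(spec.n_features)])
    Xdf = pd.DataFrame(X, columns=names)
    return Dataset(X=Xdf, y=y,
                   groups=np.zeros(n, dtype=int),
                   meta=pd.DataFrame({"row": np.arange(n)}),
                   sim_spec=spec, sim_intercept=spec.intercept)


def bayes_scores(spec: TableSimSpec, X: np.ndarray, intercept: float) -> np.ndarray:
    """True generative log-odds, the Bayes-optimal score for simulated tables."""
    return np.asarray(X, float) @ spec.betas() + intercept


# --- demo complex ------------------------------------------------------------

DEMO_SEQUENCE = "UGCAUGUACGUA"


def make_demo_complex(sequence: str = DEMO_SEQUENCE,
                      stacked: tuple[int, ...] = (1, 5, 9),
                      hbonded: tuple[int, ...] = (3, 7),
                      accession: str = "demo") -> ComplexStructure:
    """A small synthetic protein-RNA interface for end-to-end runs.

    One RNA strand laid out along x; every nucleotide gets a protein partner
    (stacked Phe at the ``stacked`` 0-based positions, an arginine
    guanidinium hydrogen-bonded to the phosphate at ``hbonded`` positions,
    and a plain-contact glycine elsewhere), so every site enters the
    contacting classification set.
    """
    from .geometry import fit_plane

    nts, aas = [], []
    spacing = 9.0
    for i, base in enumerate(sequence):
        nt = make_nucleotide(base, chi=-120.0, seq_id=i + 1)
        shift = np.array([spacing * i, 0.0, 0.0])
        for a in nt.atoms:
            a.xyz = a.xyz + shift
        nts.append(nt)

        ring = np.stack([nt.atom(n).xyz
                         for n in chem.BASE_RING_ATOMS[nt.parent_name]])
        centroid, normal, _ = fit_plane(ring)
        if i in stacked:
            lay = sidechain_layout("PHE")
            names = chem.AA_STACK_PLANES["PHE"][1]
            pcen = np.mean([lay[n] for n in names], axis=0)
            rot, _ = Rotation.align_vectors(normal[None, :],
                                            np.array([[0.0, 0.0, 1.0]]))
            coords = {k: rot.apply(v - pcen) + centroid + 3.4 * normal
                      for k, v in lay.items()}
            aas.append(_residue("P", len(aas) + 1, "PHE", coords))
        elif i in hbonded:
            anchor = nt.atom("OP1").xyz
            u = anchor - centroid
            u = u / np.linalg.norm(u)
            lay = sidechain_layout("ARG")
            coords = {k: v + (anchor + 2.9 * u) - lay["NH1"]
                      for k, v in lay.items()}
            aas.append(_residue("P", len(aas) + 1, "ARG", coords))
        else:
            edge = nt.atom("N3").xyz if nt.atom("N3") is not None else centroid
            u = edge - centroid
            u = u / np.linalg.norm(u)
            coords = {"N": edge + 4.2 * u + np.array([0.0, 1.2, 0.0]),
                      "CA": edge + 4.2 * u,
                      "C": edge + 5.0 * u + np.array([0.0, -1.2, 0.0]),
                      "O": edge + 6.0 * u + np.array([0.0, -1.6, 0.0])}
            aas.append(_residue("P", len(aas) + 1, "GLY", coords))
    return ComplexStructure(accession=accession,
                            chains=[Chain("R", nts), Chain("P", aas)])


def write_demo_bundle(outdir, seed: int = 0, n_instances: int = 30):
    """Write the demo complex + a matching CLIP instance table; return a
    ready-to-run pipeline configuration."""
    from pathlib import Path
    from . import crosslinks
    from .pipeline import RunConfig
    from .structure import write_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stacked, hbonded = (1, 5, 9), (3, 7)
    st = make_demo_complex(stacked=stacked, hbonded=hbonded)
    pdb = write_structure(st, outdir / "demo.pdb")

    rng = np.random.default_rng(seed)
    hot = set(stacked) | set(hbonded)
    instances = []
    for i in range(n_instances):
        offsets = tuple(sorted(p for p in range(len(DEMO_SEQUENCE))
                               if rng.random() < (0.6 if p in hot else 0.03)))
        instances.append((f"inst{i:03d}", offsets))
    table = crosslinks.LigandInstanceTable(DEMO_SEQUENCE, instances)
    tpath = crosslinks.write_instance_table(table, outdir / "demo_instances.tsv")

    return RunConfig(task="nucleotide", structures=[str(pdb)],
                     instance_tables={st.accession: str(tpath)},
                     cv_folds=3, n_bootstrap=20, n_permutations=10,
                     master_seed=seed, outdir=str(outdir / "run"))
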