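"""Protein-RNA interface geometry.

Re-implements the interface feature subset used for crosslink-determinant
analysis: heavy-atom contacts, typed hydrogen bonds, planar stacking (aromatic
side chains, arginine guanidinium, peptide-bond planes, base-base), coplanar
pseudo base pairs, sugar-pucker pseudorotation, glycosidic base orientation and
RNA pairing context — all computed directly from coordinates, with no hydrogen
positions required.

Conventions
-----------
* A nucleotide and an amino acid are *in contact* when their minimum
  heavy-atom distance is <= 4.5 A (inclusive).
* Hydrogen bonds are called on donor-acceptor heavy-atom distance alone
  (default cutoff 3.5 A), using pinned capability tables in :mod:`chem`.
* Interplane angles are always the acute angle, min(theta, 180 - theta).
* Stacking requires interplane angle <= 30 deg, vertical separation in
  [2.0, 4.5] A and lateral offset <= 3.0 A; pseudo pairing requires >= 2
  base-group hydrogen bonds, angle <= 30 deg and vertical separation
  <= 1.5 A (coplanar rather than stacked). These thresholds reproduce
  textbook pi-stack geometry (~3.4 A parallel separation) and are all
  configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import chem
from .structure import Atom, ComplexStructure, Residue

logger = logging.getLogger(__name__)

PUCKER_CLASSES = [
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
]

SECONDARY_ELEMENTS = [
    "helix-internal", "helix-end", "hairpin-loop", "internal-loop",
    "bulge", "junction", "terminal-ss", "isolated-ss",
]


class DegeneratePlaneError(ValueError):
    """Raised when a planar moiety's atoms are (near-)collinear."""


# --- configs ----------------------------------------------------------------

@dataclass
class ContactConfig:
    heavy_atom_cutoff: float = 4.5  # Angstrom

    def __post_init__(self):
        if self.heavy_atom_cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class GeometryConfig:
    contact: ContactConfig = field(default_factory=ContactConfig)
    hb_cutoff: float = 3.5
    stack_max_angle: float = 30.0         # degrees
    stack_min_vertical: float = 2.0       # Angstrom
    stack_max_vertical: float = 4.5
    stack_max_lateral: float = 3.0
    pair_max_angle: float = 30.0
    pair_max_vertical: float = 1.5
    pair_min_hbonds: int = 2


# --- records ----------------------------------------------------------------

@dataclass
class ContactRecord:
    nt: Residue
    aa: Residue
    min_distance: float


@dataclass
class HBond:
    nt: Residue
    aa: Residue
    rna_atom: str
    protein_atom: str
    donor_is_rna: bool
    distance: float
    rna_moiety: str       # base / sugar / phosphate
    protein_moiety: str   # sidechain / backbone


@dataclass
class StackRecord:
    nt: Residue
    partner_kind: str     # aromatic-sidechain / guanidinium / peptide-bond / nucleotide-base
    partners: tuple[Residue, ...]
    interplane_angle: float
    vertical_sep: float
    lateral_offset: float


@dataclass
class PseudoPair:
    nt: Residue
    aa: Residue
    n_hbonds: int
    interplane_angle: float
    vertical_sep: float


@dataclass
class SugarPucker:
    nu: tuple[float, float, float, float, float]
    P: float            # pseudorotation phase, [0, 360)
    tau_m: float        # amplitude, degrees
    pucker_class: str
    family: str         # N (C3'-endo-like) or S (C2'-endo-like)


@dataclass
class BaseOrientation:
    chi: float          # degrees, (-180, 180]
    orientation: str    # anti / syn


@dataclass
class NucSecondary:
    paired: bool
    element: str
    stacked_5p: bool = False
    stacked_3p: bool = False

    def __post_init__(self):
        if self.paired and self.element not in ("helix-internal", "helix-end"):
            raise ValueError("paired nucleotide must lie in a helix element")


@dataclass
class InterfaceAnnotation:
    """Per-structure bundle of all interface geometry results."""
    contacts: list[ContactRecord]
    hbonds: list[HBond]
    stacks: list[StackRecord]
    pseudo_pairs: list[PseudoPair]
    puckers: dict[tuple, SugarPucker | None]
    orientations: dict[tuple, BaseOrientation | None]
    secondary: dict[tuple, NucSecondary]
    config: GeometryConfig = field(default_factory=GeometryConfig)


# --- elementary geometry ----------------------------------------------------

def fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through >= 3 points.

    Returns (centroid, unit normal, rmsd). The normal's sign is fixed:
    positive z-component, ties broken toward positive x, then positive y.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 3:
        raise ValueError("need >= 3 points of dimension 3")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear input: second singular value ~ 0
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-9:
        raise DegeneratePlaneError("points are collinear; plane undefined")
    normal = vt[-1]
    # sign convention: positive z-component; ties broken by positive x, then y
    if abs(normal[2]) > 1e-12:
        if normal[2] < 0:
            normal = -normal
    elif abs(normal[0]) > 1e-12:
        if normal[0] < 0:
            normal = -normal
    elif normal[1] < 0:
        normal = -normal
    rmsd = float(s[-1] / math.sqrt(coords.shape[0]))
    return centroid, normal, rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1u))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def interplane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle between two plane normals, degrees in [0, 90]."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, c)))


def _plane_pair_geometry(c1, n1, c2, n2):
    """(angle, vertical, lateral) for two fitted planes.

    Vertical and lateral decompose the centroid-centroid vector along / off
    the averaged normal (normals first flipped into the same hemisphere).
    """
    angle = interplane_angle(n1, n2)
    if float(np.dot(n1, n2)) < 0:
        n2 = -n2
    navg = n1 + n2
    navg = navg / np.linalg.norm(navg)
    d = np.asarray(c2) - np.asarray(c1)
    vertical = abs(float(np.dot(d, navg)))
    lateral = math.sqrt(max(float(np.dot(d, d)) - vertical**2, 0.0))
    return angle, vertical, lateral


# --- contacts ---------------------------------------------------------------

def residue_min_distance(r1: Residue, r2: Residue) -> float:
    """Minimum heavy-atom distance between two residues (inf if no heavy atoms)."""
    a, b = r1.heavy_coords(), r2.heavy_coords()
    if a.size == 0 or b.size == 0:
        return math.inf
    return float(cdist(a, b).min())


def heavy_atom_contacts(structure: ComplexStructure,
                        config: ContactConfig | None = None) -> list[ContactRecord]:
    """All nucleotide-amino-acid pairs with min heavy-atom distance <= cutoff.

    The boundary is inclusive and hydrogens never participate. Complete by
    construction: every (nt, aa) pair is examined (with a cheap bounding-box
    prefilter that cannot drop a qualifying pair).
    """
    config = config or ContactConfig()
    cutoff = config.heavy_atom_cutoff
    records = []
    nts = structure.rna_residues()
    aas = structure.protein_residues()
    if not nts or not aas:
        return records
    nt_coords = [r.heavy_coords() for r in nts]
    aa_coords = [r.heavy_coords() for r in aas]
    nt_centers = np.array([c.mean(axis=0) if c.size else [np.inf] * 3 for c in nt_coords])
    nt_radii = np.array([np.linalg.norm(c - m, axis=1).max() if c.size else 0.0
                         for c, m in zip(nt_coords, nt_centers)])
    for aa, ac in zip(aas, aa_coords):
        if ac.size == 0:
            continue
        center = ac.mean(axis=0)
        radius = np.linalg.norm(ac - center, axis=1).max()
        reach = nt_radii + radius + cutoff
        close = np.linalg.norm(nt_centers - center, axis=1) <= reach
        for idx in np.flatnonzero(close):
            d = float(cdist(nt_coords[idx], ac).min())
            if d <= cutoff:
                records.append(ContactRecord(nt=nts[idx], aa=aa, min_distance=d))
    return records


# --- hydrogen bonds ---------------------------------------------------------

def _pairwise_hbond_atoms(donors1: list[Atom], acceptors2: list[Atom],
                          cutoff: float) -> list[tuple[Atom, Atom, float]]:
    out = []
    for d in donors1:
        for a in acceptors2:
            dist = float(np.linalg.norm(d.xyz - a.xyz))
            if dist <= cutoff:
                out.append((d, a, dist))
    return out


def hbonds_between(nt: Residue, aa: Residue, cutoff: float = 3.5) -> list[HBond]:
    """Typed hydrogen bonds between one nucleotide and one amino acid."""
    base = nt.parent_name
    nt_don = chem.nt_donor_atoms(base)
    nt_acc = chem.nt_acceptor_atoms(base)
    aa_don = chem.aa_donor_atoms(aa.name)
    aa_acc = chem.aa_acceptor_atoms(aa.name)
    nt_atoms = {a.name: a for a in nt.heavy_atoms()}
    aa_atoms = {a.name: a for a in aa.heavy_atoms()}
    bonds = []
    for d, a, dist in _pairwise_hbond_atoms(
            [nt_atoms[n] for n in nt_don if n in nt_atoms],
            [aa_atoms[n] for n in aa_acc if n in aa_atoms], cutoff):
        bonds.append(HBond(nt=nt, aa=aa, rna_atom=d.name, protein_atom=a.name,
                           donor_is_rna=True, distance=dist,
                           rna_moiety=chem.rna_moiety(d.name),
                           protein_moiety=chem.protein_moiety(a.name)))
    for d, a, dist in _pairwise_hbond_atoms(
            [aa_atoms[n] for n in aa_don if n in aa_atoms],
            [nt_atoms[n] for n in nt_acc if n in nt_atoms], cutoff):
        bonds.append(HBond(nt=nt, aa=aa, rna_atom=a.name, protein_atom=d.name,
                           donor_is_rna=False, distance=dist,
                           rna_moiety=chem.rna_moiety(a.name),
                           protein_moiety=chem.protein_moiety(d.name)))
    # one bond per atom pair: keep the donor->acceptor reading with shorter label
    seen = {}
    for b in bonds:
        key = (b.rna_atom, b.protein_atom)
        if key not in seen or b.distance < seen[key].distance:
            seen[key] = b
    return sorted(seen.values(), key=lambda b: (b.rna_atom, b.protein_atom))


def detect_hbonds(structure: ComplexStructure,
                  hb_cutoff: float = 3.5) -> list[HBond]:
    """All protein-RNA hydrogen bonds, typed by RNA moiety x protein moiety."""
    bonds = []
    nts = structure.rna_residues()
    aas = structure.protein_residues()
    for nt in nts:
        for aa in aas:
            if residue_min_distance(nt, aa) > hb_cutoff:
                continue
            bonds.extend(hbonds_between(nt, aa, cutoff=hb_cutoff))
    return bonds


def _base_base_hbonds(nt1: Residue, nt2: Residue, cutoff: float = 3.5) -> int:
    """Number of base-moiety donor/acceptor bonds between two nucleotides."""
    n = 0
    for a, b in ((nt1, nt2), (nt2, nt1)):
        don = {x for x in chem.nt_donor_atoms(a.parent_name)
               if chem.rna_moiety(x) == "base"}
        acc = {x for x in chem.nt_acceptor_atoms(b.parent_name)
               if chem.rna_moiety(x) == "base"}
        a_atoms = {x.name: x for x in a.heavy_atoms()}
        b_atoms = {x.name: x for x in b.heavy_atoms()}
        n += len(_pairwise_hbond_atoms(
            [a_atoms[x] for x in don if x in a_atoms],
            [b_atoms[x] for x in acc if x in b_atoms], cutoff))
    return n


# --- nucleotide conformation ------------------------------------------------

_RING_TORSION_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),   # nu0
    ("O4'", "C1'", "C2'", "C3'"),   # nu1
    ("C1'", "C2'", "C3'", "C4'"),   # nu2
    ("C2'", "C3'", "C4'", "O4'"),   # nu3
    ("C3'", "C4'", "O4'", "C1'"),   # nu4
]

_AS_DENOM = 2.0 * (math.sin(math.radians(36)) + math.sin(math.radians(72)))


def pucker_from_torsions(nu: tuple[float, ...]) -> SugarPucker:
    """Altona-Sundaralingam phase/amplitude from the five ring torsions.

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)), with the
    +180 deg branch shift when nu2 < 0 (handled by atan2), P reduced to
    [0, 360).
    """
    nu0, nu1, nu2, nu3, nu4 = nu
    num = (nu4 + nu1) - (nu3 + nu0)
    P = math.degrees(math.atan2(num, nu2 * _AS_DENOM)) % 360.0
    tau_m = math.hypot(nu2, num / _AS_DENOM)
    k = int(P // 36.0) % 10
    family = "N" if (P >= 270.0 or P < 90.0) else "S"
    return SugarPucker(nu=tuple(nu), P=P, tau_m=tau_m,
                       pucker_class=PUCKER_CLASSES[k], family=family)


def sugar_pucker(residue: Residue) -> SugarPucker | None:
    """Ribose pseudorotation for one ribonucleotide.

    Returns None (feature marked missing) when a ring atom is absent.
    """
    coords = {}
    for name in ("C1'", "C2'", "C3'", "C4'", "O4'"):
        atom = residue.atom(name)
        if atom is None:
            logger.warning("%s: missing ring atom %s; pucker undefined",
                           residue.label, name)
            return None
        coords[name] = atom.xyz
    nu = tuple(dihedral(*(coords[n] for n in quad)) for quad in _RING_TORSION_ATOMS)
    return pucker_from_torsions(nu)


def base_orientation(residue: Residue) -> BaseOrientation | None:
    """Glycosidic torsion chi and its syn/anti call (anti iff |chi| >= 90)."""
    names = chem.CHI_ATOMS.get(residue.parent_name)
    if names is None:
        return None
    atoms = [residue.atom(n) for n in names]
    if any(a is None for a in atoms):
        logger.warning("%s: chi atoms incomplete; orientation undefined",
                       residue.label)
        return None
    chi = dihedral(*(a.xyz for a in atoms))
    return BaseOrientation(chi=chi, orientation="anti" if abs(chi) >= 90.0 else "syn")


# --- planar moieties & stacking ---------------------------------------------

def _base_plane(nt: Residue):
    names = chem.BASE_RING_ATOMS.get(nt.parent_name)
    if names is None:
        return None
    atoms = [nt.atom(n) for n in names]
    atoms = [a for a in atoms if a is not None]
    if len(atoms) < 3:
        return None
    try:
        return fit_plane(np.stack([a.xyz for a in atoms]))
    except DegeneratePlaneError:
        logger.warning("%s: degenerate base plane skipped", nt.label)
        return None


def _sidechain_planes(aa: Residue):
    """Yield (kind, plane) for stacking-eligible side-chain groups."""
    entry = chem.AA_STACK_PLANES.get(aa.parent_name)
    if entry is None:
        return
    kind, names = entry
    atoms = [aa.atom(n) for n in names]
    atoms = [a for a in atoms if a is not None]
    if len(atoms) < 3:
        return
    try:
        yield kind, fit_plane(np.stack([a.xyz for a in atoms]))
    except DegeneratePlaneError:
        logger.warning("%s: degenerate side-chain plane skipped", aa.label)


def _peptide_planes(structure: ComplexStructure):
    """Peptide-bond planes (CAi, Ci, Oi, Ni+1, CAi+1) of consecutive residues."""
    for chain in structure.chains:
        if chain.polymer_class != "protein":
            continue
        res = [r for r in chain.residues if r.kind == "amino-acid"]
        for r1, r2 in zip(res, res[1:]):
            c, o, n = r1.atom("C"), r1.atom("O"), r2.atom("N")
            if c is None or o is None or n is None:
                continue
            if np.linalg.norm(c.xyz - n.xyz) > 1.8:  # not actually bonded
                continue
            atoms = [r1.atom("CA"), c, o, n, r2.atom("CA")]
            coords = np.stack([a.xyz for a in atoms if a is not None])
            if coords.shape[0] < 4:
                continue
            try:
                yield (r1, r2), fit_plane(coords)
            except DegeneratePlaneError:
                logger.warning("%s-%s: degenerate peptide plane skipped",
                               r1.label, r2.label)


def detect_stacking(structure: ComplexStructure,
                    config: GeometryConfig | None = None,
                    include_base_base: bool = True) -> list[StackRecord]:
    """Planar stacking of nucleotide bases on protein moieties and other bases.

    Partners: aromatic side chains (Phe/Tyr/Trp/His), the arginine
    guanidinium group, peptide-bond planes of consecutive residues, and other
    nucleotide bases.
    """
    cfg = config or GeometryConfig()
    records: list[StackRecord] = []
    nts = structure.rna_residues()
    base_planes = {nt.key: _base_plane(nt) for nt in nts}

    def check(c1n1, c2n2):
        angle, vert, lat = _plane_pair_geometry(c1n1[0], c1n1[1], c2n2[0], c2n2[1])
        ok = (angle <= cfg.stack_max_angle
              and cfg.stack_min_vertical <= vert <= cfg.stack_max_vertical
              and lat <= cfg.stack_max_lateral)
        return ok, angle, vert, lat

    protein_planes = []
    for aa in structure.protein_residues():
        for kind, plane in _sidechain_planes(aa):
            protein_planes.append((kind, (aa,), plane))
    for (r1, r2), plane in _peptide_planes(structure):
        protein_planes.append(("peptide-bond", (r1, r2), plane))

    max_cdist = math.hypot(cfg.stack_max_vertical, cfg.stack_max_lateral) + 1e-9
    for nt in nts:
        bp = base_planes[nt.key]
        if bp is None:
            continue
        for kind, partners, plane in protein_planes:
            if np.linalg.norm(plane[0] - bp[0]) > max_cdist:
                continue
            ok, angle, vert, lat = check(bp, plane)
            if ok:
                records.append(StackRecord(nt=nt, partner_kind=kind,
                                           partners=partners,
                                           interplane_angle=angle,
                                           vertical_sep=vert,
                                           lateral_offset=lat))
        if include_base_base:
            for other in nts:
                if other.key <= nt.key:
                    continue
                op = base_planes[other.key]
                if op is None or np.linalg.norm(op[0] - bp[0]) > max_cdist:
                    continue
                ok, angle, vert, lat = check(bp, op)
                if ok:
                    records.append(StackRecord(nt=nt, partner_kind="nucleotide-base",
                                               partners=(other,),
                                               interplane_angle=angle,
                                               vertical_sep=vert,
                                               lateral_offset=lat))
    return records


def detect_pseudo_pairs(structure: ComplexStructure,
                        config: GeometryConfig | None = None) -> list[PseudoPair]:
    """Coplanar, multiply hydrogen-bonded amino-acid/base pairing.

    Emitted iff >= 2 hydrogen bonds link the base to the planar side-chain
    group AND interplane angle <= 30 deg AND vertical separation <= 1.5 A
    (coplanar, i.e. explicitly *not* stacked geometry).
    """
    cfg = config or GeometryConfig()
    pairs = []
    nts = structure.rna_residues()
    for aa in structure.protein_residues():
        group = chem.AA_PAIR_PLANES.get(aa.parent_name)
        if group is None:
            continue
        group_atoms = set(group) | ({"OH"} if aa.parent_name == "TYR" else set())
        atoms = [aa.atom(n) for n in group]
        atoms = [a for a in atoms if a is not None]
        if len(atoms) < 3:
            continue
        try:
            aplane = fit_plane(np.stack([a.xyz for a in atoms]))
        except DegeneratePlaneError:
            continue
        for nt in nts:
            bp = _base_plane(nt)
            if bp is None:
                continue
            if np.linalg.norm(aplane[0] - bp[0]) > 12.0:
                continue
            bonds = [b for b in hbonds_between(nt, aa, cutoff=cfg.hb_cutoff)
                     if b.rna_moiety == "base" and b.protein_atom in group_atoms]
            if len(bonds) < cfg.pair_min_hbonds:
                continue
            angle, vert, _ = _plane_pair_geometry(bp[0], bp[1], aplane[0], aplane[1])
            if angle <= cfg.pair_max_angle and vert <= cfg.pair_max_vertical:
                pairs.append(PseudoPair(nt=nt, aa=aa, n_hbonds=len(bonds),
                                        interplane_angle=angle, vertical_sep=vert))
    return pairs


# --- RNA pairing context ----------------------------------------------------

def rna_pairing_context(structure: ComplexStructure,
                        config: GeometryConfig | None = None
                        ) -> dict[tuple, NucSecondary]:
    """Base-pairing status and loop-element class per nucleotide.

    Base pairs are called from >= 2 base-base hydrogen bonds plus coplanarity
    (interplane angle <= 30 deg); each nucleotide joins at most one pair
    (greedy, most hydrogen bonds first). Loop elements come from a nested-pair
    analysis of the resulting pair list; 5'/3' neighbor stacking flags reuse
    the stacking criteria.
    """
    cfg = config or GeometryConfig()
    chains = [(c.chain_id, [r for r in c.residues if r.kind == "ribonucleotide"])
              for c in structure.chains if c.polymer_class == "RNA"]
    nts: list[Residue] = [r for _, res in chains for r in res]
    index = {nt.key: i for i, nt in enumerate(nts)}
    planes = {nt.key: _base_plane(nt) for nt in nts}

    # candidate pairs
    candidates = []
    for i, a in enumerate(nts):
        for j in range(i + 1, len(nts)):
            b = nts[j]
            if a.chain_id == b.chain_id and abs(j - i) == 1:
                continue  # no pairing between covalent neighbors
            pa, pb = planes[a.key], planes[b.key]
            if pa is None or pb is None:
                continue
            if np.linalg.norm(pa[0] - pb[0]) > 12.0:
                continue
            n_hb = _base_base_hbonds(a, b, cutoff=cfg.hb_cutoff)
            if n_hb < 2:
                continue
            angle, _, _ = _plane_pair_geometry(pa[0], pa[1], pb[0], pb[1])
            if angle <= cfg.pair_max_angle:
                candidates.append((n_hb, -np.linalg.norm(pa[0] - pb[0]), i, j))
    candidates.sort(reverse=True)
    partner: dict[int, int] = {}
    for _, _, i, j in candidates:
        if i not in partner and j not in partner:
            partner[i] = j
            partner[j] = i

    # neighbor stacking flags
    stacked_5p = {i: False for i in range(len(nts))}
    stacked_3p = {i: False for i in range(len(nts))}
    for _, res in chains:
        for a, b in zip(res, res[1:]):
            pa, pb = planes[a.key], planes[b.key]
            if pa is None or pb is None:
                continue
            angle, vert, lat = _plane_pair_geometry(pa[0], pa[1], pb[0], pb[1])
            if (angle <= cfg.stack_max_angle
                    and cfg.stack_min_vertical <= vert <= cfg.stack_max_vertical
                    and lat <= cfg.stack_max_lateral):
                stacked_3p[index[a.key]] = True
                stacked_5p[index[b.key]] = True

    out: dict[tuple, NucSecondary] = {}
    for _, res in chains:
        gids = [index[r.key] for r in res]
        paired_flags = [g in partner for g in gids]
        any_paired = any(paired_flags)
        elements = [""] * len(res)
        # paired nucleotides: helix-internal iff both neighbors continue the helix
        for k, g in enumerate(gids):
            if not paired_flags[k]:
                continue
            p = partner[g]
            def continues(k2):
                if k2 < 0 or k2 >= len(gids) or not paired_flags[k2]:
                    return False
                return abs(partner[gids[k2]] - p) == 1
            elements[k] = ("helix-internal"
                           if continues(k - 1) and continues(k + 1)
                           else "helix-end")
        # unpaired runs
        k = 0
        while k < len(res):
            if paired_flags[k]:
                k += 1
                continue
            start = k
            while k < len(res) and not paired_flags[k]:
                k += 1
            end = k  # run is [start, end)
            if not any_paired:
                elem = "isolated-ss"
            elif start == 0 or end == len(res):
                elem = "terminal-ss"
            else:
                p, q = gids[start - 1], gids[end]
                pp, qq = partner[p], partner[q]
                if pp == q:
                    elem = "hairpin-loop"
                elif qq + 1 == pp:
                    elem = "bulge"       # zero unpaired on the partner strand
                elif qq < pp and all(g not in partner
                                     for g in range(qq + 1, pp)):
                    elem = "internal-loop"
                else:
                    elem = "junction"
            for k2 in range(start, end):
                elements[k2] = elem
        for k, r in enumerate(res):
            g = gids[k]
            out[r.key] = NucSecondary(paired=paired_flags[k], element=elements[k],
                                      stacked_5p=stacked_5p[g],
                                      stacked_3p=stacked_3p[g])
    return out


# --- full annotation --------------------------------------------------------

def annotate(structure: ComplexStructure,
             config: GeometryConfig | None = None) -> InterfaceAnnotation:
    """Compute the full interface-annotation bundle for one structure."""
    cfg = config or GeometryConfig()
    nts = structure.rna_residues()
    return InterfaceAnnotation(
        contacts=heavy_atom_contacts(structure, cfg.contact),
        hbonds=detect_hbonds(structure, hb_cutoff=cfg.hb_cutoff),
        stacks=detect_stacking(structure, cfg),
        pseudo_pairs=detect_pseudo_pairs(structure, cfg),
        puckers={nt.key: sugar_pucker(nt) for nt in nts},
        orientations={nt.key: base_orientation(nt) for nt in nts},
        secondary=rna_pairing_context(structure, cfg),
        config=cfg,
    )


def annotation_to_frame(ann: InterfaceAnnotation) -> pd.DataFrame:
    """One row per typed interaction, for TSV/JSON dumps."""
    rows = []
    for c in ann.contacts:
        rows.append(dict(kind="contact", nt=c.nt.label, partner=c.aa.label,
                         detail="", value=round(c.min_distance, 3)))
    for b in ann.hbonds:
        rows.append(dict(kind="hbond", nt=b.nt.label, partner=b.aa.label,
                         detail=f"{b.rna_moiety}x{b.protein_moiety}:"
                                f"{b.rna_atom}-{b.protein_atom}",
                         value=round(b.distance, 3)))
    for s in ann.stacks:
        rows.append(dict(kind="stack", nt=s.nt.label,
                         partner="+".join(p.label for p in s.partners),
                         detail=s.partner_kind,
                         value=round(s.vertical_sep, 3)))
    for p in ann.pseudo_pairs:
        rows.append(dict(kind="pseudo-pair", nt=p.nt.label, partner=p.aa.label,
                         detail=f"hbonds={p.n_hbonds}",
                         value=round(p.interplane_angle, 3)))
    for key, pk in ann.puckers.items():
        if pk is not None:
            rows.append(dict(kind="pucker", nt="/".join(map(str, key)), partner="",
                             detail=f"{pk.pucker_class}({pk.family})",
                             value=round(pk.P, 2)))
    for key, bo in ann.orientations.items():
        if bo is not None:
            rows.append(dict(kind="orientation", nt="/".join(map(str, key)),
                             partner="", detail=bo.orientation,
                             value=round(bo.chi, 2)))
    for key, sec in ann.secondary.items():
        rows.append(dict(kind="secondary", nt="/".join(map(str, key)), partner="",
                         detail=sec.element, value=int(sec.paired)))
    return pd.DataFrame(rows, columns=["kind", "nt", "partner", "detail", "value"])
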