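"""Pinned chemical dictionaries used across the package.

Everything that decides *what a residue is* — standard residue names, modified-
residue aliases, hydrogen-bond donor/acceptor capability, planar-moiety atom
sets, physicochemical amino-acid categories — lives here so the rest of the
code never hard-codes chemistry.

Atom names use PDB conventions with the prime character (O2', C1', ...).
"""

from __future__ import annotations

# --- residue dictionaries ---------------------------------------------------

AMINO_ACIDS_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO_ACIDS_1TO3 = {v: k for k, v in AMINO_ACIDS_3TO1.items()}
AMINO_ACID_LETTERS = sorted(AMINO_ACIDS_1TO3)  # 20, alphabetical one-letter

RIBONUCLEOTIDES = {"A", "C", "G", "U"}
DEOXYNUCLEOTIDES = {"DA", "DC", "DG", "DT", "DU"}

#: modified residues mapped to a standard parent; unmapped names become kind
#: ``other`` and are excluded from feature tables.
RESIDUE_ALIASES = {
    # nucleotides
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "OMU": "U",
    "1MA": "A", "MIA": "A", "6MA": "A", "OMA": "A",
    "5MC": "C", "OMC": "C",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "1MG": "G",
    "I": "G",
    # amino acids
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "HYP": "PRO", "MLY": "LYS",
}

SOLVENT = {"HOH", "DOD", "WAT"}


def canonical_residue_name(name: str) -> str:
    """Map a residue name to its standard parent (identity if already standard)."""
    name = name.strip().upper()
    return RESIDUE_ALIASES.get(name, name)


def residue_kind(name: str) -> str:
    """Classify a residue name: amino-acid / ribonucleotide / deoxynucleotide / other."""
    parent = canonical_residue_name(name)
    if parent in AMINO_ACIDS_3TO1:
        return "amino-acid"
    if parent in RIBONUCLEOTIDES:
        return "ribonucleotide"
    if parent in DEOXYNUCLEOTIDES:
        return "deoxynucleotide"
    return "other"


# --- amino-acid physicochemical categories (overlapping, deliberate) --------

AA_CATEGORIES: dict[str, frozenset[str]] = {
    "positive":    frozenset("RKH"),
    "negative":    frozenset("DE"),
    "aromatic":    frozenset("FWYH"),
    "aliphatic":   frozenset("AVLI"),
    "hydrophobic": frozenset("AVLIMFWCP"),
    "polar":       frozenset("STNQYCH"),
}
CATEGORY_NAMES = ["polar", "positive", "negative", "hydrophobic", "aromatic", "aliphatic"]


# --- RNA moiety partition ---------------------------------------------------

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'"}
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}


def rna_moiety(atom_name: str) -> str:
    """Partition a nucleotide heavy atom into base / sugar / phosphate."""
    if atom_name in PHOSPHATE_ATOMS:
        return "phosphate"
    if atom_name in SUGAR_ATOMS:
        return "sugar"
    return "base"


PROTEIN_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def protein_moiety(atom_name: str) -> str:
    return "backbone" if atom_name in PROTEIN_BACKBONE_ATOMS else "sidechain"


# --- hydrogen-bond capability (heavy atoms only; no H required) -------------
# donors can donate, acceptors can accept; some atoms are both.

NT_DONORS: dict[str, set[str]] = {
    "A": {"N6", "O2'"},
    "G": {"N1", "N2", "O2'"},
    "C": {"N4", "O2'"},
    "U": {"N3", "O2'"},
}
NT_ACCEPTORS: dict[str, set[str]] = {
    "A": {"N1", "N3", "N7", "O2'", "O4'", "O3'", "O5'", "OP1", "OP2"},
    "G": {"O6", "N3", "N7", "O2'", "O4'", "O3'", "O5'", "OP1", "OP2"},
    "C": {"O2", "N3", "O2'", "O4'", "O3'", "O5'", "OP1", "OP2"},
    "U": {"O2", "O4", "O2'", "O4'", "O3'", "O5'", "OP1", "OP2"},
}

AA_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
    "CYS": {"SG"},
}
AA_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
# every amino acid: backbone N donates, backbone O (and OXT) accepts
AA_BACKBONE_DONORS = {"N"}
AA_BACKBONE_ACCEPTORS = {"O", "OXT"}


def aa_donor_atoms(resname3: str) -> set[str]:
    parent = canonical_residue_name(resname3)
    atoms = set(AA_BACKBONE_DONORS)
    atoms |= AA_SIDECHAIN_DONORS.get(parent, set())
    if parent == "PRO":  # proline backbone N has no H
        atoms.discard("N")
    return atoms


def aa_acceptor_atoms(resname3: str) -> set[str]:
    parent = canonical_residue_name(resname3)
    return set(AA_BACKBONE_ACCEPTORS) | AA_SIDECHAIN_ACCEPTORS.get(parent, set())


def nt_donor_atoms(base: str) -> set[str]:
    return set(NT_DONORS.get(canonical_residue_name(base), set()))


def nt_acceptor_atoms(base: str) -> set[str]:
    return set(NT_ACCEPTORS.get(canonical_residue_name(base), set()))


# --- planar moieties --------------------------------------------------------

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

BASE_RING_ATOMS: dict[str, list[str]] = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

#: planar side-chain groups eligible for stacking (aromatic + guanidinium)
AA_STACK_PLANES: dict[str, tuple[str, list[str]]] = {
    "PHE": ("aromatic-sidechain", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]),
    "TYR": ("aromatic-sidechain", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]),
    "TRP": ("aromatic-sidechain",
            ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]),
    "HIS": ("aromatic-sidechain", ["CG", "ND1", "CD2", "CE1", "NE2"]),
    "ARG": ("guanidinium", ["NE", "CZ", "NH1", "NH2"]),
}

#: planar side-chain groups eligible for pseudo (coplanar) base pairing
AA_PAIR_PLANES: dict[str, list[str]] = {
    "ARG": ["NE", "CZ", "NH1", "NH2"],
    "ASN": ["CG", "OD1", "ND2"],
    "GLN": ["CD", "OE1", "NE2"],
    "ASP": ["CG", "OD1", "OD2"],
    "GLU": ["CD", "OE1", "OE2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
}

#: glycosidic torsion atoms: O4'-C1'-N9-C4 (purines), O4'-C1'-N1-C2 (pyrimidines)
CHI_ATOMS = {
    "A": ("O4'", "C1'", "N9", "C4"),
    "G": ("O4'", "C1'", "N9", "C4"),
    "C": ("O4'", "C1'", "N1", "C2"),
    "U": ("O4'", "C1'", "N1", "C2"),
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

HYDROGEN_ELEMENTS = {"H", "D"}
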