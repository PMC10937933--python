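"""Atomic-structure model and mmCIF/PDB input/output.

A deliberately small coordinate model (:class:`Atom` / :class:`Residue` /
:class:`Chain` / :class:`ComplexStructure`) sits between the gemmi parsers and
the geometry code. Author residue numbering (``seq_id`` + insertion code) is
the coordinate system for all site mapping, because crosslink-site tables
reference author numbering.

Rules pinned here:

* only the first model of multi-model files is kept (overridable),
* alternate locations collapse to the highest-occupancy atom
  (ties: altloc ``A``, then first encountered),
* hydrogens are kept but flagged, and excluded from all distance work
  downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import chem

logger = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed under the named dialect."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in chem.HYDROGEN_ELEMENTS

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def kind(self) -> str:
        return chem.residue_kind(self.name)

    @property
    def parent_name(self) -> str:
        """Standard parent residue name (modified residues mapped through aliases)."""
        return chem.canonical_residue_name(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_id}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.empty((0, 3))
        return np.stack([a.xyz for a in atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def polymer_class(self) -> str:
        return classify_chain(self)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self):
        return len(self.residues)


@dataclass
class ComplexStructure:
    accession: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def __post_init__(self):
        keys = [r.key for c in self.chains for r in c.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_id, icode) residue keys")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def residues(self, polymer_class: str | None = None) -> list[Residue]:
        out = []
        for c in self.chains:
            if polymer_class is not None and c.polymer_class != polymer_class:
                continue
            out.extend(c.residues)
        return out

    def rna_residues(self) -> list[Residue]:
        return [r for r in self.residues("RNA") if r.kind == "ribonucleotide"]

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues("protein") if r.kind == "amino-acid"]

    def has_interface(self) -> bool:
        return bool(self.rna_residues()) and bool(self.protein_residues())


def classify_chain(chain: Chain) -> str:
    """Majority vote over polymer residue kinds; waters/ligands-only -> ``other``.

    Ribonucleotides additionally require an O2' atom when the residue name is a
    bare nucleotide letter, which separates RNA from DNA in permissively named
    files.
    """
    counts = {"amino-acid": 0, "ribonucleotide": 0, "deoxynucleotide": 0}
    for res in chain.residues:
        kind = res.kind
        if kind == "ribonucleotide" and res.atoms and res.atom("O2'") is None \
                and res.atom("C1'") is not None:
            kind = "deoxynucleotide"
        if kind in counts:
            counts[kind] += 1
    total = sum(counts.values())
    if total == 0:
        return "other"
    best = max(counts, key=lambda k: counts[k])
    if counts[best] * 2 < total:  # no strict majority among polymer residues
        return "other"
    return {"amino-acid": "protein",
            "ribonucleotide": "RNA",
            "deoxynucleotide": "DNA"}[best]


def classify_chains(structure: ComplexStructure) -> dict[str, str]:
    """Per-chain polymer class, e.g. ``{'A': 'protein', 'B': 'RNA'}``."""
    if not structure.chains:
        raise ValueError("empty structure")
    return {c.chain_id: c.polymer_class for c in structure.chains}


# --- reading ----------------------------------------------------------------

def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties -> altloc 'A' or first."""
    by_name: dict[str, list[tuple[int, Atom]]] = {}
    for i, a in enumerate(atoms):
        by_name.setdefault(a.name, []).append((i, a))
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
            continue
        def rank(item):
            i, a = item
            return (-a.occupancy, 0 if a.altloc == "A" else 1, i)
        kept.append(min(group, key=rank))
    kept.sort(key=lambda item: item[0])
    return [a for _, a in kept]


def read_structure(path: str | Path, format: str = "auto",
                   model_index: int = 0) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    ``format`` is ``pdb``, ``mmcif`` or ``auto`` (by extension/content). Files
    with no protein or no RNA chain are readable; a warning is logged so
    interface analyses can refuse them later.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    if model_index >= len(st):
        raise StructureFormatError(
            f"model {model_index} requested but file has {len(st)} model(s)")
    model = st[model_index]

    chains: list[Chain] = []
    for gchain in model:
        residues = []
        for gres in gchain:
            if gres.name in chem.SOLVENT:
                continue
            atoms = [Atom(name=ga.name,
                          element=ga.element.name or "X",
                          xyz=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                          altloc=ga.altloc.strip() if ga.altloc else "",
                          occupancy=float(ga.occ))
                     for ga in gres]
            atoms = _resolve_altlocs(atoms)
            residues.append(Residue(
                chain_id=gchain.name,
                seq_id=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                name=gres.name,
                atoms=atoms))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    structure = ComplexStructure(
        accession=(st.name or path.stem).lower(), chains=chains,
        model_index=model_index)
    classes = set(classify_chains(structure).values()) if chains else set()
    if "protein" not in classes or "RNA" not in classes:
        logger.warning("%s: not a protein-RNA complex (chain classes: %s)",
                       path.name, sorted(classes))
    for res in structure.residues():
        if res.kind == "other" and res.name not in chem.SOLVENT:
            logger.warning("unmapped residue %s excluded from feature tables",
                           res.label)
    return structure


# --- writing ----------------------------------------------------------------

def write_structure(structure: ComplexStructure, path: str | Path,
                    format: str = "auto") -> Path:
    """Write a structure as PDB or mmCIF; the file re-reads with read_structure."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = structure.accession
    model = gemmi.Model(1)
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = a.occupancy
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        elif format == "mmcif":
            st.make_mmcif_document().write_file(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path
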