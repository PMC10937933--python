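"""Fixed feature schemas tabulated from interface annotations.

Two pinned schemas feed the classifiers:

* **nt-v1** — 246 numeric features per nucleotide in exactly 15 groups:
  eight typed-contact groups x (20 amino acids + 6 categories) = 208 counts
  (stacking; pseudo-pairing; hydrogen bonds split base/sugar/phosphate x
  sidechain/backbone), sugar-pucker one-hots (10 classes + 2 families),
  base orientation (2), secondary-structure element (8), pairing status (2),
  5'/3' neighbor-stacking flags (2), per-class totals (8) and an interface
  summary (4).
* **aa-v1** — 36 numeric features per amino acid: hydrogen-bond counts per
  base x RNA moiety x protein moiety (4 x 3 x 2 = 24), stacking counts per
  base (4), pseudo-pair counts per base (4) and a summary block (4).

Category aggregates (polar/positive/negative/hydrophobic/aromatic/aliphatic)
are sums of their member amino-acid columns; the categories overlap by
design (His is aromatic, positive and polar). Optional identity blocks add
base / overlapping-dinucleotide one-hots (nucleotides) or amino-acid
one-hots plus dipeptide categoricals (amino acids).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .geometry import (InterfaceAnnotation, PUCKER_CLASSES, SECONDARY_ELEMENTS)
from .structure import ComplexStructure, Residue

CONTACT_CLASSES = [
    "stack", "pseudo", "hb_base_sc", "hb_base_bb",
    "hb_sugar_sc", "hb_sugar_bb", "hb_phos_sc", "hb_phos_bb",
]

_HB_CLASS = {("base", "sidechain"): "hb_base_sc",
             ("base", "backbone"): "hb_base_bb",
             ("sugar", "sidechain"): "hb_sugar_sc",
             ("sugar", "backbone"): "hb_sugar_bb",
             ("phosphate", "sidechain"): "hb_phos_sc",
             ("phosphate", "backbone"): "hb_phos_bb"}


def _sanitize(name: str) -> str:
    return name.replace("'", "p").replace("-", "_")


@dataclass(frozen=True)
class FeatureSchema:
    version: str
    columns: tuple[str, ...]
    groups: tuple[str, ...]           # parallel to columns
    group_names: tuple[str, ...]      # ordered unique groups

    def __post_init__(self):
        if len(self.columns) != len(set(self.columns)):
            raise ValueError("duplicate feature names in schema")
        if len(self.columns) != len(self.groups):
            raise ValueError("columns/groups length mismatch")


def _build_nt_schema() -> FeatureSchema:
    cols, groups = [], []
    for cls in CONTACT_CLASSES:
        for aa in chem.AMINO_ACID_LETTERS:
            cols.append(f"{cls}__{aa}")
            groups.append(cls)
        for cat in chem.CATEGORY_NAMES:
            cols.append(f"{cls}__cat_{cat}")
            groups.append(cls)
    for pc in PUCKER_CLASSES:
        cols.append(f"pucker__{_sanitize(pc)}")
        groups.append("sugar-pucker")
    for fam in ("N", "S"):
        cols.append(f"pucker_family__{fam}")
        groups.append("sugar-pucker")
    for o in ("anti", "syn"):
        cols.append(f"orientation__{o}")
        groups.append("base-orientation")
    for el in SECONDARY_ELEMENTS:
        cols.append(f"element__{_sanitize(el)}")
        groups.append("secondary-element")
    for p in ("yes", "no"):
        cols.append(f"paired__{p}")
        groups.append("pairing-status")
    for f in ("stacked_5p", "stacked_3p"):
        cols.append(f)
        groups.append("neighbor-stacking")
    for cls in CONTACT_CLASSES:
        cols.append(f"total__{cls}")
        groups.append("class-totals")
    for s in ("n_contacting_residues", "n_hbonds_total",
              "n_typed_interactions_total", "min_contact_distance"):
        cols.append(s)
        groups.append("interface-summary")
    group_names = tuple(dict.fromkeys(groups))
    return FeatureSchema("nt-v1", tuple(cols), tuple(groups), group_names)


def _build_aa_schema() -> FeatureSchema:
    cols, groups = [], []
    for base in "ACGU":
        for moiety in ("base", "sugar", "phos"):
            for pm in ("sc", "bb"):
                cols.append(f"hb_{base}_{moiety}_{pm}")
                groups.append("hydrogen-bonds")
    for base in "ACGU":
        cols.append(f"stack__{base}")
        groups.append("stacking")
    for base in "ACGU":
        cols.append(f"pseudo__{base}")
        groups.append("pseudo-pairing")
    for s in ("total_hbonds", "total_stacks", "total_pseudo_pairs",
              "n_contacted_nucleotides"):
        cols.append(s)
        groups.append("summary")
    return FeatureSchema("aa-v1", tuple(cols), tuple(groups),
                         tuple(dict.fromkeys(groups)))


NT_SCHEMA = _build_nt_schema()
AA_SCHEMA = _build_aa_schema()
SCHEMAS = {s.version: s for s in (NT_SCHEMA, AA_SCHEMA)}

assert len(NT_SCHEMA.columns) == 246 and len(NT_SCHEMA.group_names) == 15
assert len(AA_SCHEMA.columns) == 36


# --- attribution helpers ----------------------------------------------------

def _stack_aa_letter(record) -> str | None:
    """Amino-acid letter a protein stack is attributed to (peptide-bond stacks
    go to the N-terminal residue of the peptide unit, once)."""
    if record.partner_kind == "nucleotide-base":
        return None
    res = record.partners[0]
    return chem.AMINO_ACIDS_3TO1.get(res.parent_name)


def _aa_letter(res: Residue) -> str | None:
    return chem.AMINO_ACIDS_3TO1.get(res.parent_name)


# --- nucleotide features ----------------------------------------------------

def build_nucleotide_features(structure: ComplexStructure,
                              ann: InterfaceAnnotation,
                              nt: Residue) -> pd.Series:
    """Fill the 246-column nt-v1 vector for one nucleotide."""
    if nt.key not in {r.key for r in structure.rna_residues()}:
        raise KeyError(f"{nt.label} is not a ribonucleotide of this structure")
    v = pd.Series(0.0, index=list(NT_SCHEMA.columns))

    def bump(cls: str, letter: str):
        v[f"{cls}__{letter}"] += 1
        for cat, members in chem.AA_CATEGORIES.items():
            if letter in members:
                v[f"{cls}__cat_{cat}"] += 1
        v[f"total__{cls}"] += 1

    for s in ann.stacks:
        if s.nt.key != nt.key:
            continue
        letter = _stack_aa_letter(s)
        if letter:
            bump("stack", letter)
    for p in ann.pseudo_pairs:
        if p.nt.key != nt.key:
            continue
        letter = _aa_letter(p.aa)
        if letter:
            bump("pseudo", letter)
    for b in ann.hbonds:
        if b.nt.key != nt.key:
            continue
        letter = _aa_letter(b.aa)
        if letter:
            bump(_HB_CLASS[(b.rna_moiety, b.protein_moiety)], letter)

    pucker = ann.puckers.get(nt.key)
    if pucker is not None:
        v[f"pucker__{_sanitize(pucker.pucker_class)}"] = 1
        v[f"pucker_family__{pucker.family}"] = 1
    orient = ann.orientations.get(nt.key)
    if orient is not None:
        v[f"orientation__{orient.orientation}"] = 1
    sec = ann.secondary.get(nt.key)
    if sec is not None:
        v[f"element__{_sanitize(sec.element)}"] = 1
        v["paired__yes" if sec.paired else "paired__no"] = 1
        v["stacked_5p"] = int(sec.stacked_5p)
        v["stacked_3p"] = int(sec.stacked_3p)

    contacting = {c.aa.key for c in ann.contacts if c.nt.key == nt.key}
    # typed interactions slightly beyond the generic cutoff still count as contacting
    typed_aas = ({b.aa.key for b in ann.hbonds if b.nt.key == nt.key}
                 | {p.aa.key for p in ann.pseudo_pairs if p.nt.key == nt.key}
                 | {r.key for s in ann.stacks if s.nt.key == nt.key
                    and s.partner_kind != "nucleotide-base" for r in s.partners})
    v["n_contacting_residues"] = len(contacting | typed_aas)
    v["n_hbonds_total"] = sum(1 for b in ann.hbonds if b.nt.key == nt.key)
    v["n_typed_interactions_total"] = (
        v["n_hbonds_total"]
        + sum(1 for s in ann.stacks
              if s.nt.key == nt.key and s.partner_kind != "nucleotide-base")
        + sum(1 for p in ann.pseudo_pairs if p.nt.key == nt.key))
    dists = [c.min_distance for c in ann.contacts if c.nt.key == nt.key]
    v["min_contact_distance"] = min(dists) if dists else 0.0
    return v


# --- amino-acid features ----------------------------------------------------

def build_aa_features(structure: ComplexStructure, ann: InterfaceAnnotation,
                      aa: Residue) -> pd.Series:
    """Fill the 36-column aa-v1 vector for one amino acid."""
    if aa.key not in {r.key for r in structure.protein_residues()}:
        raise KeyError(f"{aa.label} is not an amino acid of this structure")
    v = pd.Series(0.0, index=list(AA_SCHEMA.columns))
    moiety_tag = {"base": "base", "sugar": "sugar", "phosphate": "phos"}
    pm_tag = {"sidechain": "sc", "backbone": "bb"}
    for b in ann.hbonds:
        if b.aa.key != aa.key:
            continue
        base = b.nt.parent_name
        if base not in "ACGU":
            continue
        v[f"hb_{base}_{moiety_tag[b.rna_moiety]}_{pm_tag[b.protein_moiety]}"] += 1
        v["total_hbonds"] += 1
    for s in ann.stacks:
        if s.partner_kind == "nucleotide-base":
            continue
        if s.partners[0].key != aa.key:
            continue
        base = s.nt.parent_name
        if base in "ACGU":
            v[f"stack__{base}"] += 1
            v["total_stacks"] += 1
    for p in ann.pseudo_pairs:
        if p.aa.key != aa.key:
            continue
        base = p.nt.parent_name
        if base in "ACGU":
            v[f"pseudo__{base}"] += 1
            v["total_pseudo_pairs"] += 1
    contacted = {c.nt.key for c in ann.contacts if c.aa.key == aa.key}
    contacted |= {b.nt.key for b in ann.hbonds if b.aa.key == aa.key}
    contacted |= {p.nt.key for p in ann.pseudo_pairs if p.aa.key == aa.key}
    contacted |= {s.nt.key for s in ann.stacks
                  if s.partner_kind != "nucleotide-base"
                  and s.partners[0].key == aa.key}
    v["n_contacted_nucleotides"] = len(contacted)
    return v


# --- table builders ---------------------------------------------------------

_META_COLS = ["accession", "chain", "seq_id", "icode", "residue"]


def nucleotide_feature_table(structure: ComplexStructure,
                             ann: InterfaceAnnotation) -> pd.DataFrame:
    """One row per ribonucleotide: metadata + the 246 nt-v1 features."""
    rows = []
    for nt in structure.rna_residues():
        meta = pd.Series([structure.accession, nt.chain_id, nt.seq_id,
                          nt.icode, nt.parent_name], index=_META_COLS)
        rows.append(pd.concat([meta, build_nucleotide_features(structure, ann, nt)]))
    return pd.DataFrame(rows).reset_index(drop=True)


def aa_feature_table(structure: ComplexStructure,
                     ann: InterfaceAnnotation) -> pd.DataFrame:
    """One row per amino acid: metadata + the 36 aa-v1 features."""
    rows = []
    for aa in structure.protein_residues():
        meta = pd.Series([structure.accession, aa.chain_id, aa.seq_id,
                          aa.icode, aa.parent_name], index=_META_COLS)
        rows.append(pd.concat([meta, build_aa_features(structure, ann, aa)]))
    return pd.DataFrame(rows).reset_index(drop=True)


# --- identity encodings -----------------------------------------------------

BASES = "ACGU"
DINUCLEOTIDES = [a + b for a in BASES for b in BASES]


def encode_nucleotide_identity(base: str, left: str | None,
                               right: str | None) -> pd.Series:
    """Base one-hot (4) + overlapping-dinucleotide one-hots (left 16 + right 16).

    Terminal positions leave the corresponding dinucleotide block all-zero.
    """
    cols = ([f"base__{b}" for b in BASES]
            + [f"dileft__{d}" for d in DINUCLEOTIDES]
            + [f"diright__{d}" for d in DINUCLEOTIDES])
    v = pd.Series(0.0, index=cols)
    if base in BASES:
        v[f"base__{base}"] = 1
        if left and left in BASES:
            v[f"dileft__{left}{base}"] = 1
        if right and right in BASES:
            v[f"diright__{base}{right}"] = 1
    return v


def encode_aa_identity(letter: str, prev: str | None,
                       next_: str | None) -> pd.Series:
    """Amino-acid one-hot (20) + preceding/following dipeptide categoricals."""
    cols = [f"aa__{a}" for a in chem.AMINO_ACID_LETTERS]
    v = pd.Series(0.0, index=cols)
    if letter in chem.AMINO_ACIDS_1TO3:
        v[f"aa__{letter}"] = 1
    v["dipep_prev"] = f"{prev}{letter}" if prev else ""
    v["dipep_next"] = f"{letter}{next_}" if next_ else ""
    return v


def expand_dipeptides(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot the dipeptide categoricals over pairs observed in the table
    (avoids 400-wide constant-zero blocks)."""
    out = df.copy()
    for col in ("dipep_prev", "dipep_next"):
        if col not in out.columns:
            continue
        observed = sorted({v for v in out[col] if v})
        for pair in observed:
            out[f"{col}__{pair}"] = (out[col] == pair).astype(float)
        out = out.drop(columns=[col])
    return out


def add_identity_block(table: pd.DataFrame, sequences: dict[str, str],
                       kind: str = "nucleotide") -> pd.DataFrame:
    """Append identity one-hots using per-chain sequences (5'->3' / N->C)."""
    extra = []
    for _, row in table.iterrows():
        seq = sequences.get(row["chain"], "")
        pos = None
        # locate by order of appearance of this chain in the table
        chain_rows = table[table["chain"] == row["chain"]].reset_index()
        pos = int(chain_rows[chain_rows["seq_id"] == row["seq_id"]].index[0])
        left = seq[pos - 1] if pos > 0 else None
        right = seq[pos + 1] if pos + 1 < len(seq) else None
        if kind == "nucleotide":
            extra.append(encode_nucleotide_identity(seq[pos] if pos < len(seq)
                                                    else row["residue"],
                                                    left, right))
        else:
            letter = chem.AMINO_ACIDS_3TO1.get(row["residue"], "")
            extra.append(encode_aa_identity(letter, left, right))
    return pd.concat([table.reset_index(drop=True),
                      pd.DataFrame(extra).reset_index(drop=True)], axis=1)


# --- TSV round-trip ---------------------------------------------------------

class SchemaMismatchError(ValueError):
    pass


def export_table(df: pd.DataFrame, path: str | Path, schema: FeatureSchema):
    """Write a feature table as TSV with a self-describing schema header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# xlink3d-feature-table schema={schema.version}\n")
        for g in schema.group_names:
            members = [c for c, gg in zip(schema.columns, schema.groups) if gg == g]
            fh.write(f"# group {g}: {' '.join(members)}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def import_table(path: str | Path, schema: FeatureSchema | None = None
                 ) -> pd.DataFrame:
    """Read a feature-table TSV, validating schema version, column count and
    order against the header's declared schema."""
    path = Path(path)
    version = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# xlink3d-feature-table"):
            version = first.strip().split("schema=")[-1]
    if version is None:
        raise SchemaMismatchError(f"{path}: missing schema header")
    declared = SCHEMAS.get(version)
    if declared is None:
        raise SchemaMismatchError(f"{path}: unknown schema version {version!r}")
    if schema is not None and schema.version != version:
        raise SchemaMismatchError(
            f"{path}: expected schema {schema.version}, found {version}")
    df = pd.read_csv(path, sep="\t", comment="#")
    feature_cols = [c for c in df.columns if c not in _META_COLS
                    and c != "label"]
    expected = list(declared.columns)
    if len(feature_cols) != len(expected):
        raise SchemaMismatchError(
            f"{path}: {len(feature_cols)} feature columns, "
            f"schema {version} requires {len(expected)}")
    for i, (got, want) in enumerate(zip(feature_cols, expected)):
        if got != want:
            raise SchemaMismatchError(
                f"{path}: column {i} is {got!r}, expected {want!r}")
    return df
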