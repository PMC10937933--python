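"""From assay evidence to crosslink labels.

CLIP pipelines report, for every transcriptome instance of an RNA ligand
sequence, the offsets of crosslink-induced mutation/truncation events. This
module turns those per-instance tables into per-position crosslink calls
using a two-branch frequency rule:

    crosslinked  iff  (n >= 20 instances and frequency >= 0.3)
                   or (n >= 10 instances and frequency >= 0.5)

where n counts instances carrying at least one crosslink and the frequency
at a position is the fraction of those instances crosslinked there. Offsets
are 0-based end-exclusive throughout. A window extension of 1-2 nt each side
admits events immediately flanking the matched subsequence; called positions
outside the modeled ligand are reported but cannot be mapped to residues.

Protein crosslink sites (residue-resolution interactome capture) arrive in
full-protein numbering and are projected onto structure chains by global
pairwise alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from . import chem
from .structure import Chain, Residue

logger = logging.getLogger(__name__)


# --- instance tables --------------------------------------------------------

@dataclass
class LigandInstanceTable:
    """CLIP evidence for one RNA ligand: rows of (instance id, 0-based
    crosslink offsets within the instance, possibly empty)."""
    ligand: str
    instances: list[tuple[str, tuple[int, ...]]]
    window_ext: int = 0  # 0-2 nt each side

    def __post_init__(self):
        self.ligand = self.ligand.upper().replace("T", "U")
        if self.window_ext not in (0, 1, 2):
            raise ValueError("window extension must be 0, 1 or 2")
        n = len(self.ligand)
        for row_i, (iid, offsets) in enumerate(self.instances):
            for off in offsets:
                if not (-self.window_ext <= off < n + self.window_ext):
                    raise ValueError(
                        f"row {row_i} ({iid}): offset {off} outside "
                        f"[-{self.window_ext}, {n + self.window_ext})")


@dataclass
class CrosslinkCallConfig:
    min_instances_primary: int = 20
    min_freq_primary: float = 0.3
    min_instances_fallback: int = 10
    min_freq_fallback: float = 0.5
    #: denominator: instances carrying >= 1 crosslink ('crosslinked', pinned)
    #: or every matched instance ('all')
    denominator: str = "crosslinked"

    def __post_init__(self):
        for f in (self.min_freq_primary, self.min_freq_fallback):
            if not (0.0 < f <= 1.0):
                raise ValueError("frequencies must lie in (0, 1]")
        if self.min_instances_fallback > self.min_instances_primary:
            raise ValueError("fallback instance threshold exceeds primary")


def position_crosslink_frequency(table: LigandInstanceTable,
                                 denominator: str = "crosslinked"
                                 ) -> pd.DataFrame:
    """Per-position crosslink count and frequency.

    frequency[p] = (#instances with a crosslink at p) / n, with n the number
    of instances carrying >= 1 crosslink (default) or all instances. Counts
    are conserved: their sum equals the total number of crosslink events.
    """
    if not table.instances:
        raise ValueError("empty instance table")
    if not any(offsets for _, offsets in table.instances):
        raise ValueError("no instance carries a crosslink offset")
    w = table.window_ext
    positions = range(-w, len(table.ligand) + w)
    counts = {p: 0 for p in positions}
    for _, offsets in table.instances:
        for p in set(offsets):  # an instance contributes once per position
            counts[p] += 1
    if denominator == "crosslinked":
        n = sum(1 for _, offsets in table.instances if offsets)
    elif denominator == "all":
        n = len(table.instances)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    df = pd.DataFrame({"position": list(positions),
                       "count": [counts[p] for p in positions]})
    df["frequency"] = df["count"] / n
    df.attrs["n_instances"] = n
    return df


def call_crosslinked_positions(freqs: pd.DataFrame, n_instances: int,
                               config: CrosslinkCallConfig | None = None
                               ) -> pd.DataFrame:
    """Apply the two-branch threshold rule; adds a boolean 'crosslinked'."""
    cfg = config or CrosslinkCallConfig()
    n = n_instances
    f = freqs["frequency"].to_numpy()
    called = ((n >= cfg.min_instances_primary) & (f >= cfg.min_freq_primary)) | \
             ((n >= cfg.min_instances_fallback) & (f >= cfg.min_freq_fallback))
    out = freqs.copy()
    out["crosslinked"] = called
    return out


def call_sites(table: LigandInstanceTable,
               config: CrosslinkCallConfig | None = None) -> pd.DataFrame:
    """Frequency counting + threshold calling in one step."""
    cfg = config or CrosslinkCallConfig()
    freqs = position_crosslink_frequency(table, denominator=cfg.denominator)
    return call_crosslinked_positions(freqs, freqs.attrs["n_instances"], cfg)


# --- TSV I/O ----------------------------------------------------------------

def read_instance_table(path: str | Path) -> LigandInstanceTable:
    """TSV with a '# ligand SEQ' header and columns instance_id, offsets
    (comma-separated 0-based positions, may be empty)."""
    path = Path(path)
    ligand = None
    window = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# ligand"):
                ligand = line.split()[-1]
            elif line.startswith("# window_ext"):
                window = int(line.split()[-1])
            elif not line.startswith("#"):
                break
    if ligand is None:
        raise ValueError(f"{path}: missing '# ligand' header")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    instances = []
    for _, row in df.iterrows():
        offs = tuple(int(x) for x in str(row["offsets"]).split(",") if x != "")
        instances.append((str(row["instance_id"]), offs))
    return LigandInstanceTable(ligand=ligand, instances=instances,
                               window_ext=window)


def write_instance_table(table: LigandInstanceTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ligand {table.ligand}\n")
        fh.write(f"# window_ext {table.window_ext}\n")
        fh.write("instance_id\toffsets\n")
        for iid, offsets in table.instances:
            fh.write(f"{iid}\t{','.join(map(str, offsets))}\n")
    return path


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    """BED-like TSV: accession, chain, seq_id, label."""
    labels.to_csv(path, sep="\t", index=False)
    return Path(path)


# --- protein-site mapping ---------------------------------------------------

@dataclass
class ProteinXLSite:
    protein_id: str
    position: int       # 1-based full-protein numbering
    amino_acid: str     # one-letter


@dataclass
class MappedSite:
    site: ProteinXLSite
    residue: Residue | None
    reason: str = ""

    @property
    def mapped(self) -> bool:
        return self.residue is not None


def _chain_sequence(chain: Chain) -> tuple[str, list[Residue]]:
    residues = [r for r in chain.residues if r.kind == "amino-acid"]
    seq = "".join(chem.AMINO_ACIDS_3TO1.get(r.parent_name, "X") for r in residues)
    return seq, residues


def map_protein_site_to_chain(site: ProteinXLSite, chain: Chain,
                              full_sequence: str,
                              min_identity: float = 0.9,
                              window: int = 10) -> MappedSite:
    """Locate a full-protein crosslink site on a structure chain.

    Global pairwise alignment (match +1, mismatch -1, gap -2) of the full
    protein sequence against the chain's observed sequence; the mapping is
    accepted only when the aligned residue letter matches and local identity
    in a +-``window`` neighborhood of aligned columns is >= ``min_identity``.
    """
    chain_seq, residues = _chain_sequence(chain)
    if not chain_seq:
        return MappedSite(site, None, "chain has no amino acids")
    if not (1 <= site.position <= len(full_sequence)):
        return MappedSite(site, None, "position outside full sequence")
    if full_sequence[site.position - 1] != site.amino_acid:
        return MappedSite(site, None,
                          f"full sequence has {full_sequence[site.position - 1]} "
                          f"at {site.position}, site says {site.amino_acid}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(full_sequence, chain_seq)[0]
    # per-column index pairs (i in full, j in chain), gaps as None
    pairs = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        pairs.extend((s1 + k, s2 + k) for k in range(e1 - s1))
    by_full = {i: j for i, j in pairs}
    j = by_full.get(site.position - 1)
    if j is None:
        return MappedSite(site, None, "site falls in an alignment gap")
    if chain_seq[j] != site.amino_acid:
        return MappedSite(site, None,
                          f"aligned chain residue is {chain_seq[j]}, "
                          f"not {site.amino_acid}")
    near = [(i, jj) for i, jj in pairs
            if abs(i - (site.position - 1)) <= window]
    ident = sum(full_sequence[i] == chain_seq[jj] for i, jj in near) / len(near)
    if ident < min_identity:
        return MappedSite(site, None,
                          f"local identity {ident:.2f} below {min_identity}")
    return MappedSite(site, residues[j])


# --- redundancy & contact split ---------------------------------------------

@dataclass
class CandidateStructure:
    accession: str
    crosslink_count: int
    nonzero_feature_count: int
    payload: object = None


def select_nonredundant(candidates: list[CandidateStructure]) -> CandidateStructure:
    """Among structures for one domain, keep the one with the most crosslink
    evidence, then the most non-zero features, then the lexicographically
    smallest accession (pinned tie-break)."""
    if not candidates:
        raise ValueError("no candidates")
    return min(candidates,
               key=lambda c: (-c.crosslink_count, -c.nonzero_feature_count,
                              c.accession))


@dataclass
class LabeledSite:
    residue_key: tuple
    role: str              # 'nucleotide' or 'amino-acid'
    crosslinked: bool
    contacting: bool
    residue_name: str = ""  # one-letter amino acid / base


def split_by_contact(sites: list[LabeledSite]) -> pd.DataFrame:
    """Per-amino-acid crosslinking frequency, split by RNA contact.

    frequency(aa, group) = crosslinked / total within the group; a group
    with no residues of that amino acid is undefined (NaN), not 0. Fold
    change = contacting frequency / non-contacting frequency.
    """
    rows = []
    letters = sorted({s.residue_name for s in sites})
    for letter in letters:
        row = {"residue": letter}
        freqs = {}
        for label, group in (("contacting", True), ("non_contacting", False)):
            members = [s for s in sites
                       if s.residue_name == letter and s.contacting is group]
            if not members:
                freqs[label] = np.nan
            else:
                freqs[label] = sum(s.crosslinked for s in members) / len(members)
            row[f"n_{label}"] = len(members)
            row[f"freq_{label}"] = freqs[label]
        with np.errstate(divide="ignore", invalid="ignore"):
            row["fold_change"] = (freqs["contacting"] / freqs["non_contacting"]
                                  if freqs.get("non_contacting") not in (0, np.nan)
                                  else np.nan)
            if (not np.isnan(freqs["contacting"])
                    and not np.isnan(freqs["non_contacting"])
                    and freqs["non_contacting"] > 0):
                row["fold_change"] = freqs["contacting"] / freqs["non_contacting"]
            else:
                row["fold_change"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
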