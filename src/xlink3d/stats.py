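"""Descriptive group comparisons and alignment-profile projection.

Composition tests (Pearson chi-squared), enrichment (Fisher's exact test with
the two-sided p defined as the sum of all conditional table probabilities not
exceeding the observed one), rate comparisons (exact binomial test of one
group's event count against the other group's rate as the null), and the
projection of per-protein crosslink sites onto multiple-sequence-alignment
columns with per-column information content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio import AlignIO


def composition_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on an observed table.

    Returns (statistic, p). Rows/columns that are entirely zero are dropped
    so expected counts stay computable.
    """
    obs = np.asarray(table, dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def fisher_exact(table) -> tuple[float, float]:
    """Sample odds ratio and exact two-sided p for a 2x2 table.

    Two-sided p is the sum of hypergeometric probabilities of all tables
    (with the observed margins) whose probability does not exceed the
    observed table's.
    """
    obs = np.asarray(table, dtype=int)
    if obs.shape != (2, 2):
        raise ValueError("fisher_exact needs a 2x2 table")
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    odds, p = sps.fisher_exact(obs, alternative="two-sided")
    return float(odds), float(p)


def rate_comparison(events_a: int, n_a: int, events_b: int, n_b: int
                    ) -> float:
    """Exact binomial test of group-a events against group-b's rate.

    H0: group a's events are Binomial(n_a, p0) with p0 = events_b / n_b
    (the null construction is recorded in output metadata by callers).
    """
    if min(events_a, n_a, events_b, n_b) < 0 or n_a == 0 or n_b == 0:
        raise ValueError("invalid counts")
    p0 = events_b / n_b
    if p0 == 0.0:
        return 1.0 if events_a == 0 else 0.0
    if p0 >= 1.0:
        return 1.0 if events_a == n_a else 0.0
    return float(sps.binomtest(events_a, n_a, p0, alternative="two-sided").pvalue)


# --- alignment-profile projection -------------------------------------------

@dataclass
class AlignmentProfile:
    """Per-column alignment summary with projected crosslink counts."""
    columns: int
    residue_counts: pd.DataFrame        # columns x residue letters
    information_content: np.ndarray     # bits, per column
    crosslink_counts: np.ndarray        # per column
    sequence_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.residue_counts.copy()
        df["information_bits"] = self.information_content
        df["crosslinks"] = self.crosslink_counts
        return df


class SiteMismatchError(ValueError):
    pass


def project_crosslinks(alignment_path, sites: list[tuple[str, int, str]],
                       fmt: str = "fasta") -> AlignmentProfile:
    """Project (protein id, 1-based ungapped position, letter) crosslink
    sites onto alignment columns.

    Information content per column is log2(20) minus the Shannon entropy of
    residue frequencies (gaps excluded from the frequencies). The total
    projected crosslink count is conserved; a site whose letter disagrees
    with the ungapped sequence raises :class:`SiteMismatchError` naming the
    sequence and position.
    """
    aln = AlignIO.read(alignment_path, fmt)
    ids = [rec.id for rec in aln]
    ncol = aln.get_alignment_length()
    # gap-aware coordinate maps: (seq id, ungapped pos 0-based) -> column
    colmap: dict[str, list[int]] = {}
    for rec in aln:
        cols = []
        for c, ch in enumerate(str(rec.seq)):
            if ch != "-":
                cols.append(c)
        colmap[rec.id] = cols

    letters = sorted({ch for rec in aln for ch in str(rec.seq).upper()
                      if ch != "-"})
    counts = pd.DataFrame(0, index=range(ncol), columns=letters)
    for rec in aln:
        for c, ch in enumerate(str(rec.seq).upper()):
            if ch != "-":
                counts.loc[c, ch] += 1

    ic = np.zeros(ncol)
    for c in range(ncol):
        row = counts.loc[c]
        total = row.sum()
        if total == 0:
            continue
        freq = row[row > 0] / total
        entropy = float(-(freq * np.log2(freq)).sum())
        ic[c] = math.log2(20) - entropy
    ic = np.clip(ic, 0.0, math.log2(20))

    xl = np.zeros(ncol)
    for pid, pos, letter in sites:
        if pid not in colmap:
            raise SiteMismatchError(f"protein {pid!r} not in alignment")
        cols = colmap[pid]
        if not (1 <= pos <= len(cols)):
            raise SiteMismatchError(
                f"{pid}: position {pos} outside ungapped length {len(cols)}")
        col = cols[pos - 1]
        rec = next(r for r in aln if r.id == pid)
        found = str(rec.seq)[col].upper()
        if found != letter.upper():
            raise SiteMismatchError(
                f"{pid} position {pos}: alignment has {found}, site says {letter}")
        xl[col] += 1

    return AlignmentProfile(columns=ncol, residue_counts=counts,
                            information_content=ic, crosslink_counts=xl,
                            sequence_ids=ids)
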