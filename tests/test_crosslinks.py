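"""Crosslink calling, protein-site mapping, redundancy and contact splits."""

import numpy as np
import pytest

from xlink3d.crosslinks import (CandidateStructure, CrosslinkCallConfig,
                                LabeledSite, LigandInstanceTable,
                                ProteinXLSite, call_crosslinked_positions,
                                call_sites, map_protein_site_to_chain,
                                position_crosslink_frequency,
                                read_instance_table, select_nonredundant,
                                split_by_contact, write_instance_table)
from xlink3d.structure import Atom, Chain, Residue


def _table(ligand, rows):
    return LigandInstanceTable(ligand, [(f"i{k}", tuple(r))
                                        for k, r in enumerate(rows)])


# --- frequency counting -----------------------------------------------------

def test_all_instances_crosslinked_at_one_offset():
    t = _table("UGCAUGU", [[2]] * 10)
    f = position_crosslink_frequency(t)
    assert f.loc[f.position == 2, "frequency"].item() == 1.0
    assert f["count"].sum() == 10


def test_frequency_direct_arithmetic():
    rows = [[3]] * 10 + [[1]] * 15
    f = position_crosslink_frequency(_table("UGCAUGU", rows))
    assert f.attrs["n_instances"] == 25
    assert f.loc[f.position == 3, "frequency"].item() == pytest.approx(0.4)


def test_frequencies_match_row_tally_oracle():
    rng = np.random.default_rng(5)
    ligand = "UGCAUGUA"
    rows = []
    for _ in range(40):
        rows.append(list(np.flatnonzero(rng.random(len(ligand)) < 0.3)))
    t = _table(ligand, rows)
    f = position_crosslink_frequency(t)
    n = sum(1 for r in rows if r)
    for p in range(len(ligand)):
        count = sum(1 for r in rows if p in r)
        assert f.loc[f.position == p, "count"].item() == count
        assert f.loc[f.position == p, "frequency"].item() == pytest.approx(count / n)
    # counts conserved
    assert f["count"].sum() == sum(len(set(r)) for r in rows)


def test_empty_or_out_of_range_tables_rejected():
    with pytest.raises(ValueError):
        position_crosslink_frequency(LigandInstanceTable("ACGU", []))
    with pytest.raises(ValueError, match="row 1"):
        LigandInstanceTable("ACGU", [("a", (0,)), ("b", (7,))])


def test_window_extension_admits_flanking_offsets():
    t = LigandInstanceTable("ACGU", [("a", (-1, 2)), ("b", (2,))],
                            window_ext=1)
    f = position_crosslink_frequency(t)
    assert set(f.position) == {-1, 0, 1, 2, 3, 4}
    assert f.loc[f.position == -1, "count"].item() == 1


# --- threshold calling ------------------------------------------------------

@pytest.mark.parametrize("n,f,expected", [
    (25, 0.4, True),    # primary branch
    (12, 0.42, False),  # fails both branches
    (12, 0.58, True),   # fallback branch
    (20, 0.3, True),    # inclusive boundaries
    (9, 0.9, False),    # too few instances for either branch
])
def test_threshold_rule_branches(n, f, expected):
    import pandas as pd
    freqs = pd.DataFrame({"position": [0], "count": [int(round(n * f))],
                          "frequency": [f]})
    out = call_crosslinked_positions(freqs, n, CrosslinkCallConfig())
    assert bool(out["crosslinked"].item()) is expected


def test_calling_is_monotone_in_counts():
    # raising a position's count never flips crosslinked -> non-crosslinked
    for n in (10, 15, 20, 25, 40):
        prev = False
        for count in range(n + 1):
            import pandas as pd
            freqs = pd.DataFrame({"position": [0], "count": [count],
                                  "frequency": [count / n]})
            now = bool(call_crosslinked_positions(freqs, n)["crosslinked"].item())
            assert now >= prev
            prev = now


def test_instance_table_tsv_roundtrip(tmp_path):
    t = _table("UGCAUGU", [[2, 5], [], [5]])
    path = write_instance_table(t, tmp_path / "inst.tsv")
    back = read_instance_table(path)
    assert back.ligand == t.ligand
    assert back.instances == t.instances
    calls = call_sites(back)
    assert "crosslinked" in calls


# --- protein-site mapping ---------------------------------------------------

def _protein_chain(seq, start=1):
    from xlink3d.chem import AMINO_ACIDS_1TO3
    residues = [Residue("A", start + i, AMINO_ACIDS_1TO3[a],
                        atoms=[Atom("CA", "C", [float(i), 0, 0])])
                for i, a in enumerate(seq)]
    return Chain("A", residues)


def test_identical_numbering_maps_directly():
    full = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    chain = _protein_chain(full)
    m = map_protein_site_to_chain(ProteinXLSite("p", 5, "Y"), chain, full)
    assert m.mapped and m.residue.seq_id == 5


def test_truncated_chain_shifts_consistently():
    full = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    chain = _protein_chain(full[9:], start=10)  # N-terminal truncation
    for pos, letter in ((13, "S"), (20, "S"), (30, "I")):
        m = map_protein_site_to_chain(ProteinXLSite("p", pos, letter),
                                      chain, full)
        assert m.mapped
        assert m.residue.seq_id == pos


def _nw_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Plain dynamic-programming global alignment score."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = np.arange(n + 1) * gap
    dp[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + s, dp[i - 1, j] + gap,
                           dp[i, j - 1] + gap)
    return dp[n, m]


def test_mapping_with_engineered_mismatch_matches_nw_oracle():
    full = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    mutated = full[:3] + "W" + full[4:]  # mismatch away from the site
    chain = _protein_chain(mutated)
    m = map_protein_site_to_chain(ProteinXLSite("p", 20, "S"), chain, full)
    assert m.mapped and m.residue.seq_id == 20
    # aligner score equals an independent Needleman-Wunsch
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score, aligner.mismatch_score = 1, -1
    aligner.open_gap_score = aligner.extend_gap_score = -2
    assert aligner.score(full, mutated) == _nw_oracle(full, mutated)


def test_mismatched_site_letter_is_unmapped():
    full = "MKTAYIAKQ"
    chain = _protein_chain(full)
    m = map_protein_site_to_chain(ProteinXLSite("p", 5, "W"), chain, full)
    assert not m.mapped and "site says" in m.reason


# --- redundancy selection ---------------------------------------------------

def test_select_nonredundant_lexicographic():
    c = [CandidateStructure("2xyz", 5, 40), CandidateStructure("1abc", 3, 99)]
    assert select_nonredundant(c).accession == "2xyz"
    c = [CandidateStructure("2xyz", 5, 30), CandidateStructure("1abc", 5, 40)]
    assert select_nonredundant(c).accession == "1abc"
    c = [CandidateStructure("2xyz", 5, 40), CandidateStructure("1abc", 5, 40)]
    assert select_nonredundant(c).accession == "1abc"


def test_select_nonredundant_permutation_invariant():
    import itertools
    cands = [CandidateStructure("3aaa", 5, 40), CandidateStructure("1bbb", 5, 40),
             CandidateStructure("2ccc", 7, 1)]
    picks = {select_nonredundant(list(p)).accession
             for p in itertools.permutations(cands)}
    assert picks == {"2ccc"}


# --- contact split ----------------------------------------------------------

def test_split_by_contact_frequencies_and_undefined():
    sites = []
    for i in range(10):  # 2/10 contacting Phe crosslinked
        sites.append(LabeledSite(("A", i, ""), "amino-acid",
                                 crosslinked=i < 2, contacting=True,
                                 residue_name="F"))
    for i in range(4):   # 1/4 non-contacting Phe
        sites.append(LabeledSite(("A", 100 + i, ""), "amino-acid",
                                 crosslinked=i < 1, contacting=False,
                                 residue_name="F"))
    sites.append(LabeledSite(("A", 200, ""), "amino-acid", True, True, "C"))
    df = split_by_contact(sites).set_index("residue")
    assert df.loc["F", "freq_contacting"] == pytest.approx(0.2)
    assert df.loc["F", "freq_non_contacting"] == pytest.approx(0.25)
    assert df.loc["F", "fold_change"] == pytest.approx(0.8)
    # no non-contacting Cys: undefined, not 0
    assert np.isnan(df.loc["C", "freq_non_contacting"])
    assert np.isnan(df.loc["C", "fold_change"])


def test_split_frequencies_match_recount_oracle():
    rng = np.random.default_rng(9)
    letters = list("FYCRG")
    sites = [LabeledSite(("A", i, ""), "amino-acid",
                         bool(rng.random() < 0.3), bool(rng.random() < 0.5),
                         letters[rng.integers(len(letters))])
             for i in range(200)]
    df = split_by_contact(sites).set_index("residue")
    for letter in letters:
        for grp, flag in (("contacting", True), ("non_contacting", False)):
            members = [s for s in sites
                       if s.residue_name == letter and s.contacting is flag]
            if members:
                expected = sum(s.crosslinked for s in members) / len(members)
                assert df.loc[letter, f"freq_{grp}"] == pytest.approx(expected)
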