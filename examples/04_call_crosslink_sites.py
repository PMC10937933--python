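"""Call crosslinked nucleotides from CLIP instance evidence.

25 transcriptome instances of the ligand UGCAUGU carry crosslink offsets;
a position is crosslinked when >= 20 instances carry evidence and >= 30%
of them are crosslinked there (or >= 10 instances and >= 50%).
"""

from xlink3d import call_sites
from xlink3d.crosslinks import LigandInstanceTable

rows = ([(f"i{k}", (1,)) for k in range(12)]       # G2: 12/25 = 0.48
        + [(f"j{k}", (5,)) for k in range(9)]      # G6:  9/25 = 0.36
        + [(f"k{k}", (3,)) for k in range(4)])     # A4:  4/25 = 0.16
table = LigandInstanceTable("UGCAUGU", rows)
calls = call_sites(table)
print(calls.to_string(index=False))
print()
n_instances = sum(1 for _, offs in table.instances if offs)
for _, row in calls[calls.crosslinked].iterrows():
    base = table.ligand[int(row.position)]
    print(f"position {int(row.position)} ({base}): crosslinked "
          f"(frequency {row.frequency:.2f} over {n_instances} instances)")
# The two guanines pass the frequency rule; the weakly covered adenine
# stays non-crosslinked.
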