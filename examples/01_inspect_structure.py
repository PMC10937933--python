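"""Read a protein-RNA complex and list its chains.

Builds a small synthetic complex (a guanine stacked on a phenylalanine
ring), writes it as PDB, reads it back and classifies each chain.
"""

import tempfile
from pathlib import Path

from xlink3d import classify_chains, read_structure, write_structure
from xlink3d.fixtures import StackFixtureSpec, make_stack_fixture

structure = make_stack_fixture(StackFixtureSpec(base="G", partner="PHE"))
with tempfile.TemporaryDirectory() as tmp:
    path = write_structure(structure, Path(tmp) / "complex.pdb")
    st = read_structure(path)

print(f"structure {st.accession!r}: {len(st.chains)} chains")
for chain_id, polymer_class in classify_chains(st).items():
    n = len(st.chain(chain_id))
    print(f"  chain {chain_id}: {polymer_class}, {n} residue(s)")
# The RNA chain holds the single guanine; the protein chain the single Phe.
# A real run would read a deposited mmCIF/PDB complex instead.
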