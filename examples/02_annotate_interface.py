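"""Extract interface geometry: contacts, hydrogen bonds, stacking.

Two fixtures: a guanine stacked on phenylalanine (3.4 A, parallel), and an
arginine whose guanidinium hydrogen-bonds a guanosine phosphate at 2.9 A --
the two contact types most strongly tied to UV photo-crosslinking.
"""

from xlink3d import annotate
from xlink3d.fixtures import (StackFixtureSpec, make_hbond_fixture,
                              make_stack_fixture)
from xlink3d.geometry import annotation_to_frame

stack = make_stack_fixture(StackFixtureSpec(base="G", partner="PHE",
                                            interplane_angle=0.0,
                                            vertical_sep=3.4,
                                            lateral_offset=0.5))
ann = annotate(stack)
for s in ann.stacks:
    if s.partner_kind != "nucleotide-base":
        print(f"stack: {s.nt.label} on {s.partners[0].label} "
              f"({s.partner_kind}), angle {s.interplane_angle:.1f} deg, "
              f"rise {s.vertical_sep:.2f} A, offset {s.lateral_offset:.2f} A")

hb = make_hbond_fixture("ARG", "NH1", "G", "OP1", 2.9)
for b in annotate(hb).hbonds:
    print(f"H-bond: {b.aa.label} {b.protein_atom} ... {b.rna_atom} "
          f"{b.nt.label} at {b.distance:.2f} A "
          f"({b.rna_moiety} x {b.protein_moiety})")

# annotation_to_frame gives the same records as a tidy table for TSV export
print(annotation_to_frame(ann).head().to_string(index=False))
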