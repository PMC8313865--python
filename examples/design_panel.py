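"""Select hyper-mutable STR loci and assemble duplex-MIP precursors.

Builds a toy locus table, applies the selection rules (AC/AG repeats must
exceed 10 units, A/G mono-repeats 6), designs targeting arms, assembles the
~150 nt precursors and simulates MlyI digestion to the ~105 nt active MIP.
"""

from strlineage.panel import (
    StrLocus,
    design_panel,
    digest_precursor,
    select_hypermutable_loci,
)
from strlineage.simulate import make_panel

toy = [
    StrLocus("ac12", "chrX", 1000, 1024, "AC", 12),
    StrLocus("ac10", "chrX", 2000, 2020, "AC", 10),
    StrLocus("a7", "chrX", 3000, 3007, "A", 7),
    StrLocus("cag20", "chrX", 4000, 4060, "CAG", 20),
]
kept = select_hypermutable_loci(toy)
print("selection rules keep:", [l.locus_id for l in kept])
# -> ac12 (di-repeat > 10 units) and a7 (mono-repeat > 6); ac10 sits on the
#    strict boundary and cag20 is an unsupported unit type.

panel = make_panel(20, flank_length=70, seed=0)
design = design_panel(panel)
print(f"\ndesigned {len(design.precursors)} precursors, "
      f"{len(design.rejected)} loci rejected")
p = design.precursors[0]
print(f"example precursor {p.locus_id}: {len(p.full_sequence)} nt synthesized,"
      f" {len(digest_precursor(p))} nt active after MlyI digestion")
# The precursor carries the two universal adapters (23 nt each); digestion
# removes exactly those, leaving arms + UMIs + backbone (~105 nt for a
# 150 nt precursor).
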