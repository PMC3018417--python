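"""Per-residue display encodings of a structure model.

Computes the blue-to-red mobility gradient from temperature factors and the
grey/red hydrophobic-vs-polar coloring of the implicit sequence.
"""

from phytodesk import (
    coverage_percent,
    hydropathy_coloring,
    implicit_sequence,
    parse_pdb,
    temperature_gradient,
)
from phytodesk.fixtures import make_structure_fixture

fix = make_structure_fixture(seed=2, n_residues=12)
model = parse_pdb(fix.pdb_text, "demo")
seq, residue_map = implicit_sequence(model, "A")

print(f"implicit sequence: {seq.residues}")
print(f"coverage of a 20-residue full-length product: "
      f"{coverage_percent(len(residue_map), 20):.1f}%")

gradient = temperature_gradient(model)
colors = hydropathy_coloring(seq)
for (chain, resnum, value), color, aa in zip(gradient, colors, seq.residues):
    print(f"{chain} {resnum:>3} {aa}  mobility {value:.2f}  hydropathy {color}")
# mobility 0.0 is the least mobile residue (blue end), 1.0 the most mobile
# (red end); grey residues are hydrophobic, red ones polar or charged.
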