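"""Project curated domain sites through a gapped profile hit onto a structure.

Generates a synthetic structure model and a gapped profile alignment with
planted sites, keeps only significant hits (E < 1e-5), projects the sites,
and emits a Jmol selection script for the mapped alpha carbons.
"""

from phytodesk import filter_hits, project_sites, emit_selection_script
from phytodesk import implicit_sequence, parse_pdb
from phytodesk.fixtures import make_alignment_fixture, make_structure_fixture

struct = make_structure_fixture(seed=1, n_residues=80)
fix = make_alignment_fixture(seed=1, master_len=40, n_sites=5, gap_rate=0.1)

significant = filter_hits([fix.hit])  # strict E < 1e-5 cutoff
print(f"{len(significant)} of 1 hits significant (E = {fix.hit.evalue:g})")

projection = project_sites(fix.site, significant[0])
for m in projection.mappings:
    print(f"master position {m.master_position:>3} -> {m.status:>7}"
          + (f" (target {m.target_position})" if m.target_position else ""))
# "mapped" positions landed on a target residue; "gapped" ones sat opposite
# an alignment gap and cannot be shown on the model.

model = parse_pdb(struct.pdb_text, "demo")
_, residue_map = implicit_sequence(model, "A")
print()
print(emit_selection_script(projection, residue_map.to_dict()))
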