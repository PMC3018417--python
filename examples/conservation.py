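"""Per-column conservation scores of a multiple sequence alignment.

Scores drive the letter sizes in aligned-sequence displays: 1.0 means every
sequence agrees at that column, lower values mean divergence.
"""

from phytodesk import conservation_scores, residue_class

msa = [
    "MKV-LITAE",
    "MKVQLITAE",
    "MKVQLLSAE",
    "MRVQLITAD",
]
scores = conservation_scores(msa)
for col, score in enumerate(scores, start=1):
    column = "".join(row[col - 1] for row in msa)
    print(f"column {col}: {column}  conservation {score:.2f}")

print()
for aa in "MKVD":
    print(f"{aa}: {residue_class(aa)}")
# conservation is the modal-residue fraction among non-gap symbols; the
# residue classes drive the physico-chemical coloring of the letters.
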