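"""Ends-free alignment with the full match/mismatch matrix.

Aligns a short fragment against a longer sequence; end gaps are free, so the
fragment simply slides to its best-matching window.
"""

from phytodesk import BioSequence, build_fullmat, ends_free_align

matrix = build_fullmat("nucleotide")
print(f"matrix {matrix.name}: match {matrix.score('A', 'A'):g}, "
      f"mismatch {matrix.score('A', 'G'):g}, "
      f"gap open {matrix.gap_open:g}, gap extend {matrix.gap_extend:g}")

subject = BioSequence("gene", "ATGGCTAAAGCTTTTGGGACT", "nucleotide")
query = BioSequence("fragment", "AAAGCTTTT", "nucleotide")
aln = ends_free_align(query, subject, matrix)

print(aln.query_aligned)
print(aln.midline)
print(aln.subject_aligned)
print(f"score = {aln.score:g}")
# A perfect 9-base window scores 9 x 5 = 45; the flanking subject bases ride
# on free end gaps and cost nothing.
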