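# phytodesk

A desk-scale Python toolkit for the server-side computations behind
integrative plant-biology visualization: projecting curated functional sites
from conserved-domain profiles onto protein structure models, placing
single-nucleotide polymorphisms (SNPs) on coding sequences, and building
3D-laid-out "two-step" protein–protein interaction networks with per-node
metrics. It is aimed at bioinformaticians who want these annotation layers —
normally hidden inside a web service — as plain, testable library calls on
local files.

## What it computes

**Ends-free alignment with the full matrix.** Sequences are aligned with the
ends-free (semi-global) Needleman–Wunsch algorithm under a full substitution
matrix scoring every identity 5 and every substitution −4, with affine gap
penalties ordered `gap open < mismatch < gap extend < match` (defaults −10
and −0.5). Gap runs touching either end of the alignment are free, so a short
fragment slides to its best window in a longer sequence at no end cost.

**Site projection.** A curated site is a set of 1-based positions on a
domain-profile master sequence. Given a profile hit (kept only when its
E-value is strictly below 1e-5), the projector walks the alignment columns
with ungapped counters and carries each master position onto the target
sequence: `mapped` to a target coordinate, `gapped` when it faces an
alignment gap, or `outside` the aligned span. A second alignment
(protein sequence → model implicit sequence, same strict cutoff) composes to
structure coordinates, and mapped residues are emitted as a Jmol selection
script highlighting their alpha carbons.

**SNP placement.** Each polymorphism arrives as a flanking fragment plus the
site offset within it. The fragment is aligned ends-free to the coding
sequence; the site is projected through the alignment and classified
synonymous/non-synonymous by standard-genetic-code codon translation
(`codon = ceil(position/3)`). Placements must clear a score threshold of
`5 × ceil(0.5 × fragment length)`; the reverse complement is tried when the
forward strand fails.

**Two-step networks.** Around a query protein, the subnetwork of all nodes
within graph distance 2, with induced edges. Per node: the Watts–Strogatz
clustering coefficient `C = 2e / (k(k−1))`, Pearson expression correlation
against the query, and a localization label. A seeded 3D Fruchterman–Reingold
layout is exported in XYZ chemical format (query = `N`, first shell = `C`,
second shell = `O`) for any molecular viewer.

**Structure encodings.** A strict fixed-column PDB parser, implicit-sequence
extraction from ATOM records, model coverage percent, a predictor-confidence
filter (keep 100% only), a min–max normalized per-residue temperature-factor
gradient (blue→red mobility), and grey/red hydrophobic-vs-polar coloring.

## Worked example

```sh
python examples/alignment_basics.py
```

```
matrix FULLMAT: match 5, mismatch -4, gap open -10, gap extend -0.5
------AAAGCTTTT------
      |||||||||      
ATGGCTAAAGCTTTTGGGACT
score = 45
```

The 9-base fragment matches its window exactly (9 × 5 = 45) and the
unaligned subject flanks ride on free end gaps. SNP placement on a generated
coding sequence:

```sh
python examples/snp_placement.py
```

```
SNP0000: CDS position 234 codon  78 T->T synonymous
SNP0002: CDS position 268 codon  90 K->E nonsynonymous
...
summary: {'total': 10, 'placed': 10, 'synonymous': 2, 'nonsynonymous': 8, 'unplaced': 0}
```

Each record lands at its true position; `K->E` means the alternate allele
changes the codon's amino acid, while `T->T` is a degenerate (synonymous)
change. The other examples cover site mapping onto a structure, per-residue
coloring, conservation scoring, and the two-step network pipeline.

A thin CLI mirrors the library (`phytodesk map-sites | struct-color |
place-snps | subnet | conserve | make-fixtures`); run `phytodesk --help`.

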