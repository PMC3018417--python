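# Methods

This note records the models and procedures the toolkit implements, the
conventions chosen where the underlying methods are underspecified, and what
the synthetic fixtures do and do not establish.

## Ends-free alignment

The aligner implements semi-global Needleman–Wunsch with affine gap costs
over an explicit substitution matrix. The default matrix ("FULLMAT") scores
every identical symbol pair +5 and every non-identical pair −4, for both
nucleotide and amino-acid alphabets. Gap penalties must satisfy
`gap_open < mismatch < gap_extend < match`; the defaults are −10 (open) and
−0.5 (extend), EMBOSS-style magnitudes. The first column of an internal gap
run costs `gap_open` alone (not `gap_open + gap_extend`); each further
column costs `gap_extend`.

**End-gap convention.** "Ends-free" means gap runs at the alignment ends are
free. We adopt the standard DP formulation: the first row and column of the
matrix are initialized to zero and the optimum is taken over the last row
and column, with free trailing runs appended outside the recursion. A
consequence worth stating explicitly: an alignment may begin with a free run
in one sequence followed immediately by a run in the other, and that *second*
run is charged — only the first and last run of the alignment are end runs.
The brute-force enumeration oracle in the test suite scores alignments under
exactly this convention, and the implementation also agrees with Biopython's
`PairwiseAligner` configured with zero end-gap scores on random pairs.

**Determinism.** Ties are broken by fixed preference — residue pair over
gap-in-subject over gap-in-query, and terminal cells closer to the
bottom-right corner first — so the reported alignment (not just its score)
is reproducible.

The DP is vectorized row-wise with numpy; the gap-in-query state, which
depends on cells to its left within the same row, collapses to a running
prefix maximum because the extend penalty is linear in run length.

## Site projection

Curated sites are 1-based positions on a domain-profile master sequence.
Hits are retained when their E-value is *strictly* below 1e-5. Projection is
a single column walk over the gapped pair with ungapped counters seeded from
the hit's start coordinates — equivalent to counting gaps in the homology
string, but with simpler invariants (the midline carries no coordinate
information). Each master position resolves to exactly one of `mapped`,
`gapped`, or `outside`; `outside` (position not covered by the hit's subject
span) is this toolkit's convention, since partial-coverage behaviour is
otherwise unspecified. Composition with a second alignment
(sequence → model implicit sequence) applies the same walk again; positions
lost at either stage stay lost. When several hits of one profile cover a
target, each yields its own projection — no merging.

Viewer output uses a fixed Jmol-dialect grammar (one comment line, one
`select (res:chain, ...) and *.CA;` statement and one `color` command per
site) so script comparisons are byte-exact.

## Structure handling

PDB ATOM/HETATM records are parsed from their fixed columns with strict
diagnostics: a malformed field raises an error naming the line. The implicit
sequence is read from ATOM records (not SEQRES): the mapping targets
residues that exist in the model, and missing density simply shortens the
sequence. Residues without a standard three-letter code (including modified
residues such as MSE) become `X`. Predictor confidence is carried as sidecar
metadata (TSV), since it is not a PDB field; the significance filter keeps
models at exactly 100% confidence. Coverage is `100 × modeled residues /
full-length residues`.

The mobility gradient uses the mean temperature factor over each residue's
atoms by default (alpha-carbon-only is a flag; which the original display
used is unrecorded), min–max normalized per model so 0 is the least and 1
the most mobile residue; constant-B models map everywhere to 0.5, and the
encoding is invariant under affine transformations of the B-field.
Hydropathy coloring is grey for hydrophobic residues and red otherwise.

## Residue classes and conservation

The 20 standard residues partition into hydrophobic {A,V,L,I,M,F,W,C,P,G},
polar {S,T,N,Q,Y,H}, positive {K,R} and negative {D,E}; histidine is grouped
as polar, matching a grey/red hydrophobic-vs-polar display dichotomy; `X` is
"special" and displays as grey.

Column conservation of an MSA is the modal-residue fraction among non-gap
symbols (all-gap columns score 0). The original letter-scaling metric is
undocumented; identity-based scoring is the default here because it is
parameter-free, and a normalized-entropy variant (`1 − H/log2(n_rows)`) is
available behind a flag.

## SNP placement

Fragments are aligned ends-free to the CDS (fragment as query), the site
offset is projected through the columns, and the landed position is
classified via the standard genetic code (`codon_index = ceil(pos/3)`;
codons containing `N` translate to `X`; no ambiguity resolution). Design
choices:

- **Acceptance threshold** `score ≥ match × ceil(0.5 × fragment_length)` —
  no published threshold exists; this rejects random placements (a random
  25-mer scores far below half-perfect) while tolerating a few flank
  mismatches. Configurable.
- **Strand**: forward first, then the reverse complement, reporting strand.
- A placement is also rejected when the aligned CDS base at the site
  disagrees with the declared reference allele (`site-mismatch`), when the
  site faces a gap (`gapped`) or falls outside the aligned span (`outside`).
- Only single-base substitutions are modelled.

## Networks

The two-step model is the induced subgraph on all nodes within graph
distance 2 of the query (edges among second-shell nodes are part of the
model; hiding them is a rendering concern). A query absent from the
interactome yields a single-node network. Clustering is the Watts–Strogatz
local coefficient `2e/(k(k−1))` with `C = 0` for degree < 2. Expression
correlation is plain Pearson; zero-variance profiles report *absent*, not 0.

The 3D layout is seeded Fruchterman–Reingold (networkx `spring_layout`,
`dim=3`, 200 iterations, uniform initial placement), chosen as a documented,
deterministic replacement for the proprietary layout kernel the original
service used; outputs are byte-identical for a fixed (graph, seed). XYZ
export writes the count line, a comment carrying query id and seed, then one
`SYMBOL x y z` line per node at 3 decimals, nodes in sorted order, symbols
by BFS shell (query `N`, shell 1 `C`, shell 2 `O` — arbitrary but fixed).
Render tables map the chosen metric affinely into `[r_min, r_max]`
(degenerate metric → midpoint) and color by a fixed palette over sorted
localization labels.

Duplicate undirected edges keep the maximum confidence; self-loops are
dropped; both are logged.

## Synthetic fixtures

The fixture module generates every input format with a truth ledger, each
generator drawing from a stream derived from the master seed by a fixed
label (so generators never perturb one another). Structure fixtures are
ideal-helix CA walks with uniform B-factors; alignment fixtures plant gap
columns at a chosen rate and record each site's true status from the
construction walk; SNP fixtures cut ±12-base windows from a random 300-base
CDS (defaults), with synonymy verdicts planted via Biopython translation —
a route independent of the package's own classifier; network fixtures are
Erdős–Rényi graphs (default 30 nodes, edge probability 0.1) with planted
triangles and one expression profile orthogonalized to correlate with the
query's at exactly 0.9.

These fixtures exercise coordinate bookkeeping, gap handling, thresholds and
determinism. They are *not* statistically realistic: real B-factor fields,
interactome degree distributions and expression covariance are far more
structured, and real SNP fragments carry sequencing artifacts beyond single
flank mismatches. Passing the suite therefore demonstrates algorithmic
correctness on well-posed inputs, not robustness to the full messiness of
production data.

Problem sizes in the test and acceptance runs (exhaustive enumeration over
all sequence pairs up to length 5 on a binary alphabet, 200 projection
fixtures, 50 graphs of ≤ 30 nodes) are chosen so exhaustive oracles stay
exact while the whole suite completes in seconds.

## Known limitations

- The aligner is O(mn) with full traceback matrices; it is meant for
  fragments and single genes, not chromosome-scale alignment.
- Multi-hit site projections are reported independently; no consensus call.
- The XYZ layout is comparable to, but not the same embedding as, the
  original service's proprietary layout.
- Translation handles the standard genetic code only.
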