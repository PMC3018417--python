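"""Sequences, substitution matrices, and the ends-free dynamic-programming aligner.

This module holds the sequence-level primitives everything else builds on:

* :class:`BioSequence` — a plain ungapped nucleotide or amino-acid sequence.
* :class:`SubstitutionMatrix` and :func:`build_fullmat` — the full match/mismatch
  matrix (match 5, mismatch −4) with affine gap penalties satisfying
  ``gap_open < mismatch < gap_extend < match``.
* :func:`ends_free_align` — semi-global Needleman–Wunsch: a global alignment in
  which gap runs touching either end of the alignment cost nothing.
* :func:`translate` / :func:`classify_substitution` — standard-genetic-code
  translation and synonymous/non-synonymous calls for single-base changes.
* :func:`conservation_scores` — per-column conservation of a gapped MSA.
* :func:`residue_class` — coarse physico-chemical classes of the 20 residues.

Coordinates are 1-based inclusive at every public interface; 0-based half-open
offsets are used internally.
"""

from __future__ import annotations

import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable as _CodonTable
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

_NT_SYMBOLS = set("ACGTN")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SYMBOLS = set(_AA20) | {"X", "*"}

Alphabet = Literal["nucleotide", "amino-acid"]


class AlphabetError(ValueError):
    """A sequence or matrix was used with the wrong alphabet."""


# ---------------------------------------------------------------------------
# BioSequence


@dataclass(frozen=True)
class BioSequence:
    """An ungapped sequence with a declared alphabet.

    Gap characters are never stored here; gapped strings only appear inside
    :class:`PairwiseAlignment` and MSA inputs.
    """

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if self.alphabet == NUCLEOTIDE:
            allowed = _NT_SYMBOLS
        elif self.alphabet == AMINO_ACID:
            allowed = _AA_SYMBOLS
        else:
            raise AlphabetError(f"unknown alphabet: {self.alphabet!r}")
        bad = set(residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside 1..{len(self.residues)}"
            )
        return self.residues[position - 1]

    def reverse_complement(self) -> "BioSequence":
        if self.alphabet != NUCLEOTIDE:
            raise AlphabetError("reverse_complement needs a nucleotide sequence")
        comp = str(Seq(self.residues).reverse_complement())
        return BioSequence(self.id, comp, NUCLEOTIDE)


# ---------------------------------------------------------------------------
# Substitution matrices


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric pair scores plus affine gap penalties.

    ``gap_open`` is charged for the first column of an internal gap run and
    ``gap_extend`` for each subsequent column (the opening column does *not*
    additionally pay ``gap_extend``).
    """

    name: str
    alphabet: Alphabet
    scores: dict[tuple[str, str], float]
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if self.scores.get((b, a)) != s:
                raise ValueError(f"matrix {self.name!r} asymmetric at ({a},{b})")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(
                f"symbol pair ({a},{b}) not scored by matrix {self.name!r}"
            ) from None

    @property
    def symbols(self) -> list[str]:
        return sorted({a for a, _ in self.scores})

    def to_text(self) -> str:
        """Serialize in an EMBOSS-like whitespace grid with comment header."""
        syms = self.symbols
        lines = [
            f"# Matrix: {self.name}",
            f"# Alphabet: {self.alphabet}",
            f"# Gap open: {self.gap_open:g}",
            f"# Gap extend: {self.gap_extend:g}",
            "  " + "  ".join(syms),
        ]
        for a in syms:
            row = "  ".join(f"{self.scores[(a, b)]:g}" for b in syms)
            lines.append(f"{a} {row}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SubstitutionMatrix":
        name, alphabet = "matrix", AMINO_ACID
        gap_open, gap_extend = -10.0, -0.5
        rows: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("Matrix:"):
                    name = body.split(":", 1)[1].strip()
                elif body.startswith("Alphabet:"):
                    alphabet = body.split(":", 1)[1].strip()  # type: ignore[assignment]
                elif body.startswith("Gap open:"):
                    gap_open = float(body.split(":", 1)[1])
                elif body.startswith("Gap extend:"):
                    gap_extend = float(body.split(":", 1)[1])
            else:
                rows.append(line)
        header = rows[0].split()
        scores: dict[tuple[str, str], float] = {}
        for row in rows[1:]:
            parts = row.split()
            a = parts[0]
            for b, val in zip(header, parts[1:]):
                scores[(a, b)] = float(val)
        return cls(name, alphabet, scores, gap_open, gap_extend)


FULLMAT_MATCH = 5.0
FULLMAT_MISMATCH = -4.0
FULLMAT_GAP_OPEN = -10.0
FULLMAT_GAP_EXTEND = -0.5


def build_fullmat(
    alphabet: Alphabet,
    gap_open: float = FULLMAT_GAP_OPEN,
    gap_extend: float = FULLMAT_GAP_EXTEND,
) -> SubstitutionMatrix:
    """The full match/mismatch matrix: identical symbols score 5, others −4.

    The default gap penalties (−10 open, −0.5 extend) are EMBOSS-style
    magnitudes chosen to satisfy the defining inequality
    ``gap_open < mismatch < gap_extend < match``; both are configurable as
    long as the inequality holds.
    """
    if alphabet == NUCLEOTIDE:
        syms = sorted(_NT_SYMBOLS)
    elif alphabet == AMINO_ACID:
        syms = sorted(_AA_SYMBOLS - {"*"})
    else:
        raise AlphabetError(f"unknown alphabet: {alphabet!r}")
    if not gap_open < FULLMAT_MISMATCH < gap_extend < FULLMAT_MATCH:
        raise ValueError(
            "FULLMAT gap penalties must satisfy gap_open < mismatch "
            f"< gap_extend < match; got open={gap_open}, extend={gap_extend}"
        )
    scores = {
        (a, b): FULLMAT_MATCH if a == b else FULLMAT_MISMATCH
        for a in syms
        for b in syms
    }
    return SubstitutionMatrix("FULLMAT", alphabet, scores, gap_open, gap_extend)


# ---------------------------------------------------------------------------
# Pairwise alignments


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment with 1-based inclusive span coordinates.

    ``query_aligned`` and ``subject_aligned`` are equal-length strings over the
    sequence alphabet plus ``-``; no column is gap-vs-gap.  The ungapped
    content of each string equals the corresponding sequence slice
    ``[start..end]`` (1-based inclusive).  ``midline`` is the homology string
    (``|`` on identities); it carries no extra coordinate information and may
    be absent.
    """

    query_aligned: str
    subject_aligned: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: float | None = None
    evalue: float | None = None
    midline: str | None = None

    def __post_init__(self) -> None:
        if self.midline is None:
            self.midline = "".join(
                "|" if (q == s and q != GAP) else " "
                for q, s in zip(self.query_aligned, self.subject_aligned)
            )

    def validate(self) -> None:
        q, s = self.query_aligned, self.subject_aligned
        if len(q) != len(s):
            raise ValueError("aligned strings differ in length")
        if any(a == GAP and b == GAP for a, b in zip(q, s)):
            raise ValueError("gap-vs-gap column in alignment")
        n_q = sum(1 for c in q if c != GAP)
        n_s = sum(1 for c in s if c != GAP)
        if self.query_end - self.query_start + 1 != n_q:
            raise ValueError(
                "query span does not match non-gap character count"
            )
        if self.subject_end - self.subject_start + 1 != n_s:
            raise ValueError(
                "subject span does not match non-gap character count"
            )

    def columns(self) -> Iterator[tuple[str, str, int | None, int | None]]:
        """Yield ``(query_char, subject_char, query_pos, subject_pos)`` per column.

        Positions are 1-based on the ungapped sequences; ``None`` on a gap.
        """
        qpos = self.query_start - 1
        spos = self.subject_start - 1
        for qc, sc in zip(self.query_aligned, self.subject_aligned):
            qp = sp = None
            if qc != GAP:
                qpos += 1
                qp = qpos
            if sc != GAP:
                spos += 1
                sp = spos
            yield qc, sc, qp, sp

    def map_position(
        self, position: int, source: Literal["query", "subject"] = "subject"
    ) -> tuple[str, int | None]:
        """Project one 1-based position through the alignment.

        Returns ``(status, mapped_position)`` where status is ``"mapped"``
        (the column pairs two residues), ``"gapped"`` (the position sits
        opposite a gap) or ``"outside"`` (the position is not covered by the
        aligned span); the mapped position is ``None`` unless mapped.
        """
        if source == "subject":
            lo, hi = self.subject_start, self.subject_end
        else:
            lo, hi = self.query_start, self.query_end
        if not lo <= position <= hi:
            return "outside", None
        for qc, sc, qp, sp in self.columns():
            src, dst = (sp, qp) if source == "subject" else (qp, sp)
            if src == position:
                if dst is None:
                    return "gapped", None
                return "mapped", dst
        return "outside", None  # pragma: no cover - span check precludes this


def _validate_for_matrix(seq: BioSequence, matrix: SubstitutionMatrix) -> None:
    if seq.alphabet != matrix.alphabet:
        raise AlphabetError(
            f"sequence {seq.id!r} is {seq.alphabet}, matrix {matrix.name!r} "
            f"is {matrix.alphabet}"
        )


def ends_free_align(
    query: BioSequence, subject: BioSequence, matrix: SubstitutionMatrix
) -> PairwiseAlignment:
    """Optimal ends-free (semi-global) alignment with affine gap costs.

    Gap runs touching either end of the alignment are free; every internal
    run costs ``gap_open`` for its first column plus ``gap_extend`` per
    additional column.  Only the first and the last run of the alignment are
    treated as end runs: an alignment that skips a subject prefix *and then* a
    query prefix pays for the second run.

    Ties are broken deterministically: the aligner prefers a residue pair
    (diagonal move) over a gap in the subject over a gap in the query, and
    prefers terminal cells closer to the bottom-right corner of the DP grid.
    """
    _validate_for_matrix(query, matrix)
    _validate_for_matrix(subject, matrix)
    if not matrix.scores:
        raise ValueError("empty substitution matrix")
    q, s = query.residues, subject.residues
    m, n = len(q), len(s)
    if m == 0 or n == 0:
        # one side empty: the other rides entirely on free end gaps
        aln = PairwiseAlignment(
            query_aligned=q if n == 0 else GAP * n,
            subject_aligned=s if m == 0 else GAP * m,
            query_start=1,
            query_end=m,
            subject_start=1,
            subject_end=n,
            score=0.0,
        )
        aln.validate()
        return aln

    go, ge = matrix.gap_open, matrix.gap_extend
    NEG = -math.inf

    sub = np.empty((m, n))
    for i, qc in enumerate(q):
        for j, sc in enumerate(s):
            sub[i, j] = matrix.score(qc, sc)

    # State M: q[i] paired with s[j]; X: q[i] over a gap (gap in the subject
    # string); Y: gap in the query string under s[j].  Row/column 0 of X / Y
    # hold the free leading runs.
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0
    Y[0, 1:] = 0.0

    for i in range(1, m + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        M[i, 1:] = sub[i - 1] + np.maximum.reduce(
            [prevM[:-1], prevX[:-1], prevY[:-1]]
        )
        X[i, 1:] = np.maximum(
            np.maximum(prevM[1:], prevY[1:]) + go, prevX[1:] + ge
        )
        # Y depends on the current row to its left; with a constant extend
        # penalty the recurrence collapses to a running prefix maximum.
        base = np.maximum(M[i], X[i]) + go - ge
        run = np.maximum.accumulate(base[:-1] + ge * -np.arange(n))
        Y[i, 1:] = run + ge * np.arange(1, n + 1)

    # Terminal cell: free trailing run appended outside the DP.  Scan order
    # fixes the tie-break (corner first, then last row right-to-left, then
    # last column bottom-to-top).
    candidates: list[tuple[int, int]] = [(m, n)]
    candidates += [(m, j) for j in range(n - 1, -1, -1)]
    candidates += [(i, n) for i in range(m - 1, -1, -1)]
    best = NEG
    best_cell = (m, n)
    best_state = "M"
    for (i, j) in candidates:
        for state, table in (("M", M), ("X", X), ("Y", Y)):
            v = table[i, j]
            if v > best:
                best, best_cell, best_state = v, (i, j), state

    # Traceback.
    cols_q: list[str] = []
    cols_s: list[str] = []
    i, j = best_cell
    # free trailing run
    if j < n:
        cols_q.extend(GAP * (n - j))
        cols_s.extend(s[j:][::-1])
    elif i < m:
        cols_q.extend(q[i:][::-1])
        cols_s.extend(GAP * (m - i))
    state = best_state
    eps = 1e-9
    while True:
        if state == "M":
            if i == 0 and j == 0:
                break
            cols_q.append(q[i - 1])
            cols_s.append(s[j - 1])
            v = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            # diagonal preference: M, then X, then Y
            if abs(M[i, j] - v) < eps:
                state = "M"
            elif abs(X[i, j] - v) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if j == 0:
                # free leading run in the subject string
                cols_q.extend(q[:i][::-1])
                cols_s.extend(GAP * i)
                i = 0
                break
            cols_q.append(q[i - 1])
            cols_s.append(GAP)
            v = X[i, j]
            i -= 1
            if abs(M[i, j] + go - v) < eps:
                state = "M"
            elif abs(X[i, j] + ge - v) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            if i == 0:
                # free leading run in the query string
                cols_q.extend(GAP * j)
                cols_s.extend(s[:j][::-1])
                j = 0
                break
            cols_q.append(GAP)
            cols_s.append(s[j - 1])
            v = Y[i, j]
            j -= 1
            if abs(M[i, j] + go - v) < eps:
                state = "M"
            elif abs(Y[i, j] + ge - v) < eps:
                state = "Y"
            else:
                state = "X"

    aln = PairwiseAlignment(
        query_aligned="".join(reversed(cols_q)),
        subject_aligned="".join(reversed(cols_s)),
        query_start=1,
        query_end=m,
        subject_start=1,
        subject_end=n,
        score=float(best),
    )
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# Genetic code


def _standard_codon_table() -> dict[str, str]:
    table = _CodonTable.unambiguous_dna_by_id[1]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    assert len(codons) == 64
    return codons


CODON_TABLE: dict[str, str] = _standard_codon_table()
"""The standard genetic code: 64 codons to one-letter amino acids, stop = ``*``."""


def translate(cds: BioSequence) -> BioSequence:
    """Translate a coding sequence under the standard genetic code.

    The length must be a multiple of 3; a codon containing ``N`` translates
    to ``X`` (no ambiguity resolution is attempted).
    """
    if cds.alphabet != NUCLEOTIDE:
        raise AlphabetError("translate needs a nucleotide sequence")
    if len(cds) % 3 != 0:
        raise ValueError(
            f"CDS {cds.id!r} length {len(cds)} is not a multiple of 3"
        )
    residues = cds.residues
    aa = []
    for k in range(0, len(residues), 3):
        codon = residues[k : k + 3]
        aa.append("X" if "N" in codon else CODON_TABLE[codon])
    return BioSequence(f"{cds.id}_translated", "".join(aa), AMINO_ACID)


@dataclass(frozen=True)
class SubstitutionCall:
    """Verdict for a single-base change in a coding sequence."""

    verdict: Literal["synonymous", "nonsynonymous"]
    ref_aa: str
    alt_aa: str
    codon_index: int  # 1-based codon number


def classify_substitution(
    cds: BioSequence, position: int, alt_base: str
) -> SubstitutionCall:
    """Classify a single-nucleotide substitution as synonymous or not.

    ``position`` is 1-based on the CDS; ``alt_base`` must differ from the
    reference base there.  The codon index is ``ceil(position / 3)``.
    """
    if cds.alphabet != NUCLEOTIDE:
        raise AlphabetError("classify_substitution needs a nucleotide CDS")
    if not 1 <= position <= len(cds):
        raise ValueError(f"position {position} outside CDS 1..{len(cds)}")
    alt_base = alt_base.upper()
    ref_base = cds[position]
    if alt_base == ref_base:
        raise ValueError(
            f"alternate base {alt_base} equals the reference at {position}"
        )
    if alt_base not in _NT_SYMBOLS:
        raise ValueError(f"invalid alternate base {alt_base!r}")
    codon_index = math.ceil(position / 3)
    start = (codon_index - 1) * 3
    codon = cds.residues[start : start + 3]
    if len(codon) < 3:
        raise ValueError(
            f"position {position} falls in a trailing partial codon"
        )
    offset = position - 1 - start
    alt_codon = codon[:offset] + alt_base + codon[offset + 1 :]
    ref_aa = "X" if "N" in codon else CODON_TABLE[codon]
    alt_aa = "X" if "N" in alt_codon else CODON_TABLE[alt_codon]
    verdict = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    return SubstitutionCall(verdict, ref_aa, alt_aa, codon_index)


# ---------------------------------------------------------------------------
# MSA conservation


def conservation_scores(
    msa: Sequence[str], method: Literal["identity", "entropy"] = "identity"
) -> list[float]:
    """Per-column conservation scores in [0, 1] for an aligned set of rows.

    With the default ``identity`` method a column scores the fraction of its
    non-gap symbols equal to the modal non-gap symbol (used to scale letter
    sizes in sequence displays).  The ``entropy`` alternative returns
    ``1 − H/H_max`` with Shannon entropy over non-gap symbols and ``H_max``
    the log of the observed row count.  All-gap columns score 0 either way.
    """
    if len(msa) < 2:
        raise ValueError("an MSA needs at least 2 sequences")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged MSA: aligned rows differ in length")
    scores = []
    for col in range(width):
        symbols = [row[col].upper() for row in msa if row[col] != GAP]
        if not symbols:
            scores.append(0.0)
            continue
        counts = Counter(symbols)
        if method == "identity":
            scores.append(max(counts.values()) / len(symbols))
        elif method == "entropy":
            total = len(symbols)
            h = -sum(
                (c / total) * math.log2(c / total) for c in counts.values()
            )
            hmax = math.log2(len(msa))
            scores.append(1.0 if hmax == 0 else max(0.0, 1.0 - h / hmax))
        else:
            raise ValueError(f"unknown conservation method {method!r}")
    return scores


# ---------------------------------------------------------------------------
# Physico-chemical residue classes

HYDROPHOBIC = frozenset("AVLIMFWCPG")
POLAR = frozenset("STNQYH")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

RESIDUE_CLASSES = (
    "hydrophobic",
    "polar",
    "positively-charged",
    "negatively-charged",
    "special",
)


def residue_class(aa: str) -> str:
    """Coarse physico-chemical class of one amino acid.

    Partition of the 20 standard residues: hydrophobic {A,V,L,I,M,F,W,C,P,G},
    polar {S,T,N,Q,Y,H}, positively charged {K,R}, negatively charged {D,E};
    ``X`` is "special".  Histidine is grouped with the polar residues.
    """
    aa = aa.upper()
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in POLAR:
        return "polar"
    if aa in POSITIVE:
        return "positively-charged"
    if aa in NEGATIVE:
        return "negatively-charged"
    if aa == "X":
        return "special"
    raise ValueError(f"unknown amino-acid symbol {aa!r}")


# ---------------------------------------------------------------------------
# FASTA I/O

THREE_TO_ONE = {
    three.upper(): one for one, three in protein_letters_1to3.items()
}


def read_fasta(
    handle, alphabet: Alphabet, gapped: bool = False
) -> list[BioSequence] | list[tuple[str, str]]:
    """Read FASTA records.

    With ``gapped=False`` returns :class:`BioSequence` objects (gaps are an
    error).  With ``gapped=True`` returns ``(id, aligned_string)`` tuples so
    aligned FASTA (MSA) files can be loaded without losing gap columns.
    """
    if isinstance(handle, str) and "\n" not in handle:
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        text = handle if isinstance(handle, str) else handle.read()
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if gapped:
        return [(r.id, str(r.seq).upper()) for r in records]
    return [BioSequence(r.id, str(r.seq), alphabet) for r in records]


def write_fasta(sequences: Sequence[BioSequence], handle) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, handle, "fasta")
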