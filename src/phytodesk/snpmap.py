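"""Placing single-nucleotide polymorphisms on a coding sequence.

SNP catalogs report each polymorphism as a short sequence fragment flanking
and including the variable site, not as a genome coordinate.  To display a
SNP on a gene, the fragment is aligned to the query gene's coding sequence
with the ends-free Needleman–Wunsch algorithm under the FULLMAT matrix
(match 5 / mismatch −4), the fragment's site offset is carried through the
alignment columns, and the landed CDS position is classified as synonymous or
non-synonymous by codon translation.

A placement is accepted only when the alignment score clears
``match × ceil(min_score_frac × fragment_length)`` (default frac 0.5) — a
guard against random placements that still tolerates a few flank mismatches.
If the forward strand fails, the reverse complement is tried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .seqcore import (
    FULLMAT_MATCH,
    NUCLEOTIDE,
    BioSequence,
    SubstitutionMatrix,
    build_fullmat,
    classify_substitution,
    ends_free_align,
)

DEFAULT_MIN_SCORE_FRAC = 0.5


@dataclass(frozen=True)
class PolymorphismRecord:
    """One SNP: a flanking fragment, the site inside it, and the two alleles."""

    snp_id: str
    fragment: BioSequence
    site_offset: int  # 1-based within the fragment
    ref_allele: str
    alt_allele: str
    ecotypes: tuple[tuple[str, str], ...] = ()
    frequency: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.site_offset <= len(self.fragment):
            raise ValueError(
                f"SNP {self.snp_id!r}: site offset {self.site_offset} outside "
                f"fragment 1..{len(self.fragment)}"
            )
        if self.fragment[self.site_offset] != self.ref_allele.upper():
            raise ValueError(
                f"SNP {self.snp_id!r}: fragment base at offset "
                f"{self.site_offset} is {self.fragment[self.site_offset]}, "
                f"not the declared reference {self.ref_allele}"
            )
        if self.ref_allele.upper() == self.alt_allele.upper():
            raise ValueError(f"SNP {self.snp_id!r}: ref equals alt allele")
        if self.frequency is not None and not 0 <= self.frequency <= 1:
            raise ValueError(f"SNP {self.snp_id!r}: frequency outside [0,1]")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        object.__setattr__(self, "ecotypes", tuple(self.ecotypes))


@dataclass(frozen=True)
class SnpPlacement:
    """A SNP located (or not) on the CDS, with its synonymy verdict."""

    snp_id: str
    verdict: str  # synonymous | nonsynonymous | unplaced
    cds_position: int | None = None
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    alignment_score: float | None = None
    strand: str = "+"
    reason: str = ""

    @property
    def placed(self) -> bool:
        return self.cds_position is not None


def min_acceptance_score(
    fragment_length: int, min_score_frac: float = DEFAULT_MIN_SCORE_FRAC
) -> float:
    """Lowest alignment score accepted for a fragment of the given length."""
    return FULLMAT_MATCH * math.ceil(min_score_frac * fragment_length)


def place_snp(
    cds: BioSequence,
    record: PolymorphismRecord,
    matrix: SubstitutionMatrix | None = None,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    try_reverse: bool = True,
) -> SnpPlacement:
    """Align one SNP fragment to the CDS and classify the polymorphism.

    The fragment is the alignment query, the CDS the subject.  The site
    offset is projected through the alignment columns; if it pairs with a CDS
    base and the score clears the acceptance threshold, the substitution is
    classified by codon translation.  Otherwise the record is returned
    unplaced with a reason (``low-score``, ``gapped`` or ``outside``).
    """
    if matrix is None:
        matrix = build_fullmat(NUCLEOTIDE)
    threshold = min_acceptance_score(len(record.fragment), min_score_frac)

    attempts: list[tuple[str, BioSequence, int, str, str]] = [
        ("+", record.fragment, record.site_offset, record.ref_allele,
         record.alt_allele)
    ]
    if try_reverse:
        rc = record.fragment.reverse_complement()
        rc_offset = len(record.fragment) - record.site_offset + 1
        comp = dict(zip("ACGTN", "TGCAN"))
        attempts.append(
            ("-", rc, rc_offset, comp[record.ref_allele],
             comp[record.alt_allele])
        )

    best_failure = SnpPlacement(
        record.snp_id, "unplaced", alignment_score=None, reason="low-score"
    )
    best_score = -math.inf
    for strand, frag, offset, ref, alt in attempts:
        aln = ends_free_align(frag, cds, matrix)
        if aln.score < threshold:
            if aln.score > best_score:
                best_score = aln.score
                best_failure = SnpPlacement(
                    record.snp_id,
                    "unplaced",
                    alignment_score=aln.score,
                    strand=strand,
                    reason="low-score",
                )
            continue
        status, cds_pos = aln.map_position(offset, source="query")
        if status != "mapped":
            if aln.score > best_score:
                best_score = aln.score
                best_failure = SnpPlacement(
                    record.snp_id,
                    "unplaced",
                    alignment_score=aln.score,
                    strand=strand,
                    reason=status,
                )
            continue
        # the CDS base should be the reference allele; alignment mismatch at
        # the site itself means the fragment landed somewhere it disagrees
        if cds[cds_pos] != ref:
            if aln.score > best_score:
                best_score = aln.score
                best_failure = SnpPlacement(
                    record.snp_id,
                    "unplaced",
                    alignment_score=aln.score,
                    strand=strand,
                    reason="site-mismatch",
                )
            continue
        call = classify_substitution(cds, cds_pos, alt)
        return SnpPlacement(
            snp_id=record.snp_id,
            verdict=call.verdict,
            cds_position=cds_pos,
            codon_index=call.codon_index,
            ref_aa=call.ref_aa,
            alt_aa=call.alt_aa,
            alignment_score=aln.score,
            strand=strand,
        )
    return best_failure


def batch_place(
    cds: BioSequence,
    records: Sequence[PolymorphismRecord],
    matrix: SubstitutionMatrix | None = None,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
) -> tuple[list[SnpPlacement], dict[str, int]]:
    """Place every record (input order preserved) and tally verdicts."""
    if matrix is None:
        matrix = build_fullmat(NUCLEOTIDE)
    placements = [
        place_snp(cds, r, matrix, min_score_frac) for r in records
    ]
    summary = {
        "total": len(placements),
        "placed": sum(1 for p in placements if p.placed),
        "synonymous": sum(1 for p in placements if p.verdict == "synonymous"),
        "nonsynonymous": sum(
            1 for p in placements if p.verdict == "nonsynonymous"
        ),
        "unplaced": sum(1 for p in placements if not p.placed),
    }
    return placements, summary


# ---------------------------------------------------------------------------
# Tabular I/O

SNP_COLUMNS = [
    "snp_id",
    "fragment_seq",
    "site_offset",
    "ref",
    "alt",
    "ecotypes",
    "frequency",
]


def read_snps_tsv(path_or_buffer) -> list[PolymorphismRecord]:
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"snp_id": str})
    missing = {"snp_id", "fragment_seq", "site_offset", "ref", "alt"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        ecotypes: tuple[tuple[str, str], ...] = ()
        raw = getattr(row, "ecotypes", None)
        if isinstance(raw, str) and raw:
            ecotypes = tuple(
                tuple(part.split(":", 1)) for part in raw.split(";") if part
            )
        freq = getattr(row, "frequency", None)
        freq = None if freq is None or pd.isna(freq) else float(freq)
        records.append(
            PolymorphismRecord(
                snp_id=row.snp_id,
                fragment=BioSequence(
                    f"{row.snp_id}_fragment", row.fragment_seq, NUCLEOTIDE
                ),
                site_offset=int(row.site_offset),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                ecotypes=ecotypes,
                frequency=freq,
            )
        )
    return records


def write_snps_tsv(records: Sequence[PolymorphismRecord], path_or_buffer) -> None:
    rows = [
        {
            "snp_id": r.snp_id,
            "fragment_seq": r.fragment.residues,
            "site_offset": r.site_offset,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "ecotypes": ";".join(f"{e}:{a}" for e, a in r.ecotypes),
            "frequency": "" if r.frequency is None else r.frequency,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SNP_COLUMNS).to_csv(
        path_or_buffer, sep="\t", index=False
    )


def placements_table(placements: Sequence[SnpPlacement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": p.snp_id,
                "verdict": p.verdict,
                "cds_position": p.cds_position,
                "codon_index": p.codon_index,
                "ref_aa": p.ref_aa,
                "alt_aa": p.alt_aa,
                "strand": p.strand,
                "alignment_score": p.alignment_score,
                "reason": p.reason,
            }
            for p in placements
        ],
        columns=[
            "snp_id",
            "verdict",
            "cds_position",
            "codon_index",
            "ref_aa",
            "alt_aa",
            "strand",
            "alignment_score",
            "reason",
        ],
    )
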