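"""Deterministic generators for every input the toolkit consumes.

Each generator is a pure function of a master seed plus its parameters, and
returns both the artifact (PDB text, TSV text, domain objects) and a *truth
ledger* recording the planted facts — true site statuses, true SNP positions
and synonymy, planted triangles and correlations — so downstream operations
can be checked against ground truth without any external data.

Every generator draws from its own pseudorandom stream, derived from the
master seed by a fixed per-generator label, so adding a generator never
perturbs the output of existing ones.  These fixtures aim at exercising the
algorithms, not at statistical realism: B-factors are uniform, interactomes
are Erdős–Rényi, expression profiles are Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from Bio.Seq import Seq

from .seqcore import AMINO_ACID, GAP, NUCLEOTIDE, BioSequence, PairwiseAlignment, _AA20
from .sitemap import AlignmentHit, CuratedSite
from .snpmap import PolymorphismRecord
from .netview import write_edges

# per-generator stream labels: adding one must never renumber the others
_STREAM_STRUCTURE = 1
_STREAM_ALIGNMENT = 2
_STREAM_SNP = 3
_STREAM_NETWORK = 4

_NT = "ACGT"
_ECOTYPES = ("Col-0", "Ler-1", "Ws-2", "Cvi-0", "Kas-1")


def _rng(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng([label, seed])


def write_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Structure fixture

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_BACKBONE_OFFSETS = {
    "N": (-1.20, 0.30, -0.50),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.25, 0.20, 0.45),
    "O": (1.60, 1.30, 0.80),
}


@dataclass
class StructureFixture:
    pdb_text: str
    sequence: str
    residue_numbers: list[int]
    ledger: dict


def make_structure_fixture(seed: int, n_residues: int) -> StructureFixture:
    """A synthetic single-chain helix-walk model with random B-factors.

    Alpha-carbon positions follow an ideal alpha-helix trace (rise 1.5 Å,
    100° per residue, radius 2.3 Å) with N/C/O placed at fixed offsets;
    B-factors are uniform on [5, 50] rounded to 2 decimals.  The ledger
    records the planted sequence, atom count and B-factor list.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = _rng(seed, _STREAM_STRUCTURE)
    sequence = "".join(rng.choice(list(_AA20), size=n_residues))
    lines = []
    serial = 0
    bfactors = []
    for i in range(n_residues):
        angle = np.deg2rad(100.0 * i)
        ca = np.array([2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i])
        b = round(float(rng.uniform(5.0, 50.0)), 2)
        bfactors.append(b)
        resname = _ONE_TO_THREE[sequence[i]]
        for name, off in _BACKBONE_OFFSETS.items():
            serial += 1
            x, y, z = ca + np.array(off)
            pad_name = name if len(name) == 4 else f" {name:<3}"
            lines.append(
                f"ATOM  {serial:>5} {pad_name} {resname:>3} A{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          "
                f"{name[0]:>2}"
            )
    lines += ["TER", "END"]
    ledger = {
        "seed": seed,
        "n_residues": n_residues,
        "atom_count": serial,
        "sequence": sequence,
        "bfactors": bfactors,
    }
    return StructureFixture(
        "\n".join(lines) + "\n",
        sequence,
        list(range(1, n_residues + 1)),
        ledger,
    )


# ---------------------------------------------------------------------------
# Alignment / curated-site fixture


@dataclass
class AlignmentFixture:
    hit: AlignmentHit
    site: CuratedSite
    target_sequence: str
    ledger: dict


def make_alignment_fixture(
    seed: int,
    master_len: int = 40,
    n_sites: int = 5,
    gap_rate: float = 0.1,
) -> AlignmentFixture:
    """A gapped profile hit with known column structure and planted sites.

    The master (subject) sequence is random; each master column is deleted
    from the target with probability ``gap_rate`` and target-only insertions
    occur at the same rate.  The ledger lists every planted site position's
    true status and target coordinate, derived from the construction walk
    itself, never from the projection code.
    """
    if not 0 <= gap_rate < 1:
        raise ValueError("gap_rate must be in [0, 1)")
    if n_sites > master_len:
        raise ValueError("cannot plant more sites than master positions")
    rng = _rng(seed, _STREAM_ALIGNMENT)
    master = "".join(rng.choice(list(_AA20), size=master_len))
    query_start = int(rng.integers(1, 20))

    q_cols: list[str] = []
    s_cols: list[str] = []
    truth: dict[int, tuple[str, int | None]] = {}
    qpos = query_start - 1
    for mi in range(1, master_len + 1):
        if rng.random() < gap_rate:  # target-only insertion before this column
            qpos += 1
            q_cols.append(str(rng.choice(list(_AA20))))
            s_cols.append(GAP)
        if rng.random() < gap_rate:  # master column deleted from the target
            q_cols.append(GAP)
            s_cols.append(master[mi - 1])
            truth[mi] = ("gapped", None)
        else:
            qpos += 1
            q_cols.append(master[mi - 1])
            s_cols.append(master[mi - 1])
            truth[mi] = ("mapped", qpos)

    query_aligned = "".join(q_cols)
    subject_aligned = "".join(s_cols)
    query_end = query_start + sum(1 for c in query_aligned if c != GAP) - 1
    alignment = PairwiseAlignment(
        query_aligned=query_aligned,
        subject_aligned=subject_aligned,
        query_start=query_start,
        query_end=query_end,
        subject_start=1,
        subject_end=master_len,
        evalue=1e-12,
    )
    alignment.validate()
    hit = AlignmentHit("PF_FIX", alignment, 1e-12)

    positions = tuple(
        sorted(rng.choice(master_len, size=n_sites, replace=False) + 1)
    )
    site = CuratedSite("PF_FIX", "fixture_site", tuple(int(p) for p in positions))
    target_sequence = query_aligned.replace(GAP, "")
    ledger = {
        "seed": seed,
        "master_len": master_len,
        "gap_rate": gap_rate,
        "query_start": query_start,
        "sites": {
            str(int(p)): {"status": truth[int(p)][0], "target": truth[int(p)][1]}
            for p in positions
        },
    }
    return AlignmentFixture(hit, site, target_sequence, ledger)


# ---------------------------------------------------------------------------
# SNP fixture


@dataclass
class SnpFixture:
    cds: BioSequence
    records: list[PolymorphismRecord]
    ledger: dict


def make_snp_fixture(
    seed: int,
    cds_len: int = 300,
    n_records: int = 20,
    noise: float = 0.0,
    flank: int = 12,
) -> SnpFixture:
    """SNP fragments cut from a random CDS with known true placements.

    Each record takes a window of ±``flank`` bases around a random CDS
    position; with probability ``noise`` one flank base (never the site) is
    mutated.  True CDS positions and synonymy verdicts are planted in the
    ledger; verdicts are computed by translating the mutated codon with
    Biopython, independently of the package's own classifier.
    """
    if cds_len % 3:
        raise ValueError("cds_len must be a multiple of 3")
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    rng = _rng(seed, _STREAM_SNP)
    cds_seq = "".join(rng.choice(list(_NT), size=cds_len))
    cds = BioSequence("fixture_cds", cds_seq, NUCLEOTIDE)

    records = []
    truths = {}
    for k in range(n_records):
        p = int(rng.integers(1, cds_len + 1))
        start = max(1, p - flank)
        end = min(cds_len, p + flank)
        frag = list(cds_seq[start - 1 : end])
        site_offset = p - start + 1
        ref = cds_seq[p - 1]
        alt = str(rng.choice([b for b in _NT if b != ref]))
        clean = True
        if noise > 0 and rng.random() < noise:
            clean = False
            while True:
                mut_at = int(rng.integers(0, len(frag)))
                if mut_at != site_offset - 1:
                    break
            frag[mut_at] = str(
                rng.choice([b for b in _NT if b != frag[mut_at]])
            )
        snp_id = f"SNP{k:04d}"
        frequency = round(float(rng.uniform(0.01, 0.5)), 3)
        n_eco = int(rng.integers(1, len(_ECOTYPES) + 1))
        eco_names = rng.choice(_ECOTYPES, size=n_eco, replace=False)
        ecotypes = tuple((str(e), alt) for e in eco_names)
        records.append(
            PolymorphismRecord(
                snp_id=snp_id,
                fragment=BioSequence(f"{snp_id}_fragment", "".join(frag), NUCLEOTIDE),
                site_offset=site_offset,
                ref_allele=ref,
                alt_allele=alt,
                ecotypes=ecotypes,
                frequency=frequency,
            )
        )
        codon_index = (p - 1) // 3 + 1
        cstart = (codon_index - 1) * 3
        codon = cds_seq[cstart : cstart + 3]
        off = p - 1 - cstart
        alt_codon = codon[:off] + alt + codon[off + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        truths[snp_id] = {
            "cds_position": p,
            "codon_index": codon_index,
            "ref_aa": ref_aa,
            "alt_aa": alt_aa,
            "verdict": "synonymous" if ref_aa == alt_aa else "nonsynonymous",
            "clean": clean,
        }
    clean_fraction = (
        sum(1 for t in truths.values() if t["clean"]) / n_records
        if n_records
        else 1.0
    )
    ledger = {
        "seed": seed,
        "cds_len": cds_len,
        "noise": noise,
        "clean_fraction": clean_fraction,
        "records": truths,
    }
    return SnpFixture(cds, records, ledger)


# ---------------------------------------------------------------------------
# Network fixture


@dataclass
class NetworkFixture:
    graph: nx.Graph
    expression: "np.ndarray"
    expression_tsv: str
    edges_tsv: str
    query: str
    ledger: dict


def make_network_fixture(
    seed: int,
    n: int = 30,
    p: float = 0.1,
    planted_triangles: int = 2,
    n_conditions: int = 12,
    target_correlation: float = 0.9,
) -> NetworkFixture:
    """An Erdős–Rényi interactome with planted triangles and expression data.

    Triangles are planted on disjoint node triples (their three edges are
    forced present) and one neighbor's expression profile is generated to
    correlate with the query's at ``target_correlation`` in expectation.
    """
    import io as _io
    import pandas as pd

    rng = _rng(seed, _STREAM_NETWORK)
    base_seed = int(rng.integers(0, 2**31 - 1))
    g_raw = nx.gnp_random_graph(n, p, seed=base_seed)
    mapping = {i: f"G{i:03d}" for i in g_raw.nodes}
    g = nx.relabel_nodes(g_raw, mapping)

    nodes = sorted(g.nodes)
    triangles: list[tuple[str, str, str]] = []
    if planted_triangles * 3 > n:
        raise ValueError("not enough nodes for the requested triangles")
    picks = rng.choice(n, size=planted_triangles * 3, replace=False)
    for t in range(planted_triangles):
        tri = tuple(sorted(f"G{picks[3 * t + i]:03d}" for i in range(3)))
        triangles.append(tri)  # type: ignore[arg-type]
        g.add_edges_from(
            [(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])]
        )

    for a, b in g.edges:
        g.edges[a, b]["confidence"] = round(float(rng.uniform(0.2, 1.0)), 3)
        g.edges[a, b]["provenance"] = (
            "documented" if rng.random() < 0.1 else "predicted"
        )

    query = nodes[0]
    profiles = rng.normal(size=(n, n_conditions))
    # plant one profile correlated with the query's at the target level
    partner_idx = 1 if n > 1 else 0
    if n > 1:
        z = (profiles[0] - profiles[0].mean()) / profiles[0].std()
        noise = rng.normal(size=n_conditions)
        noise = noise - noise.mean()
        # orthogonalize so the sample correlation equals the target exactly
        noise = noise - (noise @ z) / (z @ z) * z
        noise = noise / noise.std()
        profiles[partner_idx] = (
            target_correlation * z
            + np.sqrt(1 - target_correlation**2) * noise
        )
    expr = pd.DataFrame(
        np.round(profiles, 4),
        index=nodes,
        columns=[f"cond{j + 1:02d}" for j in range(n_conditions)],
    )
    expr.index.name = "gene"

    edges_buf = _io.StringIO()
    write_edges(g, edges_buf)
    expr_buf = _io.StringIO()
    expr.to_csv(expr_buf, sep="\t")

    ledger = {
        "seed": seed,
        "n_nodes": n,
        "n_edges": g.number_of_edges(),
        "planted_triangles": [list(t) for t in triangles],
        "query": query,
        "correlated_pair": [query, nodes[partner_idx]],
        "target_correlation": target_correlation,
    }
    return NetworkFixture(
        g, profiles, expr_buf.getvalue(), edges_buf.getvalue(), query, ledger
    )


# ---------------------------------------------------------------------------
# Bundle writer (used by the CLI's make-fixtures subcommand)


def write_fixture_bundle(seed: int, outdir) -> dict:
    """Generate one of everything into ``outdir``; returns the merged ledger."""
    from pathlib import Path

    from . import sitemap as _sitemap
    from . import snpmap as _snpmap
    from .seqcore import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 80 residues comfortably covers every target coordinate the alignment
    # fixture can produce (query offset + master length + insertions)
    struct = make_structure_fixture(seed, n_residues=80)
    (outdir / "model.pdb").write_text(struct.pdb_text)

    alnfix = make_alignment_fixture(seed)
    _sitemap.write_hits_tsv([alnfix.hit], outdir / "hits.tsv")
    _sitemap.write_sites_tsv([alnfix.site], outdir / "sites.tsv")

    snpfix = make_snp_fixture(seed)
    write_fasta([snpfix.cds], str(outdir / "cds.fasta"))
    _snpmap.write_snps_tsv(snpfix.records, outdir / "snps.tsv")

    netfix = make_network_fixture(seed)
    (outdir / "edges.tsv").write_text(netfix.edges_tsv)
    (outdir / "expression.tsv").write_text(netfix.expression_tsv)

    ledger = {
        "seed": seed,
        "structure": struct.ledger,
        "alignment": alnfix.ledger,
        "snp": snpfix.ledger,
        "network": netfix.ledger,
    }
    write_ledger(ledger, outdir / "ledger.json")
    return ledger
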