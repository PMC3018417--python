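"""Minimal protein-structure handling for annotation and display encodings.

Parses fixed-column PDB ATOM/HETATM records into a light in-memory model,
reads the *implicit sequence* (one letter per residue actually present in the
coordinates — which may be shorter than the full-length gene product when
density is missing), computes model coverage of the full-length sequence,
filters predicted models by predictor confidence, and produces the two
per-residue display encodings used on structure surfaces: a blue-to-red
mobility gradient from temperature factors, and a grey/red
hydrophobic-vs-polar coloring.

The parser is deliberately strict: a malformed fixed-width record raises with
its line number rather than being silently skipped, and write->parse round
trips preserve numbering and temperature factors to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import (
    AMINO_ACID,
    BioSequence,
    THREE_TO_ONE,
    residue_class,
)


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    temperature_factor: float
    occupancy: float = 1.0
    het: bool = False
    element: str = ""


@dataclass
class StructureModel:
    """Parsed atoms plus optional predictor-confidence metadata (percent)."""

    model_id: str
    atoms: list[Atom]
    confidence: float | None = None

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            if not a.het:
                seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        """Distinct (chain, residue_number, residue_name) in file order."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.het:
                continue
            if chain is not None and a.chain_id != chain:
                continue
            key = (a.chain_id, a.residue_number)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_number, a.residue_name))
        return out


@dataclass
class ResidueMap:
    """Bridge between 1-based sequence indices and PDB (chain, residue number)."""

    entries: list[tuple[int, str, int]]

    def __post_init__(self) -> None:
        idxs = [e[0] for e in self.entries]
        if idxs != list(range(1, len(idxs) + 1)):
            raise ValueError("sequence indices must be contiguous from 1")
        keys = [(c, r) for _, c, r in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue_number) pairs must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict[int, tuple[str, int]]:
        return {i: (c, r) for i, c, r in self.entries}


class PDBFormatError(ValueError):
    pass


def _field(line: str, start: int, stop: int) -> str:
    return line[start:stop].strip()


def parse_pdb(text: str, model_id: str = "model") -> StructureModel:
    """Parse ATOM/HETATM records from fixed-column PDB text.

    TER/END and header-type records are ignored; a malformed coordinate,
    serial or residue-number field raises :class:`PDBFormatError` naming the
    offending line.
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record not in ("ATOM", "HETATM"):
            continue
        if len(line) < 66:
            raise PDBFormatError(
                f"line {lineno}: record too short for fixed-column layout"
            )
        try:
            atoms.append(
                Atom(
                    serial=int(_field(line, 6, 11)),
                    name=_field(line, 12, 16),
                    residue_name=_field(line, 17, 20),
                    chain_id=_field(line, 21, 22) or " ",
                    residue_number=int(_field(line, 22, 26)),
                    x=float(_field(line, 30, 38)),
                    y=float(_field(line, 38, 46)),
                    z=float(_field(line, 46, 54)),
                    occupancy=float(_field(line, 54, 60) or 1.0),
                    temperature_factor=float(_field(line, 60, 66) or 0.0),
                    het=(record == "HETATM"),
                    element=_field(line, 76, 78),
                )
            )
        except ValueError as exc:
            raise PDBFormatError(f"line {lineno}: {exc}") from None
    model = StructureModel(model_id, atoms)
    _check_residue_order(model)
    return model


def _check_residue_order(model: StructureModel) -> None:
    last: dict[str, int] = {}
    for a in model.atoms:
        if a.het:
            continue
        prev = last.get(a.chain_id)
        if prev is not None and a.residue_number < prev:
            raise PDBFormatError(
                f"chain {a.chain_id}: residue numbers decrease at "
                f"{a.residue_number} (after {prev})"
            )
        last[a.chain_id] = a.residue_number


def write_pdb(model: StructureModel) -> str:
    """Serialize back to fixed-column PDB text (ATOM/HETATM/TER/END)."""
    lines = []
    last_chain = None
    for a in model.atoms:
        if last_chain is not None and a.chain_id != last_chain:
            lines.append("TER")
        last_chain = a.chain_id
        record = "HETATM" if a.het else "ATOM"
        name = a.name if len(a.name) == 4 else f" {a.name:<3}"
        lines.append(
            f"{record:<6}{a.serial:>5} {name}"
            f" {a.residue_name:>3} {a.chain_id}{a.residue_number:>4}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}"
            f"{a.temperature_factor:6.2f}          {a.element:>2}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def implicit_sequence(
    model: StructureModel, chain: str
) -> tuple[BioSequence, ResidueMap]:
    """Read the amino-acid sequence implied by a chain's ATOM records.

    One letter per distinct residue in file order; residues without a
    standard three-letter code (including modified residues such as MSE)
    become ``X``.
    """
    if chain not in model.chains():
        raise KeyError(
            f"chain {chain!r} not in model {model.model_id!r} "
            f"(has {model.chains()})"
        )
    letters = []
    entries = []
    for idx, (ch, resnum, resname) in enumerate(
        model.residues(chain), start=1
    ):
        letters.append(THREE_TO_ONE.get(resname.upper(), "X"))
        entries.append((idx, ch, resnum))
    seq = BioSequence(f"{model.model_id}_{chain}", "".join(letters), AMINO_ACID)
    return seq, ResidueMap(entries)


def coverage_percent(model_residue_count: int, full_sequence_length: int) -> float:
    """Percent of the full-length sequence represented in the model."""
    if model_residue_count <= 0 or full_sequence_length <= 0:
        raise ValueError("residue counts must be positive")
    if model_residue_count > full_sequence_length:
        raise ValueError("model cannot contain more residues than the sequence")
    return 100.0 * model_residue_count / full_sequence_length


def filter_models_by_confidence(
    models: Iterable[StructureModel], required: float = 100.0
) -> list[StructureModel]:
    """Keep predicted models whose confidence equals the required value.

    Mirrors the significance rule for homology models: only predictions at
    100% predictor confidence are retained by default.
    """
    out = []
    for m in models:
        if m.confidence is None:
            raise ValueError(
                f"model {m.model_id!r} has no confidence metadata"
            )
        if m.confidence == required:
            out.append(m)
    return out


def read_confidence_tsv(path_or_buffer) -> dict[str, float]:
    """Sidecar TSV (model_id, confidence_percent) -> mapping."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"model_id": str})
    return dict(
        zip(df["model_id"], df["confidence_percent"].astype(float))
    )


def temperature_gradient(
    model: StructureModel, chain: str | None = None, ca_only: bool = False
) -> list[tuple[str, int, float]]:
    """Normalized per-residue mobility: 0 = least mobile (blue), 1 = most (red).

    The per-residue temperature factor is the mean over the residue's atoms
    (or the alpha carbon alone with ``ca_only``); values are min-max scaled,
    and a model with constant factors maps every residue to 0.5.
    """
    per_residue: dict[tuple[str, int], list[float]] = {}
    order: list[tuple[str, int]] = []
    for a in model.atoms:
        if a.het:
            continue
        if chain is not None and a.chain_id != chain:
            continue
        if ca_only and a.name != "CA":
            continue
        key = (a.chain_id, a.residue_number)
        if key not in per_residue:
            per_residue[key] = []
            order.append(key)
        per_residue[key].append(a.temperature_factor)
    if not per_residue:
        raise ValueError("no residues selected for the temperature gradient")
    means = {k: sum(v) / len(v) for k, v in per_residue.items()}
    lo, hi = min(means.values()), max(means.values())
    if hi == lo:
        return [(c, r, 0.5) for c, r in order]
    return [(c, r, (means[(c, r)] - lo) / (hi - lo)) for c, r in order]


def hydropathy_coloring(sequence: BioSequence) -> list[str]:
    """Grey/red coloring per residue: grey for hydrophobic, red otherwise.

    Matches the membrane-protein display convention — hydrophobic residues
    (facing the lipid bilayer) in grey, polar and charged residues (facing
    solvent) in red.  ``X`` is colored grey.
    """
    out = []
    for aa in sequence.residues:
        cls = residue_class(aa)
        out.append("grey" if cls in ("hydrophobic", "special") else "red")
    return out


def coloring_table(
    model: StructureModel,
    mode: str,
    chain: str | None = None,
    ca_only: bool = False,
) -> pd.DataFrame:
    """Per-residue display values as a (chain, residue_number, value) table."""
    if mode == "bfactor":
        rows = [
            {"chain": c, "residue_number": r, "value": round(v, 6)}
            for c, r, v in temperature_gradient(model, chain, ca_only)
        ]
    elif mode == "hydropathy":
        rows = []
        for ch in model.chains() if chain is None else [chain]:
            seq, rmap = implicit_sequence(model, ch)
            colors = hydropathy_coloring(seq)
            for (idx, c, r), color in zip(rmap.entries, colors):
                rows.append({"chain": c, "residue_number": r, "value": color})
    else:
        raise ValueError(f"unknown coloring mode {mode!r}")
    return pd.DataFrame(rows, columns=["chain", "residue_number", "value"])
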