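"""Protein records and proteome I/O.

A proteome is represented as a mapping ``species_id -> list[ProteinRecord]``.
Protein identifiers must be unique across the whole collection because they
are the node labels of every downstream set, graph and partition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

#: The 20 standard amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species of origin."""

    protein_id: str
    species_id: str
    sequence: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise InvalidInputError(
                f"protein {self.protein_id!r} contains residues outside the "
                f"20-letter alphabet plus X: {sorted(bad)}"
            )
        object.__setattr__(self, "length", len(self.sequence))


Proteomes = Mapping[str, list[ProteinRecord]]


def _check_unique(records: Iterable[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.protein_id in seen:
            raise InvalidInputError(f"duplicate protein_id {rec.protein_id!r}")
        seen.add(rec.protein_id)


def read_fasta(path: str | os.PathLike, species_id: str | None = None) -> list[ProteinRecord]:
    """Read one species' proteome from a FASTA file.

    The first whitespace-delimited token of each header is the protein_id.
    ``species_id`` defaults to the filename stem.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    records = [
        ProteinRecord(protein_id=rec.id, species_id=species_id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique(records)
    return records


def read_proteomes(
    paths: Iterable[str | os.PathLike] | None = None,
    manifest: str | os.PathLike | None = None,
) -> dict[str, list[ProteinRecord]]:
    """Load a proteome collection from FASTA files or a two-column manifest TSV.

    The manifest has columns ``species_id<TAB>path``; without a manifest the
    species_id is each file's stem.  Protein ids must be globally unique.
    """
    entries: list[tuple[str, Path]] = []
    if manifest is not None:
        base = Path(manifest).parent
        with open(manifest) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                species_id, p = line.split("\t")
                p = Path(p)
                entries.append((species_id, p if p.is_absolute() else base / p))
    elif paths is not None:
        entries = [(Path(p).stem, Path(p)) for p in paths]
    else:
        raise InvalidInputError("provide FASTA paths or a manifest TSV")

    proteomes: dict[str, list[ProteinRecord]] = {}
    for species_id, p in entries:
        if species_id in proteomes:
            raise InvalidInputError(f"duplicate species_id {species_id!r}")
        proteomes[species_id] = read_fasta(p, species_id=species_id)
    _check_unique(r for recs in proteomes.values() for r in recs)
    return proteomes


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def flatten(proteomes: Proteomes) -> list[ProteinRecord]:
    """All records of a collection in deterministic (species, id) order."""
    return [r for sp in sorted(proteomes) for r in sorted(proteomes[sp], key=lambda r: r.protein_id)]
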