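"""Diproline (XPPX) stall-motif scanning over protein sequences.

Elongation factor P (EF-P) relieves ribosome stalling at consecutive
prolines; the four-residue XPPX window — any residue, Pro, Pro, any
residue — is the canonical signature of a stall-prone site. This module
finds every such window in a protein sequence, plus user-supplied
non-canonical stall triplets (e.g. IPI, KPG, DPG), and aggregates the
per-protein motif flags a downstream regulatory classification consumes.

Position convention: a hit's ``position`` is the 1-based index of the
motif's *first* residue (the leading X for XPPX, the first letter for a
triplet). A proline pair flush against the N- or C-terminus has no
in-sequence flanking residue and is therefore not an XPPX hit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "AA_ALPHABET",
    "NONCANONICAL_TRIPLETS",
    "ProteinRecord",
    "MotifHit",
    "scan_xppx",
    "scan_noncanonical",
    "proteome_motif_table",
    "read_fasta",
    "write_fasta",
    "write_motif_table",
]

# 20 standard residues plus 'X' for an unknown residue. 'X' may occupy
# the flanking slots of an XPPX window but never counts as proline.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Non-XPPX stall triplets reported for B. subtilis EF-P.
NONCANONICAL_TRIPLETS = frozenset({"IPI", "KPG", "DPG"})

KIND_XPPX = "xppx"
KIND_NONCANONICAL = "noncanonical"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and (optional) gene link."""

    id: str
    sequence: str
    gene: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene or self.id)
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        for offset, residue in enumerate(self.sequence, start=1):
            if residue not in AA_ALPHABET:
                raise ValueError(
                    f"protein {self.id!r}: invalid residue {residue!r} "
                    f"at position {offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence; ``position`` is 1-based at the first residue."""

    protein_id: str = field(compare=False)
    position: int
    motif: str = field(compare=False)
    kind: str = field(compare=False)


def scan_xppx(protein: ProteinRecord) -> list[MotifHit]:
    """Return every length-4 window whose middle two residues are P-P.

    Overlapping windows (polyproline tracts of three or more P) are each
    reported; a run of n prolines yields n-3 windows once flanked
    in-sequence. Hits come back in ascending position order.
    """
    seq = protein.sequence
    hits = []
    for i in range(len(seq) - 3):
        if seq[i + 1] == "P" and seq[i + 2] == "P":
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    position=i + 1,
                    motif=seq[i : i + 4],
                    kind=KIND_XPPX,
                )
            )
    return hits


def scan_noncanonical(
    protein: ProteinRecord, triplets: Iterable[str]
) -> list[MotifHit]:
    """Report every occurrence of any 3-letter stall triplet.

    The ``motif`` field holds the bare 3-letter match (no padding); an
    empty triplet set yields an empty list.
    """
    tripset = set(triplets)
    for t in tripset:
        if len(t) != 3 or not t.isupper():
            raise ValueError(f"stall triplet must be 3 uppercase letters, got {t!r}")
    if not tripset:
        return []
    seq = protein.sequence
    hits = []
    for i in range(len(seq) - 2):
        window = seq[i : i + 3]
        if window in tripset:
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    position=i + 1,
                    motif=window,
                    kind=KIND_NONCANONICAL,
                )
            )
    return hits


def proteome_motif_table(
    proteome: Iterable[ProteinRecord],
) -> dict[str, tuple[bool, list[MotifHit]]]:
    """Map protein id -> (has_xppx, xppx hits) across a proteome.

    ``has_xppx`` is True iff the protein carries at least one XPPX window.
    Duplicate ids are an input error.
    """
    table: dict[str, tuple[bool, list[MotifHit]]] = {}
    for protein in proteome:
        if protein.id in table:
            raise ValueError(f"duplicate protein id {protein.id!r} in proteome")
        hits = scan_xppx(protein)
        table[protein.id] = (bool(hits), hits)
    return table


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-FASTA of amino-acid sequences.

    The header token up to the first whitespace is the protein id; a
    ``gene=NAME`` key anywhere in the description is parsed as the gene
    name (defaulting to the id). Sequences are uppercased before
    validation.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = ""
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[len("gene=") :]
                break
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), gene=gene)
        )
    return records


def write_fasta(proteome: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteome:
            fh.write(f">{p.id} gene={p.gene}\n")
            seq = p.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_motif_table(path: str | Path) -> dict[str, tuple[bool, list[MotifHit]]]:
    """Read a motif TSV back into the per-protein table form.

    Only proteins with at least one hit appear in the file, so absent
    proteins are simply missing keys (treated as motif-free downstream).
    """
    table: dict[str, tuple[bool, list[MotifHit]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            if len(row) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            hit = MotifHit(
                protein_id=row[0], position=int(row[1]), motif=row[2], kind=row[3]
            )
            has, hits = table.get(hit.protein_id, (False, []))
            hits.append(hit)
            table[hit.protein_id] = (has or hit.kind == KIND_XPPX, hits)
    return table


def write_motif_table(
    table: Mapping[str, tuple[bool, list[MotifHit]]] | Iterable[MotifHit],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write motif hits as TSV (protein_id, position, motif, kind).

    ``position`` is the 1-based index of the motif's first residue.
    """
    if isinstance(table, Mapping):
        hits: list[MotifHit] = [h for _, hs in table.values() for h in hs]
    else:
        hits = list(table)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "position", "motif", "kind"])
        for h in hits:
            writer.writerow([h.protein_id, h.position, h.motif, h.kind])
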