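"""PROSITE-style peptide motifs and proteome scanning.

A tolerance profile serializes to a dash-separated pattern of residue
classes, e.g. ``[FILMT]-W-[QT]``: bracketed classes list the tolerated
residues at a position, singleton classes are written bare.  Scanning slides
the motif across every window of each protein sequence; all overlapping
matches are reported with 1-based inclusive offsets (the ScanProSite
reporting convention).

Non-canonical letters (X, B, Z, U, ...) never match any class: candidate
cross-reactive epitopes must be real, synthesizable peptides.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

from .activation import AMINO_ACIDS

logger = logging.getLogger(__name__)

_CANONICAL = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class PeptideMotif:
    """Ordered residue classes, one per peptide position."""

    classes: tuple[frozenset[str], ...]
    id: str = ""

    def __post_init__(self) -> None:
        classes = tuple(frozenset(c) for c in self.classes)
        if not classes:
            raise ValueError("motif must have at least one class")
        for i, c in enumerate(classes, start=1):
            if not c:
                raise ValueError(f"empty class at position {i}")
            bad = sorted(c - _CANONICAL)
            if bad:
                raise ValueError(f"illegal residues {bad} in class at position {i}")
        object.__setattr__(self, "classes", classes)

    def __len__(self) -> int:
        return len(self.classes)

    def contains(self, other: "PeptideMotif") -> bool:
        """True if every class of ``other`` is a subset of this motif's."""
        return len(self) == len(other) and all(
            a <= b for a, b in zip(other.classes, self.classes)
        )


@dataclass(frozen=True)
class ProteomeRecord:
    """One protein sequence; id is the first whitespace token of the header."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id}: sequence must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())


class ProteomeHit(NamedTuple):
    motif_id: str
    protein_id: str
    offset: int  # 1-based inclusive start
    peptide: str


_ELEMENT_RE = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z])")


def parse_motif(text: str, motif_id: str = "") -> PeptideMotif:
    """Parse a dash-separated pattern of bracketed classes / bare residues.

    Duplicate letters inside a class collapse; lower case is accepted.
    Malformed elements are rejected with the 1-based element position named.
    """
    if not text or not text.strip():
        raise ValueError("empty motif text")
    classes = []
    for i, element in enumerate(text.strip().split("-"), start=1):
        m = _ELEMENT_RE.fullmatch(element)
        if m is None:
            raise ValueError(
                f"malformed motif element {element!r} at position {i}"
            )
        letters = (m.group(1) or m.group(2)).upper()
        bad = sorted(set(letters) - _CANONICAL)
        if bad:
            raise ValueError(
                f"illegal residues {bad} in motif element at position {i}"
            )
        classes.append(frozenset(letters))
    return PeptideMotif(classes=tuple(classes), id=motif_id)


def emit_motif(motif: PeptideMotif) -> str:
    """Serialize a motif; deterministic and byte-stable.

    Classes with two or more members become alphabetically sorted bracketed
    lists; singletons are written bare; elements are joined by ``-``.
    """
    parts = []
    for c in motif.classes:
        letters = "".join(sorted(c))
        parts.append(letters if len(letters) == 1 else f"[{letters}]")
    return "-".join(parts)


def match_peptide(peptide: str, motif: PeptideMotif) -> bool:
    """Position-wise class membership; non-canonical letters never match."""
    if len(peptide) != len(motif):
        raise ValueError(
            f"peptide length {len(peptide)} != motif length {len(motif)}"
        )
    return all(res in c for res, c in zip(peptide.upper(), motif.classes))


def motif_regex(motif: PeptideMotif) -> "re.Pattern[str]":
    """Compile a motif to a lookahead regex that reports overlapping windows."""
    body = "".join(f"[{''.join(sorted(c))}]" for c in motif.classes)
    return re.compile(f"(?=({body}))")


def scan_sequence(
    sequence: str, motif: PeptideMotif
) -> list[tuple[int, str]]:
    """All motif-matching windows of a sequence as (1-based offset, peptide).

    Overlapping matches are all reported; a sequence shorter than the motif
    yields an empty list.
    """
    seq = sequence.upper()
    pattern = motif_regex(motif)
    return [(m.start() + 1, m.group(1)) for m in pattern.finditer(seq)]


def read_fasta(path) -> list[ProteomeRecord]:
    """Read a FASTA file into proteome records (UniProt headers tolerated)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteomeRecord(
                id=rec.id, sequence=str(rec.seq), description=rec.description
            )
        )
    return records


def scan_proteome(
    records: Iterable[ProteomeRecord],
    motifs: Sequence[PeptideMotif],
    exclude_peptides: Iterable[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every record against every motif.

    Returns
    -------
    hits
        One row per match: motif_id, protein_id, offset (1-based), peptide.
        Excluded peptides are retained here for completeness.
    summary
        Deduplicated per (motif_id, peptide): occurrence count and the
        semicolon-joined source protein ids.  Peptides listed in
        ``exclude_peptides`` (typically the wild-type target epitope itself)
        are removed from the summary.
    """
    exclude = {p.upper() for p in exclude_peptides}
    rows: list[ProteomeHit] = []
    skipped = 0
    for rec in records:
        try:
            seq = rec.sequence
        except AttributeError:
            skipped += 1
            logger.warning("skipping unreadable proteome record: %r", rec)
            continue
        for motif in motifs:
            for offset, peptide in scan_sequence(seq, motif):
                rows.append(ProteomeHit(motif.id, rec.id, offset, peptide))
    if skipped:
        logger.warning("skipped %d unreadable records", skipped)
    hits = pd.DataFrame(rows, columns=["motif_id", "protein_id", "offset", "peptide"])
    if hits.empty:
        summary = pd.DataFrame(
            columns=["motif_id", "peptide", "n_occurrences", "protein_ids"]
        )
        return hits, summary
    kept = hits[~hits["peptide"].isin(exclude)]
    summary = (
        kept.groupby(["motif_id", "peptide"], as_index=False)
        .agg(
            n_occurrences=("protein_id", "size"),
            protein_ids=("protein_id", lambda s: ";".join(sorted(set(s)))),
        )
        .sort_values(["motif_id", "n_occurrences", "peptide"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    return hits, summary
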