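"""Transcript data model, FASTA I/O and site mutagenesis.

All sequences are stored in the RNA alphabet (A, C, G, U), 5'->3'.  DNA
input (T, lowercase, mixed) is silently normalized on read, because the
upstream sources mix conventions: plasmid inserts and cloning reports are
written as DNA while miRNA binding sites are written as RNA.  Coordinates
are 1-based and inclusive throughout, matching the convention used when
binding-site intervals are reported on transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: transcript biotypes understood by the pipeline
BIOTYPES = ("lncRNA", "utr3", "miRNA")


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad alphabet, bad coordinates)."""


def normalize_rna(sequence: str) -> str:
    """Uppercase, convert T->U and validate the RNA alphabet.

    Raises :class:`SequenceError` naming the first offending position.
    """
    seq = sequence.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise SequenceError(
                f"invalid character {ch!r} at position {pos} (expected A/C/G/U or DNA equivalents)"
            )
    return seq


@dataclass(frozen=True)
class Transcript:
    """One identified RNA sequence.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within any collection handled here.
    biotype:
        One of ``lncRNA``, ``utr3`` (an mRNA 3'UTR) or ``miRNA``.
    sequence:
        RNA string, 5'->3'.  Normalized (T->U, uppercased) at construction.
    """

    id: str
    biotype: str
    sequence: str = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("transcript id must be non-empty")
        if self.biotype not in BIOTYPES:
            raise SequenceError(
                f"unknown biotype {self.biotype!r} for {self.id!r}; expected one of {BIOTYPES}"
            )
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not self.sequence:
            raise SequenceError(f"transcript {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, end: int) -> str:
        """Return the 1-based inclusive slice [start, end]."""
        _check_region(self, start, end)
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class SequenceRegion:
    """A 1-based inclusive interval on a named transcript."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"invalid region [{self.start}, {self.end}] on {self.transcript_id!r}"
            )


def _check_region(transcript: Transcript, start: int, end: int) -> None:
    if not (1 <= start <= end <= transcript.length):
        raise SequenceError(
            f"region [{start}, {end}] out of bounds for transcript "
            f"{transcript.id!r} of length {transcript.length}"
        )


def reverse_complement(sequence: str) -> str:
    """Watson-Crick complement, reversed (an involution on RNA strings)."""
    seq = normalize_rna(sequence)
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, biotype: str = "lncRNA") -> list[Transcript]:
    """Read a multi-record FASTA file into :class:`Transcript` objects.

    T is converted to U and case is folded to upper; wrapped and unwrapped
    records are both accepted.  Duplicate ids and empty sequences raise
    :class:`SequenceError`.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[Transcript] = []
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise SequenceError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        seq = str(record.seq)
        if not seq:
            raise SequenceError(f"empty sequence for FASTA record {record.id!r} in {path}")
        out.append(Transcript(id=record.id, biotype=biotype, sequence=seq))
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    """Write transcripts as FASTA (RNA alphabet, fixed line width)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def apply_site_mutation(
    transcript: Transcript, region: SequenceRegion, replacement: str
) -> tuple[Transcript, str]:
    """Replace ``region`` of ``transcript`` with ``replacement``.

    Returns ``(mutant, original_subsequence)``; the input transcript is not
    modified.  The replacement may differ in length from the region, in
    which case the mutant's length changes accordingly.
    """
    if region.transcript_id != transcript.id:
        raise SequenceError(
            f"region names transcript {region.transcript_id!r} but was applied to {transcript.id!r}"
        )
    _check_region(transcript, region.start, region.end)
    repl = normalize_rna(replacement)
    original = transcript.subsequence(region.start, region.end)
    mutated = (
        transcript.sequence[: region.start - 1] + repl + transcript.sequence[region.end :]
    )
    return replace(transcript, sequence=mutated), original
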