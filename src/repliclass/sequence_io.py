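"""FASTA input/output, annotation-keyword labelling and sequence composition.

Contigs are the package's unit of data: a nucleotide sequence plus an
optional plasmid/chromosome truth label and, when the contig was cut out of
a complete replicon, the provenance coordinates on that replicon. All
internal coordinates are 0-based, half-open; conversions to 1-based
conventions happen only at format boundaries (see :mod:`repliclass.homology`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import ValidationError

PLASMID = "plasmid"
CHROMOSOME = "chromosome"
UNKNOWN = "unknown"

#: Default annotation keywords used in the pre-classification step. RefSeq
#: headers of complete replicons are worded like "... plasmid pXYZ, complete
#: sequence" or "... chromosome, complete genome"; matching is
#: case-insensitive substring search. Both lists are configurable.
PLASMID_KEYWORDS: tuple[str, ...] = ("plasmid",)
CHROMOSOME_KEYWORDS: tuple[str, ...] = ("chromosome", "complete genome")


@dataclass
class Contig:
    """A nucleotide sequence with identity, truth label and provenance.

    ``source_start``/``source_end`` are 0-based half-open coordinates on the
    replicon the contig was cut from, when known.
    """

    id: str
    sequence: str
    description: str = ""
    truth_label: str = UNKNOWN
    source_id: str | None = None
    source_start: int | None = None
    source_end: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("contig id must be non-empty")
        if any(c.isspace() for c in self.id):
            raise ValidationError(
                f"contig id {self.id!r} contains whitespace; it would not "
                "survive a FASTA header round trip"
            )
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"contig {self.id!r} has an empty sequence")
        if self.truth_label not in (PLASMID, CHROMOSOME, UNKNOWN):
            raise ValidationError(
                f"contig {self.id!r}: truth_label must be one of "
                f"{PLASMID!r}, {CHROMOSOME!r}, {UNKNOWN!r}"
            )
        if (self.source_start is None) != (self.source_end is None):
            raise ValidationError(
                f"contig {self.id!r}: source_start and source_end must be "
                "set together"
            )
        if self.source_start is not None:
            span = self.source_end - self.source_start
            if span != len(self.sequence):
                raise ValidationError(
                    f"contig {self.id!r}: source span {span} != sequence "
                    f"length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig`.

    Record order is preserved, sequences are uppercased, and ids must be
    unique within the file. Multi-line sequences and CR/LF line endings are
    accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    contigs: list[Contig] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(maxsplit=1)
            if not parts:
                raise ValidationError(f"{path}: record with empty header")
            rec_id = parts[0]
            description = parts[1] if len(parts) == 2 else ""
            if rec_id in seen:
                raise ValidationError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            if not seq:
                raise ValidationError(f"{path}: record {rec_id!r} has no sequence")
            contigs.append(Contig(id=rec_id, sequence=seq, description=description))
    return contigs


def write_fasta(
    contigs: Sequence[Contig], path: str | os.PathLike, line_width: int = 60
) -> None:
    """Write contigs as FASTA, wrapping sequence lines at ``line_width``."""
    if len(contigs) == 0:
        raise ValidationError("cannot write an empty FASTA file")
    if line_width < 1:
        raise ValidationError("line_width must be >= 1")
    path = Path(path)
    with open(path, "w") as handle:
        for contig in contigs:
            header = contig.id
            if contig.description:
                header = f"{header} {contig.description}"
            handle.write(f">{header}\n")
            seq = contig.sequence
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")


def annotation_label(
    description: str,
    plasmid_keywords: Iterable[str] = PLASMID_KEYWORDS,
    chromosome_keywords: Iterable[str] = CHROMOSOME_KEYWORDS,
) -> str:
    """Classify a FASTA description by annotation keywords.

    Returns ``"plasmid"`` or ``"chromosome"`` on an unambiguous keyword
    match (case-insensitive substring), ``"unknown"`` otherwise. A header
    matching both classes is ambiguous and returns ``"unknown"`` so the
    contig flows on to the classifier instead of being mislabelled.
    """
    text = description.lower()
    is_plasmid = any(k.lower() in text for k in plasmid_keywords)
    is_chromosome = any(k.lower() in text for k in chromosome_keywords)
    if is_plasmid and not is_chromosome:
        return PLASMID
    if is_chromosome and not is_plasmid:
        return CHROMOSOME
    return UNKNOWN


def gc_content(sequence: str) -> float:
    """Fraction of G+C in a sequence, in [0, 1].

    Counts G, C and the IUPAC "strong" code S in the numerator (matching the
    semantics of the classic Biopython GC utility); every other character,
    including ambiguity codes, counts only toward the denominator.
    Case-insensitive.
    """
    if len(sequence) == 0:
        raise ValidationError("gc_content of an empty sequence is undefined")
    upper = sequence.upper()
    gc = upper.count("G") + upper.count("C") + upper.count("S")
    return gc / len(upper)
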