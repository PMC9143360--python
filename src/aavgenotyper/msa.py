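"""Aligned sequence sets and alignment-coordinate utilities.

The whole pipeline operates on a nucleotide multiple sequence alignment
(gap character ``-``). Coordinates are 1-based and inclusive everywhere a
user sees them, matching the convention of genome annotations such as
"453-1700".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Data import CodonTable


class MsaError(ValueError):
    """Base class for alignment errors."""


class AlignmentLengthError(MsaError):
    """Sequences in an alignment do not share one length."""


class DuplicateIdError(MsaError):
    """Two records carry the same identifier."""


class FastaFormatError(MsaError):
    """The input is not a usable FASTA alignment."""


class RegionBoundsError(MsaError):
    """A region does not fit inside the alignment."""


@dataclass(frozen=True, order=True)
class Region:
    """A 1-based, inclusive span of alignment columns.

    ``Region(453, 1700)`` is the rep-gene classification region used
    throughout: 1248 columns.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise RegionBoundsError(
                f"invalid region {self.start}-{self.end}: need 1 <= start <= end"
            )

    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def slice(self) -> slice:
        """0-based half-open slice over alignment columns."""
        return slice(self.start - 1, self.end)

    def __str__(self) -> str:  # "453-1700"
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``"453:1700"`` or ``"453-1700"``."""
        sep = ":" if ":" in text else "-"
        a, b = text.split(sep, 1)
        return cls(int(a), int(b))


_NT_CHARS = set("ACGTRYSWKMBDHVN-")


@dataclass
class Msa:
    """An in-memory multiple sequence alignment.

    Records are ordered; ids are the first whitespace-delimited token of the
    FASTA header and must be unique. Sequences are stored upper-case with
    ``U`` normalised to ``T`` on construction via :func:`read_fasta_alignment`.
    """

    ids: list[str]
    seqs: list[str]
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise MsaError("ids and seqs differ in number")
        if not self.descriptions:
            self.descriptions = list(self.ids)
        if any(not i for i in self.ids):
            raise DuplicateIdError("empty sequence id")
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise DuplicateIdError(f"duplicate sequence id: {i!r}")
            seen.add(i)
        if self.seqs:
            L = len(self.seqs[0])
            for i, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentLengthError(
                        f"record {i!r} has length {len(s)}, expected {L}"
                    )

    @property
    def alignment_length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    def seq(self, record_id: str) -> str:
        try:
            return self.seqs[self.ids.index(record_id)]
        except ValueError:
            raise MsaError(f"unknown record id: {record_id!r}") from None

    def subset(self, record_ids: list[str]) -> "Msa":
        idx = [self.ids.index(r) for r in record_ids]
        return Msa(
            [self.ids[i] for i in idx],
            [self.seqs[i] for i in idx],
            [self.descriptions[i] for i in idx],
        )


def read_fasta_alignment(path: str | Path) -> Msa:
    """Read a FASTA alignment.

    Ids are truncated at the first whitespace (full header kept as
    description); sequences are upper-cased and ``U`` is normalised to ``T``.
    Records of unequal length raise :class:`AlignmentLengthError` naming the
    offending record; an empty file raises :class:`FastaFormatError`.
    """
    ids: list[str] = []
    seqs: list[str] = []
    descs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        descs.append(rec.description)
        seqs.append(str(rec.seq).upper().replace("U", "T"))
    if not ids:
        raise FastaFormatError(f"no FASTA records in {path}")
    return Msa(ids, seqs, descs)


def write_fasta_alignment(msa: Msa, path: str | Path, wrap: int = 70) -> None:
    """Write the alignment as FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rid, desc, seq in zip(msa.ids, msa.descriptions, msa.seqs):
            header = desc if desc.split()[:1] == [rid] else rid
            fh.write(f">{header}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def extract_region(msa: Msa, region: Region) -> Msa:
    """Slice every sequence to the columns of ``region`` (1-based inclusive)."""
    if region.end > msa.alignment_length:
        raise RegionBoundsError(
            f"region {region} exceeds alignment length {msa.alignment_length}"
        )
    return Msa(
        list(msa.ids),
        [s[region.slice] for s in msa.seqs],
        list(msa.descriptions),
    )


_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
_CODON_MAP.update({c: "*" for c in _STANDARD_TABLE.stop_codons})


def translate_sequence(seq: str, frame_offset: int = 0) -> str:
    """Translate one aligned nucleotide sequence with the standard code.

    Any codon containing a gap or ambiguity code becomes ``X``; stop codons
    become ``*``; a trailing partial codon is dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    bad = set(seq) - _NT_CHARS
    if bad:
        raise TypeError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        out.append(_CODON_MAP.get(seq[i : i + 3], "X"))
    return "".join(out)


def translate_region(msa: Msa, region: Region, frame_offset: int = 0) -> Msa:
    """Translate ``region`` of every record in frame ``frame_offset``.

    The reading-frame phase of the region within the alignment is the
    caller's responsibility (default 0: translation starts at
    ``region.start + frame_offset``).
    """
    if region.length() - frame_offset < 3:
        raise RegionBoundsError(
            f"region {region} too short to translate in frame {frame_offset}"
        )
    nt = extract_region(msa, region)
    return Msa(
        list(nt.ids),
        [translate_sequence(s, frame_offset) for s in nt.seqs],
        list(nt.descriptions),
    )


def ref_coordinate_map(msa: Msa, ref_id: str) -> dict[int, int | None]:
    """Map alignment columns to ungapped positions of a reference record.

    Returns ``{column: position}`` over all columns (both 1-based); columns
    where the reference is gapped map to ``None``. The column holding the
    reference's k-th non-gap character maps to k.
    """
    ref = msa.seq(ref_id)
    out: dict[int, int | None] = {}
    pos = 0
    for col, ch in enumerate(ref, start=1):
        if ch == "-":
            out[col] = None
        else:
            pos += 1
            out[col] = pos
    return out
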