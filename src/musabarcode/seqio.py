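"""FASTA input/output and alignment validation for labeled barcode sequences.

Records carry a species label and an optional genome-constitution code
(e.g. ``AA``, ``AAB`` for *Musa* cultivars) parsed from the FASTA header.
The default header scheme is pipe-delimited ``species|sample_id|genome_code``
with the genome code optional; a regex-configurable scheme is provided
because public-database deflines vary.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes plus the gap character. "." is deliberately
# rejected so that gap dialects are never silently mixed.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

__all__ = [
    "LabeledSequence",
    "AlignedSet",
    "LabelScheme",
    "PIPE_SCHEME",
    "FastaParseError",
    "SequenceValidationError",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "read_sample_sheet",
    "apply_sample_sheet",
    "validate_alignment",
]


class FastaParseError(ValueError):
    """A FASTA header did not match the expected labeling scheme."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class SequenceValidationError(ValueError):
    """A residue string contains characters outside the IUPAC alphabet."""


class AlignmentError(ValueError):
    """Records do not form a valid alignment."""


@dataclass(frozen=True)
class LabelScheme:
    """Header-parsing rule mapping a defline to (species, sample_id, genome_code).

    ``pattern`` must expose named groups ``species`` and ``sample_id``;
    ``genome_code`` is optional.
    """

    pattern: str

    def parse(self, header: str) -> tuple[str, str, str | None]:
        m = re.match(self.pattern, header.strip())
        if m is None:
            raise FastaParseError(
                f"header {header!r} does not match scheme {self.pattern!r}"
            )
        groups = m.groupdict()
        species = groups.get("species")
        sample_id = groups.get("sample_id")
        if not species or not sample_id:
            raise FastaParseError(f"header {header!r} lacks species or sample id")
        return species, sample_id, groups.get("genome_code") or None


#: Default scheme: ``species|sample_id`` or ``species|sample_id|genome_code``.
PIPE_SCHEME = LabelScheme(
    r"^(?P<species>[^|\s]+)\|(?P<sample_id>[^|\s]+)(?:\|(?P<genome_code>[^|\s]+))?$"
)


def _normalize_residues(raw: str, sample_id: str) -> str:
    residues = raw.upper().replace("U", "T")
    for pos, ch in enumerate(residues, start=1):
        if ch not in IUPAC_ALPHABET:
            raise SequenceValidationError(
                f"record {sample_id!r}: illegal character {ch!r} at position {pos}"
            )
    if not residues:
        raise SequenceValidationError(f"record {sample_id!r}: empty sequence")
    return residues


@dataclass(frozen=True)
class LabeledSequence:
    """One barcode record: sample id, species label, optional genome code, residues.

    Residues are stored uppercase with ``U`` mapped to ``T``; only IUPAC
    nucleotide codes and ``-`` are accepted.
    """

    sample_id: str
    species: str
    residues: str
    genome_code: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, self.sample_id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        """Residues with alignment gaps removed."""
        return self.residues.replace("-", "")

    def header(self) -> str:
        parts = [self.species, self.sample_id]
        if self.genome_code:
            parts.append(self.genome_code)
        return "|".join(parts)


@dataclass(frozen=True)
class AlignedSet:
    """A validated alignment: equal-length records over a shared coordinate system."""

    records: tuple[LabeledSequence, ...]
    length: int = field(default=0)

    def __post_init__(self):
        if self.length == 0 and self.records:
            object.__setattr__(self, "length", len(self.records[0]))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}

    def species_counts(self) -> Counter:
        """Per-species sample counts."""
        return Counter(r.species for r in self.records)

    def n_species(self) -> int:
        return len(self.species_counts())

    def subset(self, sample_ids: Iterable[str]) -> "AlignedSet":
        wanted = set(sample_ids)
        return validate_alignment([r for r in self.records if r.sample_id in wanted])


def _header_lines(path: Path) -> dict[str, int]:
    """Map each defline (sans '>') to its 1-based line number, for error reporting."""
    lines: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                lines.setdefault(line[1:].strip(), i)
    return lines


def read_fasta(
    path: str | Path, label_scheme: LabelScheme = PIPE_SCHEME
) -> list[LabeledSequence]:
    """Read a (plain or aligned) FASTA file into labeled records, in file order.

    Raises :class:`FastaParseError` with the offending line number on a
    malformed header and :class:`SequenceValidationError` on illegal residues.
    """
    path = Path(path)
    records: list[LabeledSequence] = []
    line_of = _header_lines(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.strip()
        try:
            species, sample_id, genome = label_scheme.parse(header)
        except FastaParseError as err:
            raise FastaParseError(str(err.args[0]), line=line_of.get(header)) from None
        records.append(
            LabeledSequence(
                sample_id=sample_id,
                species=species,
                genome_code=genome,
                residues=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Iterable[LabeledSequence], path: str | Path) -> None:
    """Write records with pipe-delimited headers (round-trips with read_fasta)."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.header(), description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_sample_sheet(path: str | Path) -> dict[str, tuple[str, str | None]]:
    """Read a TSV sample sheet (sample_id, species, genome_code) as a label source.

    The genome_code column is optional. A header row starting with
    ``sample_id`` is skipped.
    """
    mapping: dict[str, tuple[str, str | None]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 1 and parts[0].lower() == "sample_id":
                continue
            if len(parts) < 2:
                raise FastaParseError("sample sheet row needs >=2 columns", line=i)
            genome = parts[2] if len(parts) > 2 and parts[2] else None
            mapping[parts[0]] = (parts[1], genome)
    return mapping


def apply_sample_sheet(
    records: Iterable[LabeledSequence], sheet: dict[str, tuple[str, str | None]]
) -> list[LabeledSequence]:
    """Relabel records from a sample sheet keyed by sample_id."""
    out = []
    for r in records:
        if r.sample_id in sheet:
            species, genome = sheet[r.sample_id]
            out.append(
                LabeledSequence(
                    sample_id=r.sample_id,
                    species=species,
                    genome_code=genome,
                    residues=r.residues,
                )
            )
        else:
            out.append(r)
    return out


def validate_alignment(records: Sequence[LabeledSequence]) -> AlignedSet:
    """Check that all records share one length and build an :class:`AlignedSet`.

    Idempotent: re-validating an AlignedSet's records yields an equal set.
    Raises :class:`AlignmentError` listing every offending record when
    lengths are ragged, or when fewer than two records are supplied.
    """
    if isinstance(records, AlignedSet):
        records = records.records
    if not records:
        raise AlignmentError("alignment requires at least one record")
    length = len(records[0])
    ragged = [r.sample_id for r in records if len(r) != length]
    if ragged:
        raise AlignmentError(
            f"ragged alignment: records {ragged} differ from length {length}"
        )
    if len(records) < 2:
        raise AlignmentError("alignment requires >=2 records")
    return AlignedSet(records=tuple(records), length=length)
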