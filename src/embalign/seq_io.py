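"""FASTA input/output, alphabet validation, and CDS translation.

Sequences are plain upper-case strings over closed alphabets.  The protein
alphabet is the 20 canonical amino acids; ambiguity codes (B, Z, X, J, U, O)
are rejected so that every residue can be embedded and scored.  The DNA
alphabet is {A, C, G, T}; N and other IUPAC codes are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

GAP = "-"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

ALPHABETS: dict[str, frozenset[str]] = {
    "protein20": frozenset(PROTEIN_ALPHABET),
    "dna4": frozenset(DNA_ALPHABET),
    "gapped-protein": frozenset(PROTEIN_ALPHABET + GAP),
    "gapped-dna": frozenset(DNA_ALPHABET + GAP),
}

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)


class SequenceError(ValueError):
    """Base class for sequence-level validation failures."""


class DuplicateIdError(SequenceError):
    pass


class AlphabetError(SequenceError):
    pass


class TranslationError(SequenceError):
    pass


class EmptyInputError(SequenceError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence over a declared alphabet.

    ``description`` carries the remainder of the FASTA header after the id
    token; it is preserved on output but takes no part in identity.
    """

    id: str
    residues: str
    alphabet: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if self.alphabet not in ALPHABETS:
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        validate_symbols(self.residues, self.alphabet, record_id=self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def with_residues(self, residues: str, alphabet: str | None = None) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=residues,
            alphabet=alphabet or self.alphabet,
            description=self.description,
        )


def validate_symbols(residues: str, alphabet: str, record_id: str = "?") -> None:
    allowed = ALPHABETS[alphabet]
    for pos, sym in enumerate(residues, start=1):
        if sym not in allowed:
            raise AlphabetError(
                f"record {record_id!r}: symbol {sym!r} at position {pos} "
                f"is not in alphabet {alphabet!r}"
            )


@dataclass
class MultipleAlignment:
    """A gapped multi-row alignment; all rows share one column count."""

    rows: list[SequenceRecord]
    column_count: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise SequenceError("alignment must have at least one row")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"rows have unequal lengths: {sorted(lengths)}")
        self.column_count = lengths.pop()
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("alignment rows carry duplicate ids")
        for c in range(self.column_count):
            if all(r.residues[c] == GAP for r in self.rows):
                raise SequenceError(f"column {c} consists entirely of gaps")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, record_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def column(self, c: int) -> str:
        return "".join(r.residues[c] for r in self.rows)


def read_fasta(path: str | Path, alphabet: str | None) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records, in file order.

    Ids are the header token up to the first whitespace; the remainder is
    kept as the description.  ``alphabet=None`` skips symbol validation
    (used by CDS validation, which reports alphabet failures itself) and
    tags records as raw DNA candidates.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        tokens = header.split(None, 1)
        rec_id = tokens[0] if tokens else ""
        if not rec_id:
            raise SequenceError(f"{path}: empty FASTA header")
        if rec_id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        residues = "".join(chunks).upper()
        desc = tokens[1].strip() if len(tokens) > 1 else ""
        if alphabet is None:
            records.append(
                _raw_record(rec_id, residues, desc)
            )
        else:
            records.append(
                SequenceRecord(id=rec_id, residues=residues, alphabet=alphabet, description=desc)
            )

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            chunks = []
        else:
            if header is None:
                raise SequenceError(f"{path}: sequence data before first header")
            chunks.append(line)
    flush()
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def _raw_record(rec_id: str, residues: str, desc: str) -> SequenceRecord:
    """Build a record bypassing alphabet validation (raw CDS candidates)."""
    rec = object.__new__(SequenceRecord)
    object.__setattr__(rec, "id", rec_id)
    object.__setattr__(rec, "residues", residues)
    object.__setattr__(rec, "alphabet", "raw")
    object.__setattr__(rec, "description", desc)
    return rec


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 60) -> None:
    if not records:
        raise EmptyInputError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("line width must be positive")
    lines: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header = f"{header} {rec.description}"
        lines.append(header)
        for start in range(0, len(rec.residues), width):
            lines.append(rec.residues[start : start + width])
        if not rec.residues:
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_alignment(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    write_fasta(msa.rows, path, width=width)


def translate(cds: SequenceRecord) -> SequenceRecord:
    """Translate a CDS with the standard genetic code (table 1).

    A trailing stop codon is stripped with a logged warning; an internal
    stop or a length not divisible by three is an error.
    """
    seq = cds.residues.upper()
    validate_symbols(seq, "dna4", record_id=cds.id)
    if len(seq) % 3 != 0:
        raise TranslationError(
            f"record {cds.id!r}: length {len(seq)} is not divisible by 3"
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        logger.warning("record %r: trailing stop codon %s stripped", cds.id, codons[-1])
        codons = codons[:-1]
    amino = []
    for idx, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise TranslationError(
                f"record {cds.id!r}: internal stop codon {codon} at codon {idx}"
            )
        amino.append(CODON_TO_AA[codon])
    return SequenceRecord(
        id=cds.id, residues="".join(amino), alphabet="protein20", description=cds.description
    )


def records_to_alignment(records: Iterable[SequenceRecord], alphabet: str) -> MultipleAlignment:
    rows = [r if r.alphabet == alphabet else r.with_residues(r.residues, alphabet) for r in records]
    return MultipleAlignment(rows=rows)
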