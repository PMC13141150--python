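"""Codon-aware alignment: validate CDS, align in protein space, back-map.

Validation applies, in order: (i) length divisible by three, (ii) no
internal stop codon, (iii) canonical A/C/G/T alphabet; the first failure
is reported per sequence and failing sequences are excluded (the run
proceeds while at least two survive).  A trailing stop codon is noted,
stripped before translation, and excluded from the nucleotide output so
every aligned residue maps 1:1 to an original codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align_core import GapPenalties
from .embeddings import EmbeddingProvider
from .progressive import progressive_align
from .scoring import Backend
from .seq_io import (
    DNA_ALPHABET,
    GAP,
    STOP_CODONS,
    MultipleAlignment,
    SequenceRecord,
    translate,
)

logger = logging.getLogger(__name__)


class CodonModeError(ValueError):
    pass


@dataclass(frozen=True)
class CdsStatus:
    id: str
    accepted: bool
    reason: str | None = None  # "frame" | "internal-stop" | "alphabet"
    position: int | None = None  # codon index or nucleotide position (1-based)
    trailing_stop: bool = False


@dataclass
class CdsValidationReport:
    statuses: list[CdsStatus] = field(default_factory=list)

    def accepted_ids(self) -> list[str]:
        return [s.id for s in self.statuses if s.accepted]

    def rejected(self) -> list[CdsStatus]:
        return [s for s in self.statuses if not s.accepted]

    def status(self, rec_id: str) -> CdsStatus:
        for s in self.statuses:
            if s.id == rec_id:
                return s
        raise KeyError(rec_id)

    def to_tsv(self) -> str:
        lines = ["id\tstatus\treason\tposition\ttrailing_stop"]
        for s in self.statuses:
            lines.append(
                "\t".join(
                    [
                        s.id,
                        "accepted" if s.accepted else "rejected",
                        s.reason or ".",
                        str(s.position) if s.position is not None else ".",
                        "yes" if s.trailing_stop else "no",
                    ]
                )
            )
        return "\n".join(lines) + "\n"


_DNA_SET = frozenset(DNA_ALPHABET)


def _validate_one(rec: SequenceRecord) -> CdsStatus:
    seq = rec.residues.upper()
    if len(seq) == 0 or len(seq) % 3 != 0:
        return CdsStatus(id=rec.id, accepted=False, reason="frame")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    trailing = codons[-1] in STOP_CODONS
    for idx, codon in enumerate(codons[:-1], start=1):
        if codon in STOP_CODONS:
            return CdsStatus(
                id=rec.id, accepted=False, reason="internal-stop", position=idx,
                trailing_stop=trailing,
            )
    for pos, sym in enumerate(seq, start=1):
        if sym not in _DNA_SET:
            return CdsStatus(
                id=rec.id, accepted=False, reason="alphabet", position=pos,
                trailing_stop=trailing,
            )
    return CdsStatus(id=rec.id, accepted=True, trailing_stop=trailing)


def validate_cds(records: list[SequenceRecord]) -> CdsValidationReport:
    report = CdsValidationReport()
    for rec in records:
        status = _validate_one(rec)
        if not status.accepted:
            logger.warning(
                "CDS %r rejected: %s%s",
                rec.id,
                status.reason,
                f" (position {status.position})" if status.position else "",
            )
        report.statuses.append(status)
    if not report.accepted_ids():
        raise CodonModeError("all CDS records failed validation; nothing to align")
    return report


def backmap(
    protein_msa: MultipleAlignment, originals: dict[str, SequenceRecord]
) -> MultipleAlignment:
    """Project a protein alignment back to codon space.

    Each residue is replaced by its original codon verbatim; each protein
    gap expands to '---'.  A trailing stop codon in the CDS is dropped to
    match the translated protein.
    """
    nuc_rows = []
    for row in protein_msa.rows:
        if row.id not in originals:
            raise CodonModeError(f"no CDS supplied for aligned row {row.id!r}")
        cds = originals[row.id].residues.upper()
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        ungapped = row.ungapped()
        if len(codons) != len(ungapped):
            raise CodonModeError(
                f"row {row.id!r}: aligned protein has {len(ungapped)} residues "
                f"but CDS supplies {len(codons)} codons"
            )
        translated = translate(originals[row.id].with_residues(cds, "dna4")).residues
        if translated != ungapped:
            raise CodonModeError(
                f"row {row.id!r}: aligned protein does not match the CDS translation"
            )
        pieces = []
        k = 0
        for sym in row.residues:
            if sym == GAP:
                pieces.append("---")
            else:
                pieces.append(codons[k])
                k += 1
        nuc_rows.append(
            SequenceRecord(
                id=row.id,
                residues="".join(pieces),
                alphabet="gapped-dna",
                description=row.description,
            )
        )
    return MultipleAlignment(rows=nuc_rows)


def codon_align(
    cds_records: list[SequenceRecord],
    provider: EmbeddingProvider,
    backend: Backend,
    penalties: GapPenalties,
    policy: str = "upgma",
    order_seed: int | None = None,
    codon_gap_scale: float = 1.0,
    profiler=None,
) -> tuple[MultipleAlignment, MultipleAlignment, CdsValidationReport]:
    """Full codon pipeline: validate -> translate -> align -> back-map."""
    report = validate_cds(cds_records)
    accepted = [r for r in cds_records if report.status(r.id).accepted]
    if len(accepted) < 2:
        raise CodonModeError(
            f"only {len(accepted)} CDS passed validation; need at least 2"
        )
    clean = [r.with_residues(r.residues.upper(), "dna4") for r in accepted]
    proteins = [translate(r) for r in clean]
    if profiler is not None:
        with profiler.phase("embedding"):
            embs = [provider.embed(p) for p in proteins]
    else:
        embs = [provider.embed(p) for p in proteins]
    scaled = penalties.scaled(codon_gap_scale)
    protein_msa = progressive_align(
        proteins,
        embs,
        backend,
        scaled,
        policy=policy,
        order_seed=order_seed,
        profiler=profiler,
    )
    nuc_msa = backmap(protein_msa, {r.id: r for r in clean})
    return protein_msa, nuc_msa, report
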