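"""Codon-level consequence calls and cross-species conservation.

A variant on a transcript is mapped to its codon through the annotated CDS
start, translated with the standard nuclear genetic code, and classified as
synonymous, missense, nonsense, stop-loss, or noncoding (outside the CDS).
A companion helper extracts one alignment column from a protein multiple
alignment and scores how conserved the reference residue is across
orthologues — the evidence used to argue that a candidate substitution is
damaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .variant_io import PooledVariant, TranscriptModel

STOP = "*"
GAP_CHARS = frozenset("-.")

#: consequence classes that alter the protein sequence
NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense", "stop_loss"})


class DataIntegrityError(ValueError):
    """Variant contradicts its transcript (e.g. ref base mismatch)."""


@dataclass(frozen=True)
class ConsequenceCall:
    """Codon-level annotation of one variant.

    ``codon_index`` is the 1-based codon number within the CDS; the codon
    and amino-acid fields are ``None`` for noncoding calls.
    """

    variant_id: str
    consequence_class: str
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence_class in NONSYNONYMOUS_CLASSES


@dataclass(frozen=True)
class ConservationColumn:
    """One alignment column scored against the reference residue.

    Gap characters are excluded from the denominator, so five sequences of
    which one is gapped score unanimity over the remaining four.
    """

    reference_name: str
    reference_residue: str
    residues: Mapping[str, str]
    conserved_fraction: float
    is_conserved: bool


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code ('*' for stop)."""
    if len(codon) != 3:
        raise ValueError(f"codon {codon!r} is not a triplet")
    return str(Seq(codon).translate())


def classify(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == STOP:
        return "nonsense"
    if ref_aa == STOP:
        return "stop_loss"
    return "missense"


def call_consequence(
    variant: PooledVariant, transcript: TranscriptModel
) -> ConsequenceCall:
    """Annotate a single-base variant against its transcript ORF.

    The variant's ref allele must match the cDNA base at its position;
    a mismatch raises :class:`DataIntegrityError` naming the variant.
    Positions outside the CDS are classified ``noncoding``.
    """
    if variant.transcript_id != transcript.transcript_id:
        raise ValueError(
            f"{variant.variant_id}: variant transcript {variant.transcript_id!r} "
            f"does not match {transcript.transcript_id!r}"
        )
    pos = variant.position
    if pos > len(transcript.cdna):
        raise DataIntegrityError(
            f"{variant.variant_id}: position {pos} beyond cDNA length "
            f"{len(transcript.cdna)}"
        )
    cdna_base = transcript.cdna[pos - 1]
    if cdna_base != variant.ref:
        raise DataIntegrityError(
            f"{variant.variant_id}: ref allele {variant.ref} does not match "
            f"cDNA base {cdna_base} at position {pos} of {transcript.transcript_id}"
        )
    if pos < transcript.cds_start or pos > transcript.cds_end:
        return ConsequenceCall(variant.variant_id, "noncoding")

    offset = pos - transcript.cds_start
    codon_index = offset // 3 + 1
    within = offset % 3
    cds = transcript.cds
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]
    alt_codon = ref_codon[:within] + variant.alt + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    return ConsequenceCall(
        variant_id=variant.variant_id,
        consequence_class=classify(ref_aa, alt_aa),
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def annotate_variants(
    variants: Iterable[PooledVariant],
    transcripts: Mapping[str, TranscriptModel],
) -> dict[str, ConsequenceCall]:
    """Annotate many variants, keyed by variant id."""
    calls: dict[str, ConsequenceCall] = {}
    for variant in variants:
        try:
            transcript = transcripts[variant.transcript_id]
        except KeyError:
            raise DataIntegrityError(
                f"{variant.variant_id}: transcript {variant.transcript_id!r} unknown"
            ) from None
        calls[variant.variant_id] = call_consequence(variant, transcript)
    return calls


def conservation_at(
    alignment,
    reference_name: str,
    residue_position: int,
    conserved_threshold: float = 1.0,
) -> ConservationColumn:
    """Score conservation of one reference residue across an alignment.

    ``alignment`` is any iterable of records with ``id`` and ``seq``
    attributes (a Biopython ``MultipleSeqAlignment`` works directly).
    ``residue_position`` is 1-based in the *ungapped* reference sequence;
    reference gap columns are skipped when locating it.
    """
    records = {str(rec.id): str(rec.seq) for rec in alignment}
    if reference_name not in records:
        raise ValueError(f"reference sequence {reference_name!r} not in alignment")
    if residue_position < 1:
        raise ValueError("residue_position must be >= 1")
    reference = records[reference_name]
    seen = 0
    column = None
    for col, char in enumerate(reference):
        if char in GAP_CHARS:
            continue
        seen += 1
        if seen == residue_position:
            column = col
            break
    if column is None:
        raise ValueError(
            f"residue position {residue_position} beyond ungapped length {seen} "
            f"of reference {reference_name!r}"
        )
    reference_residue = reference[column]
    residues = {name: seq[column] for name, seq in records.items()}
    informative = [r for r in residues.values() if r not in GAP_CHARS]
    matches = sum(1 for r in informative if r == reference_residue)
    fraction = matches / len(informative)
    return ConservationColumn(
        reference_name=reference_name,
        reference_residue=reference_residue,
        residues=residues,
        conserved_fraction=fraction,
        is_conserved=fraction >= conserved_threshold,
    )


def write_consequence_table(
    calls: Mapping[str, ConsequenceCall],
    path,
    conservation: Mapping[str, float] | None = None,
) -> None:
    """Write a consequence TSV; conservation column filled where provided."""
    from pathlib import Path

    columns = [
        "variant_id", "codon_index", "ref_codon", "alt_codon",
        "ref_aa", "alt_aa", "class", "conserved_fraction",
    ]
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("\t".join(columns) + "\n")
        for variant_id in calls:
            call = calls[variant_id]
            cons = "" if conservation is None else conservation.get(variant_id, "")
            fields = [
                variant_id,
                call.codon_index if call.codon_index is not None else "",
                call.ref_codon or "",
                call.alt_codon or "",
                call.ref_aa or "",
                call.alt_aa or "",
                call.consequence_class,
                cons,
            ]
            handle.write("\t".join(str(f) for f in fields) + "\n")
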