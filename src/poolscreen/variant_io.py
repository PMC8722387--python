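"""Readers and writers for the screening pipeline's on-disk formats.

Three formats are handled here:

* the **pooled-variant table**, a flat UTF-8 TSV with one row per biallelic
  transcript variant and per-pool ref/alt read counts for the wild-type
  (WT), mutant (MUT) and phenotypically normal sibling (SIB) pools;
* **transcript models**: a cDNA FASTA plus a sidecar TSV giving the 1-based
  inclusive CDS bounds on each transcript;
* a **VCF v4.3 export** of variants with per-pool allelic depths.

All coordinates in the package are 1-based inclusive on the transcript's own
forward orientation; de novo transcripts have no genomic strand, so no
coordinate shifts or strand flips happen anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

POOL_LABELS = ("WT", "MUT", "SIB")
_BASES = frozenset("ACGT")

TABLE_COLUMNS = [
    "variant_id",
    "transcript_id",
    "position",
    "ref",
    "alt",
    "wt_ref",
    "wt_alt",
    "mut_ref",
    "mut_alt",
    "sib_ref",
    "sib_alt",
]

CDS_SIDECAR_COLUMNS = ["transcript_id", "cds_start", "cds_end"]

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class VariantTableError(ValueError):
    """Malformed pooled-variant table (names the offending line)."""


class TranscriptError(ValueError):
    """Invalid transcript model or FASTA/sidecar mismatch."""


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic site on a transcript with per-pool read counts.

    ``counts`` maps each pool label in :data:`POOL_LABELS` to a
    ``(ref_reads, alt_reads)`` pair. Zero counts are legal; missing pools
    are not.
    """

    variant_id: str
    transcript_id: str
    position: int
    ref: str
    alt: str
    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if allele not in _BASES:
                raise ValueError(
                    f"{self.variant_id}: {name} allele {allele!r} is not one of A/C/G/T"
                )
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        missing = [p for p in POOL_LABELS if p not in self.counts]
        if missing:
            raise ValueError(f"{self.variant_id}: missing pool counts for {missing}")
        unknown = [p for p in self.counts if p not in POOL_LABELS]
        if unknown:
            raise ValueError(f"{self.variant_id}: unknown pool labels {unknown}")
        for pool, (ref_reads, alt_reads) in self.counts.items():
            if ref_reads < 0 or alt_reads < 0:
                raise ValueError(
                    f"{self.variant_id}: negative read count in pool {pool}"
                )

    def total(self, pool: str) -> int:
        ref_reads, alt_reads = self.counts[pool]
        return ref_reads + alt_reads


@dataclass(frozen=True)
class TranscriptModel:
    """A de novo transcript: cDNA sequence plus CDS bounds.

    ``cds_start``/``cds_end`` are 1-based inclusive on the cDNA. By default
    the CDS must start with ATG and end with a stop codon; set
    ``require_orf=False`` in :func:`validate_transcript` (or when building
    models for partial ORFs) to relax that.
    """

    transcript_id: str
    cdna: str
    cds_start: int
    cds_end: int

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start - 1 : self.cds_end]


def validate_transcript(model: TranscriptModel, require_orf: bool = True) -> TranscriptModel:
    tid = model.transcript_id
    n = len(model.cdna)
    if not tid:
        raise TranscriptError("transcript_id must be non-empty")
    if set(model.cdna) - _BASES:
        bad = sorted(set(model.cdna) - _BASES)
        raise TranscriptError(f"{tid}: cDNA contains non-ACGT characters {bad}")
    if not (1 <= model.cds_start < model.cds_end <= n):
        raise TranscriptError(
            f"{tid}: CDS bounds [{model.cds_start}, {model.cds_end}] out of range "
            f"for cDNA of length {n}"
        )
    cds_len = model.cds_end - model.cds_start + 1
    if cds_len % 3 != 0:
        raise TranscriptError(f"{tid}: CDS length {cds_len} is not divisible by 3")
    if require_orf:
        cds = model.cds
        if not cds.startswith("ATG"):
            raise TranscriptError(f"{tid}: CDS does not begin with ATG")
        if cds[-3:] not in _STOP_CODONS:
            raise TranscriptError(f"{tid}: CDS does not end at a stop codon")
    return model


def read_variant_table(path: str | Path) -> list[PooledVariant]:
    """Parse a pooled-variant TSV, preserving row order.

    Raises :class:`VariantTableError` naming the offending line for a bad
    header, non-integer or negative counts, duplicate variant ids, or a
    wrong column count.
    """
    path = Path(path)
    variants: list[PooledVariant] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != TABLE_COLUMNS:
            raise VariantTableError(
                f"{path}: line 1: bad header {header!r}; expected {TABLE_COLUMNS!r}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(TABLE_COLUMNS):
                raise VariantTableError(
                    f"{path}: line {lineno}: expected {len(TABLE_COLUMNS)} fields, "
                    f"found {len(fields)}"
                )
            row = dict(zip(TABLE_COLUMNS, fields))
            try:
                position = int(row["position"])
                numbers = {
                    key: int(row[key])
                    for key in (
                        "wt_ref", "wt_alt", "mut_ref", "mut_alt", "sib_ref", "sib_alt",
                    )
                }
            except ValueError as exc:
                raise VariantTableError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if row["variant_id"] in seen:
                raise VariantTableError(
                    f"{path}: line {lineno}: duplicate variant_id {row['variant_id']!r}"
                )
            try:
                variant = PooledVariant(
                    variant_id=row["variant_id"],
                    transcript_id=row["transcript_id"],
                    position=position,
                    ref=row["ref"],
                    alt=row["alt"],
                    counts={
                        "WT": (numbers["wt_ref"], numbers["wt_alt"]),
                        "MUT": (numbers["mut_ref"], numbers["mut_alt"]),
                        "SIB": (numbers["sib_ref"], numbers["sib_alt"]),
                    },
                )
            except ValueError as exc:
                raise VariantTableError(f"{path}: line {lineno}: {exc}") from None
            seen.add(variant.variant_id)
            variants.append(variant)
    return variants


def write_variant_table(variants: Iterable[PooledVariant], path: str | Path) -> None:
    """Write variants in the flat TSV dialect (explicit zeros, no quoting)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(TABLE_COLUMNS) + "\n")
        for v in variants:
            wt, mut, sib = v.counts["WT"], v.counts["MUT"], v.counts["SIB"]
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        v.variant_id, v.transcript_id, v.position, v.ref, v.alt,
                        wt[0], wt[1], mut[0], mut[1], sib[0], sib[1],
                    )
                )
                + "\n"
            )


def read_transcripts(
    fasta_path: str | Path,
    cds_sidecar_path: str | Path,
    require_orf: bool = True,
) -> dict[str, TranscriptModel]:
    """Load transcript models from a FASTA plus CDS-bounds sidecar TSV.

    Sequences are upper-cased and U is normalised to T. Every sidecar row
    must reference a FASTA id; transcripts without a sidecar row are
    rejected (every transcript needs CDS bounds downstream).
    """
    fasta_path, cds_sidecar_path = Path(fasta_path), Path(cds_sidecar_path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise TranscriptError(f"{fasta_path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq).upper().replace("U", "T")

    models: dict[str, TranscriptModel] = {}
    with cds_sidecar_path.open(encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != CDS_SIDECAR_COLUMNS:
            raise TranscriptError(
                f"{cds_sidecar_path}: bad header {header!r}; expected {CDS_SIDECAR_COLUMNS!r}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TranscriptError(
                    f"{cds_sidecar_path}: line {lineno}: expected 3 fields"
                )
            tid, start_s, end_s = fields
            if tid not in sequences:
                raise TranscriptError(
                    f"{cds_sidecar_path}: line {lineno}: transcript id {tid!r} "
                    "absent from FASTA"
                )
            if tid in models:
                raise TranscriptError(
                    f"{cds_sidecar_path}: line {lineno}: duplicate transcript id {tid!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TranscriptError(
                    f"{cds_sidecar_path}: line {lineno}: non-integer CDS bounds"
                ) from None
            models[tid] = validate_transcript(
                TranscriptModel(tid, sequences[tid], start, end), require_orf=require_orf
            )
    missing = sorted(set(sequences) - set(models))
    if missing:
        raise TranscriptError(f"transcripts without CDS sidecar rows: {missing}")
    return models


def write_transcripts(
    transcripts: Mapping[str, TranscriptModel],
    fasta_path: str | Path,
    cds_sidecar_path: str | Path,
) -> None:
    with Path(fasta_path).open("w", encoding="utf-8") as handle:
        for tid in transcripts:
            model = transcripts[tid]
            handle.write(f">{tid}\n")
            seq = model.cdna
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
    with Path(cds_sidecar_path).open("w", encoding="utf-8") as handle:
        handle.write("\t".join(CDS_SIDECAR_COLUMNS) + "\n")
        for tid in transcripts:
            model = transcripts[tid]
            handle.write(f"{tid}\t{model.cds_start}\t{model.cds_end}\n")


def write_vcf(
    variants: Iterable[PooledVariant],
    transcripts: Mapping[str, TranscriptModel],
    path: str | Path,
) -> None:
    """Export variants as VCF v4.3 with AD sample fields for WT/MUT/SIB.

    CHROM is the transcript id and POS the transcript coordinate (both
    conventions are 1-based, so no shift is applied).
    """
    variants = list(variants)
    missing = sorted({v.transcript_id for v in variants} - set(transcripts))
    if missing:
        raise TranscriptError(f"variants reference missing transcripts: {missing}")
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("##fileformat=VCFv4.3\n")
        handle.write('##source=poolscreen\n')
        used = sorted({v.transcript_id for v in variants})
        for tid in used:
            handle.write(f"##contig=<ID={tid},length={len(transcripts[tid].cdna)}>\n")
        handle.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tWT\tMUT\tSIB\n"
        )
        for v in variants:
            samples = "\t".join(
                f"{v.counts[pool][0]},{v.counts[pool][1]}" for pool in POOL_LABELS
            )
            handle.write(
                f"{v.transcript_id}\t{v.position}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                f"\t.\t.\t.\tAD\t{samples}\n"
            )
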