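"""Simulation of a pooled RNA-seq screen in a selfing isogenic line.

The model mirrors the study design the screening cascade assumes: a single
self-fertilizing F1 parent heterozygous for one recessive lethal ENU allele
produces an F2 clutch; embryos are sorted by phenotype into a mutant pool
(homozygous for the causal allele) and a sibling pool (hom-ref or het, in
expected ratio 1:2), each of ``n_embryos_per_pool`` embryos; an unmutagenized
wild-type pool of the parental strain is sequenced alongside. Because the
strain is near-isogenic, the only segregating sites are the causal mutation,
other ENU-induced variants, and a tiny residual-heterozygosity fraction of
strain polymorphism.

Pools are sequenced at the allele-count level: per site and pool, depth is
drawn from a negative binomial (overdispersed, as for RNA-seq coverage) and
the alt read count from a binomial whose success probability is the pool's
expression-weighted alt-allele dosage, perturbed by a symmetric per-read
allele miscall rate. Read-level artefacts (FASTQ, alignment, assembly) are
deliberately not modelled.

Everything is driven by one seeded generator: identical ``(model, seed)``
pairs give byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import consequence as _consequence
from .variant_io import PooledVariant, TranscriptModel, validate_transcript

GENOTYPES = ("hom_ref", "het", "hom_alt")
#: selfing of a heterozygote: hom_ref : het : hom_alt
SELFING_PROBS = (0.25, 0.5, 0.25)
#: genotype distribution among phenotypically normal siblings (not hom_alt)
SIBLING_PROBS = (1.0 / 3.0, 2.0 / 3.0, 0.0)

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ("TAA", "TAG", "TGA")


class ConfigurationError(ValueError):
    """Invalid cross model or founder configuration."""


@dataclass(frozen=True)
class CausalAllele:
    """The planted recessive mutation, in transcript coordinates."""

    transcript_id: str
    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CrossModel:
    """Parameters of the simulated selfing cross and pooled sequencing.

    Parameters
    ----------
    seed
        Mandatory seed for the pseudo-random stream; there is no silent
        clock seeding.
    n_embryos_per_pool
        Embryos pooled per phenotype group (20 in the emulated design).
    n_background_variants
        Non-causal variants (ENU-induced plus residual strain
        polymorphism) segregating in the mutagenized lineage.
    residual_het_rate
        Probability a background site is residual strain polymorphism,
        heterozygous in both the wild-type strain and the mutant lineage
        (models the ~0.03% non-isogenic fraction of the inbred genome).
    enu_het_rate
        Probability a background site is an ENU-induced variant still
        heterozygous in the F1 founder; remaining background sites are
        fixed in the mutant lineage, split evenly hom-ref/hom-alt relative
        to the wild-type strain.
    depth_mean, depth_dispersion
        Negative-binomial read depth per site per pool: variance
        ``m + m^2/k``; large ``depth_dispersion`` approaches Poisson.
    seq_error_rate
        Per-read probability of miscalling the allele, applied as a
        symmetric biallelic flip (third alleles are not modelled).
    expression_cv
        Coefficient of variation of per-embryo expression weights
        (gamma-distributed, mean 1). 0 means equal expression across
        embryos, the default model for expression-weighted allele dosage.
    transcript_mean_variants
        Average number of variants placed per synthetic transcript
        (controls how many transcripts are generated).
    causal_allele
        Explicit placement of the causal mutation; when ``None`` a missense
        site is chosen automatically on the first transcript.
    """

    seed: int
    n_embryos_per_pool: int = 20
    n_background_variants: int = 5000
    residual_het_rate: float = 3e-4
    enu_het_rate: float = 0.2
    depth_mean: float = 50.0
    depth_dispersion: float = 10.0
    seq_error_rate: float = 0.005
    expression_cv: float = 0.0
    transcript_mean_variants: float = 10.0
    causal_allele: CausalAllele | None = None

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        if self.n_embryos_per_pool < 1:
            raise ConfigurationError("n_embryos_per_pool must be >= 1")
        if self.n_background_variants < 0:
            raise ConfigurationError("n_background_variants must be >= 0")
        for name in ("residual_het_rate", "enu_het_rate", "seq_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.residual_het_rate + self.enu_het_rate > 1.0:
            raise ConfigurationError(
                "residual_het_rate + enu_het_rate must not exceed 1"
            )
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ConfigurationError("depth_dispersion must be > 0")
        if self.expression_cv < 0:
            raise ConfigurationError("expression_cv must be >= 0")
        if self.transcript_mean_variants <= 0:
            raise ConfigurationError("transcript_mean_variants must be > 0")


@dataclass(frozen=True)
class VariantSite:
    """A placed variant before sequencing: alleles plus founder genotypes."""

    variant_id: str
    transcript_id: str
    position: int
    ref: str
    alt: str
    origin: str  # causal | residual_het | enu_het | enu_hom_ref | enu_hom_alt
    founder_genotype: str  # genotype in the mutagenized F1 founder
    wt_strain_genotype: str  # genotype in the unmutagenized strain

    @property
    def is_causal(self) -> bool:
        return self.origin == "causal"


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for one simulated dataset.

    Genotype matrices hold per-embryo alt-allele dosage (0/1/2), one row
    per variant site (same order as ``sites``), one column per embryo.
    ``expected_alt_fraction`` holds the analytic expectation of each pool's
    alt-allele fraction given the founder genotypes (not the realised
    draw).
    """

    sites: tuple[VariantSite, ...]
    causal_id: str
    wt_genotypes: np.ndarray
    mut_genotypes: np.ndarray
    sib_genotypes: np.ndarray
    expected_alt_fraction: Mapping[str, np.ndarray]  # pool label -> vector

    def __post_init__(self) -> None:
        causal = [s for s in self.sites if s.is_causal]
        if len(causal) != 1 or causal[0].variant_id != self.causal_id:
            raise ValueError("truth set must flag exactly one causal variant")

    @property
    def causal_index(self) -> int:
        return next(i for i, s in enumerate(self.sites) if s.is_causal)


@dataclass(frozen=True)
class SimulatedDataset:
    variants: list[PooledVariant]
    transcripts: dict[str, TranscriptModel]
    truth: TruthSet


def segregate_selfing(
    founder_genotype: str, n_offspring: int, rng: np.random.Generator
) -> list[str]:
    """Draw selfed offspring of a heterozygous founder (1:2:1 segregation).

    The screen design assumes the F1 parent is heterozygous at the causal
    site; any other founder genotype is a configuration error.
    """
    if founder_genotype != "het":
        raise ConfigurationError(
            f"selfing segregation requires a heterozygous founder, got "
            f"{founder_genotype!r}"
        )
    if n_offspring < 0:
        raise ConfigurationError("n_offspring must be >= 0")
    if n_offspring == 0:
        return []
    draws = rng.choice(3, size=n_offspring, p=SELFING_PROBS)
    return [GENOTYPES[i] for i in draws]


def make_transcripts(
    rng: np.random.Generator,
    n_transcripts: int,
    cds_codons: tuple[int, int] = (120, 360),
    utr5: tuple[int, int] = (20, 60),
    utr3: tuple[int, int] = (30, 120),
) -> dict[str, TranscriptModel]:
    """Generate random transcripts with valid ORFs (ATG ... stop)."""
    transcripts: dict[str, TranscriptModel] = {}
    for i in range(n_transcripts):
        tid = f"tx{i + 1:05d}"
        n_codons = int(rng.integers(cds_codons[0], cds_codons[1] + 1))
        len5 = int(rng.integers(utr5[0], utr5[1] + 1))
        len3 = int(rng.integers(utr3[0], utr3[1] + 1))
        interior = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
        stop = _STOP_CODONS[int(rng.integers(3))]
        cds = "ATG" + "".join(_SENSE_CODONS[j] for j in interior) + stop
        seq5 = "".join(rng.choice(_BASES, size=len5))
        seq3 = "".join(rng.choice(_BASES, size=len3))
        model = TranscriptModel(tid, seq5 + cds + seq3, len5 + 1, len5 + len(cds))
        transcripts[tid] = validate_transcript(model)
    return transcripts


def _pick_missense_site(
    transcript: TranscriptModel, rng: np.random.Generator
) -> CausalAllele:
    """Choose a position/alt on the transcript whose substitution is missense."""
    cds_positions = rng.permutation(
        np.arange(transcript.cds_start + 3, transcript.cds_end - 2)
    )
    for pos in cds_positions:
        pos = int(pos)
        ref = transcript.cdna[pos - 1]
        offset = pos - transcript.cds_start
        codon_index = offset // 3
        within = offset % 3
        ref_codon = transcript.cds[codon_index * 3 : codon_index * 3 + 3]
        for alt in rng.permutation([b for b in "ACGT" if b != ref]):
            alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
            ref_aa = _consequence.translate_codon(ref_codon)
            alt_aa = _consequence.translate_codon(alt_codon)
            if _consequence.classify(ref_aa, alt_aa) == "missense":
                return CausalAllele(transcript.transcript_id, pos, ref, str(alt))
    raise ConfigurationError(
        f"no missense site available on {transcript.transcript_id}"
    )


def place_variants(
    transcripts: Mapping[str, TranscriptModel],
    model: CrossModel,
    rng: np.random.Generator,
) -> tuple[VariantSite, ...]:
    """Place the causal variant and background variants on the transcripts.

    Background sites draw an origin class: residual strain polymorphism
    (het in both lineages), ENU-induced still-heterozygous, or ENU-induced
    fixed (hom-ref or hom-alt relative to the wild-type strain, evenly
    split). Sites are unique per (transcript, position); output is sorted
    by (transcript_id, position) and ids are assigned in that order.
    """
    tids = list(transcripts)
    if model.causal_allele is not None:
        causal = model.causal_allele
        if causal.transcript_id not in transcripts:
            raise ConfigurationError(
                f"causal transcript {causal.transcript_id!r} not in transcripts"
            )
        tx = transcripts[causal.transcript_id]
        if not 1 <= causal.position <= len(tx.cdna):
            raise ConfigurationError("causal position outside its transcript")
        if tx.cdna[causal.position - 1] != causal.ref:
            raise ConfigurationError(
                f"causal ref {causal.ref!r} does not match transcript base "
                f"{tx.cdna[causal.position - 1]!r} at position {causal.position}"
            )
    else:
        causal = _pick_missense_site(transcripts[tids[0]], rng)

    lengths = np.array([len(transcripts[t].cdna) for t in tids])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    if model.n_background_variants > total - 1:
        raise ConfigurationError(
            "not enough transcript positions for the requested variant count"
        )
    causal_tx_index = tids.index(causal.transcript_id)
    causal_flat = int(offsets[causal_tx_index]) + causal.position - 1

    flat = rng.choice(total, size=model.n_background_variants + 1, replace=False)
    flat = [f for f in flat if f != causal_flat][: model.n_background_variants]

    u = rng.random(model.n_background_variants)
    hom_alt_bit = rng.random(model.n_background_variants) < 0.5
    alt_choice = rng.integers(3, size=model.n_background_variants)

    raw: list[tuple[str, int, str, str, str]] = []
    for i, f in enumerate(flat):
        tx_index = int(np.searchsorted(offsets, f, side="right")) - 1
        tid = tids[tx_index]
        pos = int(f - offsets[tx_index]) + 1
        ref = transcripts[tid].cdna[pos - 1]
        alt = [b for b in "ACGT" if b != ref][int(alt_choice[i])]
        if u[i] < model.residual_het_rate:
            origin = "residual_het"
        elif u[i] < model.residual_het_rate + model.enu_het_rate:
            origin = "enu_het"
        else:
            origin = "enu_hom_alt" if hom_alt_bit[i] else "enu_hom_ref"
        raw.append((tid, pos, ref, alt, origin))
    raw.append((causal.transcript_id, causal.position, causal.ref, causal.alt, "causal"))

    founder_by_origin = {
        "causal": "het",
        "residual_het": "het",
        "enu_het": "het",
        "enu_hom_ref": "hom_ref",
        "enu_hom_alt": "hom_alt",
    }
    wt_by_origin = {
        "causal": "hom_ref",
        "residual_het": "het",
        "enu_het": "hom_ref",
        "enu_hom_ref": "hom_ref",
        "enu_hom_alt": "hom_ref",
    }
    raw.sort(key=lambda r: (r[0], r[1]))
    sites = tuple(
        VariantSite(
            variant_id=f"v{i + 1:06d}",
            transcript_id=tid,
            position=pos,
            ref=ref,
            alt=alt,
            origin=origin,
            founder_genotype=founder_by_origin[origin],
            wt_strain_genotype=wt_by_origin[origin],
        )
        for i, (tid, pos, ref, alt, origin) in enumerate(raw)
    )
    return sites


_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2}


def _segregate_matrix(
    founder: np.ndarray,
    n_embryos: int,
    rng: np.random.Generator,
    probs: Sequence[float] = SELFING_PROBS,
) -> np.ndarray:
    """Per-embryo offspring dosages; het founder rows segregate, hom rows fix."""
    n = founder.shape[0]
    geno = np.repeat(founder[:, None], n_embryos, axis=1)
    het_rows = np.flatnonzero(founder == 1)
    if het_rows.size:
        draws = rng.choice(
            np.array([0, 1, 2]), size=(het_rows.size, n_embryos), p=list(probs)
        )
        geno[het_rows, :] = draws
    return geno


def build_pools(
    model: CrossModel,
    sites: Sequence[VariantSite],
    rng: np.random.Generator,
) -> TruthSet:
    """Draw embryo genotypes for the WT, mutant and sibling pools.

    The mutant pool is conditioned hom-alt at the causal site and the
    sibling pool conditioned not-hom-alt (hom-ref:het in expected ratio
    1:2); background sites segregate independently per embryo. The WT pool
    segregates only at residual-polymorphism sites.
    """
    n = len(sites)
    n_embryos = model.n_embryos_per_pool
    founder = np.array([_DOSAGE[s.founder_genotype] for s in sites])
    wt_founder = np.array([_DOSAGE[s.wt_strain_genotype] for s in sites])
    causal_index = next(i for i, s in enumerate(sites) if s.is_causal)
    if founder[causal_index] != 1:
        raise ConfigurationError("F1 founder must be heterozygous at the causal site")

    wt_geno = _segregate_matrix(wt_founder, n_embryos, rng)
    mut_geno = _segregate_matrix(founder, n_embryos, rng)
    sib_geno = _segregate_matrix(founder, n_embryos, rng)
    # phenotype conditioning at the causal site
    mut_geno[causal_index, :] = 2
    sib_geno[causal_index, :] = rng.choice(
        np.array([0, 1, 2]), size=n_embryos, p=list(SIBLING_PROBS)
    )

    expected = {
        "WT": wt_founder / 2.0,
        "MUT": founder / 2.0,
        "SIB": founder / 2.0,
    }
    expected["MUT"] = expected["MUT"].copy()
    expected["SIB"] = expected["SIB"].copy()
    expected["MUT"][causal_index] = 1.0
    expected["SIB"][causal_index] = 1.0 / 3.0

    return TruthSet(
        sites=tuple(sites),
        causal_id=sites[causal_index].variant_id,
        wt_genotypes=wt_geno,
        mut_genotypes=mut_geno,
        sib_genotypes=sib_geno,
        expected_alt_fraction=expected,
    )


def sequence_pools(
    truth: TruthSet, model: CrossModel, rng: np.random.Generator
) -> list[PooledVariant]:
    """Draw per-pool read counts for every site.

    Depth per site and pool is negative binomial ``(depth_mean,
    depth_dispersion)``; the alt count is binomial with success probability
    equal to the pool's expression-weighted alt dosage after the symmetric
    allele-miscall adjustment ``p = q(1-e) + (1-q)e``.
    """
    k = model.depth_dispersion
    m = model.depth_mean
    nb_p = k / (k + m)
    e = model.seq_error_rate
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    genotypes = {
        "WT": truth.wt_genotypes,
        "MUT": truth.mut_genotypes,
        "SIB": truth.sib_genotypes,
    }
    n_sites = len(truth.sites)
    for pool in ("WT", "MUT", "SIB"):
        geno = genotypes[pool]
        n_embryos = geno.shape[1]
        if model.expression_cv > 0:
            shape = 1.0 / model.expression_cv**2
            weights = rng.gamma(shape, 1.0 / shape, size=n_embryos)
        else:
            weights = np.ones(n_embryos)
        q = (geno @ weights) / (2.0 * weights.sum())
        p = np.clip(q * (1.0 - e) + (1.0 - q) * e, 0.0, 1.0)
        depth = rng.negative_binomial(k, nb_p, size=n_sites)
        alt = rng.binomial(depth, p)
        counts[pool] = (depth - alt, alt)

    variants = []
    for i, site in enumerate(truth.sites):
        variants.append(
            PooledVariant(
                variant_id=site.variant_id,
                transcript_id=site.transcript_id,
                position=site.position,
                ref=site.ref,
                alt=site.alt,
                counts={
                    pool: (int(counts[pool][0][i]), int(counts[pool][1][i]))
                    for pool in ("WT", "MUT", "SIB")
                },
            )
        )
    return variants


def simulate_dataset(model: CrossModel) -> SimulatedDataset:
    """Run the full generator: transcripts -> sites -> pools -> read counts."""
    rng = np.random.default_rng(model.seed)
    n_transcripts = max(
        1, int(np.ceil((model.n_background_variants + 1) / model.transcript_mean_variants))
    )
    transcripts = make_transcripts(rng, n_transcripts)
    sites = place_variants(transcripts, model, rng)
    truth = build_pools(model, sites, rng)
    variants = sequence_pools(truth, model, rng)
    return SimulatedDataset(variants=variants, transcripts=transcripts, truth=truth)


def simulate_coverage(
    transcripts: Mapping[str, TranscriptModel],
    rng: np.random.Generator,
    n_downregulated: int = 30,
    fold_change: float = 0.2,
    mean_coverage: float = 50.0,
    dispersion: float = 10.0,
) -> tuple["object", list[str]]:
    """Simulate a per-gene coverage table with planted downregulation.

    A random subset of genes has its mutant-pool coverage scaled by
    ``fold_change`` (< 1 means downregulated in mutants), emulating loss of
    a tissue's transcriptional program downstream of the causal gene.
    Returns a pandas DataFrame (gene_id, mut_depth, sib_depth) and the list
    of truly downregulated gene ids.
    """
    import pandas as pd

    if not 0 < fold_change:
        raise ConfigurationError("fold_change must be > 0")
    gene_ids = list(transcripts)
    n_genes = len(gene_ids)
    n_down = min(n_downregulated, n_genes)
    down = sorted(rng.choice(n_genes, size=n_down, replace=False))
    down_ids = [gene_ids[i] for i in down]
    k = dispersion
    sib_mean = np.full(n_genes, mean_coverage)
    mut_mean = sib_mean.copy()
    mut_mean[down] *= fold_change
    sib = rng.negative_binomial(k, k / (k + sib_mean))
    mut = rng.negative_binomial(k, k / (k + mut_mean))
    frame = pd.DataFrame(
        {"gene_id": gene_ids, "mut_depth": mut, "sib_depth": sib}
    )
    return frame, down_ids


def write_truth_table(truth: TruthSet, path: str | Path) -> None:
    """Write the per-variant ground truth as TSV."""
    columns = [
        "variant_id", "transcript_id", "position", "ref", "alt", "origin",
        "founder_genotype", "wt_strain_genotype", "is_causal",
        "expected_wt_alt_fraction", "expected_mut_alt_fraction",
        "expected_sib_alt_fraction",
    ]
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("\t".join(columns) + "\n")
        for i, s in enumerate(truth.sites):
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.variant_id, s.transcript_id, s.position, s.ref, s.alt,
                        s.origin, s.founder_genotype, s.wt_strain_genotype,
                        int(s.is_causal),
                        f"{truth.expected_alt_fraction['WT'][i]:.6g}",
                        f"{truth.expected_alt_fraction['MUT'][i]:.6g}",
                        f"{truth.expected_alt_fraction['SIB'][i]:.6g}",
                    )
                )
                + "\n"
            )
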