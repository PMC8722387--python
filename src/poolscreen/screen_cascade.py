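"""The six-screen filtering cascade over pooled variant tables.

Candidate causal mutations are nominated by an ordered conjunction of
deterministic read-count filters on the WT / mutant / sibling pools:

1. WT and mutant pools are homozygous for *different* alleles (at a
   configurable homozygosity fraction, default 0.9);
2. full enrichment — exactly 100% alt reads in the mutant pool and 0% in
   the WT pool (defaults; both fractions configurable);
3. WT total depth strictly greater than 10;
4. mutant total depth strictly greater than 5;
5. the sibling pool is heterozygous, with strictly more than 4 reads from
   each allele;
6. in the sibling pool the WT (ref) allele has strictly more reads than the
   mutant (alt) allele — the Mendelian expectation for a pool of hom-ref
   and het siblings.

An optional seventh condition keeps only protein-changing (non-synonymous)
variants; it can run after Screen 6 (default), before Screen 1, or be
disabled. All "more than" comparisons are strict: ties fail. The cascade is
a pure filter — no p-values, no multiple-testing correction — so the final
candidate set is order-invariant even though per-screen survivor counts are
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .consequence import ConsequenceCall
from .variant_io import PooledVariant

NONSYN_MODES = ("final", "prefilter", "off")


class ConfigurationError(ValueError):
    """Invalid thresholds or missing inputs for a requested screen."""


@dataclass(frozen=True)
class ScreenThresholds:
    """Numeric criteria of the six screens plus the non-synonymous flag.

    Count thresholds use strict greater-than comparison. The fraction pair
    (``wt_alt_fraction_max``, ``mut_alt_fraction_required``) defaults to the
    exact 0%/100% enrichment criterion; relaxing them admits pools with a
    few stray reads. ``screen1_hom_fraction`` defines how fixed a pool must
    be to be called homozygous in Screen 1.
    """

    wt_min_total: int = 10
    mut_min_total: int = 5
    sib_min_each_allele: int = 4
    mut_alt_fraction_required: float = 1.0
    wt_alt_fraction_max: float = 0.0
    screen1_hom_fraction: float = 0.9
    require_nonsynonymous: bool = True

    def __post_init__(self) -> None:
        for name in ("wt_min_total", "mut_min_total", "sib_min_each_allele"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.wt_alt_fraction_max < self.mut_alt_fraction_required <= 1.0:
            raise ConfigurationError(
                "need 0 <= wt_alt_fraction_max < mut_alt_fraction_required <= 1"
            )
        if not 0.5 < self.screen1_hom_fraction <= 1.0:
            raise ConfigurationError("screen1_hom_fraction must lie in (0.5, 1]")


def alt_fraction(counts: tuple[int, int]) -> float | None:
    """Alt-allele read fraction, or ``None`` (undefined) at zero depth.

    Zero depth is explicitly undefined rather than 0 so that downstream
    screens can fail such sites instead of mistaking them for fixed-ref.
    """
    ref_reads, alt_reads = counts
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        return None
    return alt_reads / total


def _pool_call(fraction: float, hom_fraction: float) -> str | None:
    """Allele a pool is fixed for at the given homozygosity fraction."""
    if fraction >= hom_fraction:
        return "alt"
    if fraction <= 1.0 - hom_fraction:
        return "ref"
    return None


def screen1_homozygous_difference(
    variant: PooledVariant, thresholds: ScreenThresholds
) -> bool:
    """WT and mutant pools each homozygous, and for different alleles."""
    f_wt = alt_fraction(variant.counts["WT"])
    f_mut = alt_fraction(variant.counts["MUT"])
    if f_wt is None or f_mut is None:
        return False
    call_wt = _pool_call(f_wt, thresholds.screen1_hom_fraction)
    call_mut = _pool_call(f_mut, thresholds.screen1_hom_fraction)
    return call_wt is not None and call_mut is not None and call_wt != call_mut


def screen2_full_enrichment(
    variant: PooledVariant, thresholds: ScreenThresholds
) -> bool:
    """Mutant pool at (default exactly) 100% alt, WT pool at 0% alt."""
    f_wt = alt_fraction(variant.counts["WT"])
    f_mut = alt_fraction(variant.counts["MUT"])
    if f_wt is None or f_mut is None:
        return False
    return (
        f_mut >= thresholds.mut_alt_fraction_required
        and f_wt <= thresholds.wt_alt_fraction_max
    )


def screen3_wt_depth(variant: PooledVariant, thresholds: ScreenThresholds) -> bool:
    """WT pool total depth strictly above the floor (default > 10)."""
    return variant.total("WT") > thresholds.wt_min_total


def screen4_mut_depth(variant: PooledVariant, thresholds: ScreenThresholds) -> bool:
    """Mutant pool total depth strictly above the floor (default > 5)."""
    return variant.total("MUT") > thresholds.mut_min_total


def screen5_sib_het(variant: PooledVariant, thresholds: ScreenThresholds) -> bool:
    """Sibling pool heterozygous: both alleles strictly above the floor."""
    sib_ref, sib_alt = variant.counts["SIB"]
    return (
        sib_ref > thresholds.sib_min_each_allele
        and sib_alt > thresholds.sib_min_each_allele
    )


def screen6_sib_ratio(variant: PooledVariant, thresholds: ScreenThresholds) -> bool:
    """Sibling ref reads strictly outnumber alt reads (ties fail)."""
    sib_ref, sib_alt = variant.counts["SIB"]
    return sib_ref > sib_alt


SCREENS: tuple[tuple[str, Callable[[PooledVariant, ScreenThresholds], bool]], ...] = (
    ("screen1_homozygous_difference", screen1_homozygous_difference),
    ("screen2_full_enrichment", screen2_full_enrichment),
    ("screen3_wt_depth", screen3_wt_depth),
    ("screen4_mut_depth", screen4_mut_depth),
    ("screen5_sib_het", screen5_sib_het),
    ("screen6_sib_ratio", screen6_sib_ratio),
)


@dataclass(frozen=True)
class ScreenResult:
    label: str
    n_survivors: int
    survivor_ids: tuple[str, ...]


@dataclass(frozen=True)
class CascadeReport:
    """Per-screen survivor counts plus the final sorted candidate list."""

    screens: tuple[ScreenResult, ...]
    candidates: tuple[PooledVariant, ...]

    @property
    def candidate_ids(self) -> tuple[str, ...]:
        return tuple(v.variant_id for v in self.candidates)

    def survivor_counts(self) -> dict[str, int]:
        return {s.label: s.n_survivors for s in self.screens}


def _nonsyn_pass(
    variant: PooledVariant,
    consequences: Mapping[str, ConsequenceCall],
) -> bool:
    try:
        call = consequences[variant.variant_id]
    except KeyError:
        raise ConfigurationError(
            f"non-synonymous screening requested but no consequence call was "
            f"supplied for surviving variant {variant.variant_id!r}"
        ) from None
    return call.is_nonsynonymous


def run_cascade(
    variants: Sequence[PooledVariant],
    thresholds: ScreenThresholds | None = None,
    consequences: Mapping[str, ConsequenceCall] | None = None,
    nonsyn_mode: str = "final",
) -> CascadeReport:
    """Apply Screens 1-6 (and optionally the non-synonymous condition).

    ``nonsyn_mode`` places the protein-consequence condition after Screen 6
    (``"final"``), before Screen 1 (``"prefilter"``), or disables it
    (``"off"``); because all screens are conjunctive the final candidate
    set is the same for ``final`` and ``prefilter``, only the per-screen
    survivor counts differ. Candidates are sorted by (transcript_id,
    position) and the whole report is deterministic for fixed input.
    """
    if thresholds is None:
        thresholds = ScreenThresholds()
    if nonsyn_mode not in NONSYN_MODES:
        raise ConfigurationError(
            f"nonsyn_mode must be one of {NONSYN_MODES}, got {nonsyn_mode!r}"
        )
    nonsyn_active = thresholds.require_nonsynonymous and nonsyn_mode != "off"
    if nonsyn_active and consequences is None:
        raise ConfigurationError(
            "require_nonsynonymous is on but no consequence calls were supplied"
        )

    survivors = list(variants)
    results: list[ScreenResult] = []

    def apply(label: str, predicate: Callable[[PooledVariant], bool]) -> None:
        nonlocal survivors
        survivors = [v for v in survivors if predicate(v)]
        results.append(
            ScreenResult(label, len(survivors), tuple(v.variant_id for v in survivors))
        )

    if nonsyn_active and nonsyn_mode == "prefilter":
        apply("nonsynonymous", lambda v: _nonsyn_pass(v, consequences))
    for label, fn in SCREENS:
        apply(label, lambda v, _fn=fn: _fn(v, thresholds))
    if nonsyn_active and nonsyn_mode == "final":
        apply("nonsynonymous", lambda v: _nonsyn_pass(v, consequences))

    final = sorted(survivors, key=lambda v: (v.transcript_id, v.position))
    return CascadeReport(screens=tuple(results), candidates=tuple(final))


def write_report_tsv(report: CascadeReport, path: str | Path) -> None:
    """Per-screen survivor counts, mirroring the shape of a screening table."""
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("screen\tn_survivors\n")
        for result in report.screens:
            handle.write(f"{result.label}\t{result.n_survivors}\n")


def write_candidates_tsv(report: CascadeReport, path: str | Path) -> None:
    """Final candidates with per-pool counts and alt fractions."""
    columns = [
        "variant_id", "transcript_id", "position", "ref", "alt",
        "wt_ref", "wt_alt", "mut_ref", "mut_alt", "sib_ref", "sib_alt",
        "wt_alt_fraction", "mut_alt_fraction", "sib_alt_fraction",
    ]

    def fmt(fraction: float | None) -> str:
        return "NA" if fraction is None else f"{fraction:.4f}"

    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("\t".join(columns) + "\n")
        for v in report.candidates:
            wt, mut, sib = v.counts["WT"], v.counts["MUT"], v.counts["SIB"]
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        v.variant_id, v.transcript_id, v.position, v.ref, v.alt,
                        wt[0], wt[1], mut[0], mut[1], sib[0], sib[1],
                        fmt(alt_fraction(wt)), fmt(alt_fraction(mut)),
                        fmt(alt_fraction(sib)),
                    )
                )
                + "\n"
            )
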