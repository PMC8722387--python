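"""Shared fixtures and helpers for the poolscreen test suite."""

from __future__ import annotations

import numpy as np
import pytest

from poolscreen.screen_cascade import ScreenThresholds
from poolscreen.variant_io import PooledVariant, TranscriptModel, validate_transcript


def make_variant(
    vid: str = "v1",
    tid: str = "tx1",
    pos: int = 1,
    ref: str = "A",
    alt: str = "G",
    wt: tuple[int, int] = (20, 0),
    mut: tuple[int, int] = (0, 20),
    sib: tuple[int, int] = (12, 8),
) -> PooledVariant:
    return PooledVariant(vid, tid, pos, ref, alt, {"WT": wt, "MUT": mut, "SIB": sib})


def random_variant_table(rng: np.random.Generator, n_rows: int) -> list[PooledVariant]:
    """Random tables that exercise the screens' boundary counts.

    Counts are drawn near the decision thresholds (0-25) so that every
    screen both passes and fails often.
    """
    variants = []
    for i in range(n_rows):
        bases = rng.permutation(list("ACGT"))
        counts = rng.integers(0, 26, size=6)
        variants.append(
            PooledVariant(
                variant_id=f"r{i:06d}",
                transcript_id=f"tx{int(rng.integers(1, 6)):03d}",
                position=int(rng.integers(1, 2000)),
                ref=str(bases[0]),
                alt=str(bases[1]),
                counts={
                    "WT": (int(counts[0]), int(counts[1])),
                    "MUT": (int(counts[2]), int(counts[3])),
                    "SIB": (int(counts[4]), int(counts[5])),
                },
            )
        )
    return variants


def brute_force_final_set(variants, thresholds: ScreenThresholds) -> set[str]:
    """Independent row-by-row conjunction of the six screen predicates.

    Written flat, without the cascade machinery, to serve as an oracle.
    """
    survivors = set()
    h = thresholds.screen1_hom_fraction
    for v in variants:
        wt_ref, wt_alt = v.counts["WT"]
        mut_ref, mut_alt = v.counts["MUT"]
        sib_ref, sib_alt = v.counts["SIB"]
        wt_total = wt_ref + wt_alt
        mut_total = mut_ref + mut_alt
        if wt_total == 0 or mut_total == 0:
            continue
        f_wt = wt_alt / wt_total
        f_mut = mut_alt / mut_total
        wt_is_alt, wt_is_ref = f_wt >= h, f_wt <= 1 - h
        mut_is_alt, mut_is_ref = f_mut >= h, f_mut <= 1 - h
        if not ((wt_is_alt and mut_is_ref) or (wt_is_ref and mut_is_alt)):
            continue  # screen 1
        if f_mut < thresholds.mut_alt_fraction_required:
            continue  # screen 2, mutant side
        if f_wt > thresholds.wt_alt_fraction_max:
            continue  # screen 2, WT side
        if not wt_total > thresholds.wt_min_total:
            continue  # screen 3
        if not mut_total > thresholds.mut_min_total:
            continue  # screen 4
        if not (sib_ref > thresholds.sib_min_each_allele
                and sib_alt > thresholds.sib_min_each_allele):
            continue  # screen 5
        if not sib_ref > sib_alt:
            continue  # screen 6
        survivors.add(v.variant_id)
    return survivors


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    # 5' UTR (6 nt) + ATG CGC ATT GCT AAA TAA + 3' UTR (6 nt)
    cdna = "GGGGGG" + "ATGCGCATTGCTAAATAA" + "CCCCCC"
    return validate_transcript(TranscriptModel("tx1", cdna, 7, 24))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
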