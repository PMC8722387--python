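"""Boundary behaviour, oracle equivalence and invariants of the cascade."""

from __future__ import annotations

import numpy as np
import pytest

from poolscreen import consequence as consequence_mod
from poolscreen import cross_sim
from poolscreen.screen_cascade import (
    ConfigurationError,
    ScreenThresholds,
    alt_fraction,
    run_cascade,
    screen1_homozygous_difference,
    screen2_full_enrichment,
    screen3_wt_depth,
    screen4_mut_depth,
    screen5_sib_het,
    screen6_sib_ratio,
)

from conftest import brute_force_final_set, make_variant, random_variant_table

TH = ScreenThresholds()


# -- alt fraction -------------------------------------------------------------

@pytest.mark.parametrize(
    "counts, expected",
    [((0, 30), 1.0), ((30, 0), 0.0), ((10, 30), 0.75), ((0, 0), None)],
)
def test_alt_fraction(counts, expected):
    assert alt_fraction(counts) == expected


def test_alt_fraction_rejects_negative_counts():
    with pytest.raises(ValueError):
        alt_fraction((-1, 5))


# -- individual screens (boundary fidelity) ----------------------------------

@pytest.mark.parametrize(
    "wt, mut, expected",
    [
        ((20, 0), (0, 25), True),    # fully fixed, different alleles
        ((20, 0), (12, 13), False),  # MUT not homozygous at 0.9
        ((0, 0), (0, 25), False),    # undefined WT fraction
        ((20, 1), (1, 25), True),    # 0.95 fixed both sides
        ((0, 20), (25, 0), True),    # fixed for swapped alleles still differs
        ((20, 0), (25, 0), False),   # both fixed for the same allele
    ],
)
def test_screen1_homozygous_difference(wt, mut, expected):
    v = make_variant(wt=wt, mut=mut)
    assert screen1_homozygous_difference(v, TH) is expected


@pytest.mark.parametrize(
    "wt, mut, expected",
    [
        ((15, 0), (0, 9), True),    # exact 0% / 100%
        ((15, 1), (0, 9), False),   # any WT alt read breaks 0%
        ((15, 0), (1, 9), False),   # any MUT ref read breaks 100%
        ((0, 0), (0, 9), False),    # undefined WT fraction
    ],
)
def test_screen2_full_enrichment(wt, mut, expected):
    v = make_variant(wt=wt, mut=mut)
    assert screen2_full_enrichment(v, TH) is expected


@pytest.mark.parametrize(
    "total, expected", [(11, True), (10, False), (0, False)]
)
def test_screen3_wt_depth_is_strictly_more_than_ten(total, expected):
    v = make_variant(wt=(total, 0))
    assert screen3_wt_depth(v, TH) is expected


@pytest.mark.parametrize(
    "total, expected", [(6, True), (5, False), (0, False)]
)
def test_screen4_mut_depth_is_strictly_more_than_five(total, expected):
    v = make_variant(mut=(0, total))
    assert screen4_mut_depth(v, TH) is expected


@pytest.mark.parametrize(
    "sib, expected",
    [((5, 5), True), ((4, 9), False), ((9, 4), False), ((0, 50), False)],
)
def test_screen5_sibling_het_needs_more_than_four_each(sib, expected):
    v = make_variant(sib=sib)
    assert screen5_sib_het(v, TH) is expected


@pytest.mark.parametrize(
    "sib, expected", [((12, 7), True), ((7, 7), False), ((7, 12), False)]
)
def test_screen6_sibling_ref_strictly_outnumbers_alt(sib, expected):
    v = make_variant(sib=sib)
    assert screen6_sib_ratio(v, TH) is expected


# -- thresholds validation ----------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(wt_alt_fraction_max=1.0, mut_alt_fraction_required=1.0),
        dict(wt_alt_fraction_max=0.5, mut_alt_fraction_required=0.4),
        dict(screen1_hom_fraction=0.5),
        dict(wt_min_total=-1),
    ],
)
def test_impossible_thresholds_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        ScreenThresholds(**kwargs)


# -- cascade ------------------------------------------------------------------

def _nonsyn_all(variants):
    return {
        v.variant_id: consequence_mod.ConsequenceCall(
            v.variant_id, "missense", 1, "CGC", "TGC", "R", "C"
        )
        for v in variants
    }


def test_empty_table_reports_zero_survivors():
    report = run_cascade([], TH, consequences={})
    assert all(s.n_survivors == 0 for s in report.screens)
    assert report.candidates == ()


def test_missing_consequences_is_a_configuration_error():
    v = make_variant(wt=(20, 0), mut=(0, 20), sib=(12, 8))
    with pytest.raises(ConfigurationError, match="consequence"):
        run_cascade([v], TH, consequences=None)
    report = run_cascade([v], TH, consequences=None, nonsyn_mode="off")
    assert report.candidate_ids == ("v1",)


def test_survivor_counts_are_non_increasing(rng):
    variants = random_variant_table(rng, 500)
    report = run_cascade(variants, TH, consequences=_nonsyn_all(variants))
    counts = [s.n_survivors for s in report.screens]
    assert counts == sorted(counts, reverse=True)


def test_cascade_equals_bruteforce_conjunction(rng):
    for _ in range(50):
        variants = random_variant_table(rng, int(rng.integers(0, 400)))
        report = run_cascade(variants, TH, consequences=None, nonsyn_mode="off")
        assert set(report.candidate_ids) == brute_force_final_set(variants, TH)


def test_final_set_is_invariant_to_screen_order(rng):
    """Conjunctive screens commute: any predicate order gives the same set."""
    from poolscreen.screen_cascade import SCREENS

    variants = random_variant_table(rng, 600)
    baseline = set(
        run_cascade(variants, TH, consequences=None, nonsyn_mode="off").candidate_ids
    )
    for _ in range(5):
        order = rng.permutation(len(SCREENS))
        survivors = list(variants)
        for i in order:
            _, fn = SCREENS[i]
            survivors = [v for v in survivors if fn(v, TH)]
        assert {v.variant_id for v in survivors} == baseline


def test_prefilter_and_final_nonsyn_modes_agree_on_candidates(rng):
    variants = random_variant_table(rng, 600)
    consequences = {
        v.variant_id: consequence_mod.ConsequenceCall(
            v.variant_id,
            "missense" if i % 2 == 0 else "synonymous",
            1, "CGC", "TGC", "R", "C",
        )
        for i, v in enumerate(variants)
    }
    final = run_cascade(variants, TH, consequences, nonsyn_mode="final")
    pre = run_cascade(variants, TH, consequences, nonsyn_mode="prefilter")
    assert final.candidate_ids == pre.candidate_ids
    assert final.screens[-1].label == "nonsynonymous"
    assert pre.screens[0].label == "nonsynonymous"


def test_tightening_thresholds_never_enlarges_final_set(rng):
    variants = random_variant_table(rng, 800)
    loose = set(
        run_cascade(variants, TH, consequences=None, nonsyn_mode="off").candidate_ids
    )
    for tighter in (
        ScreenThresholds(wt_min_total=15),
        ScreenThresholds(mut_min_total=9),
        ScreenThresholds(sib_min_each_allele=7),
        ScreenThresholds(screen1_hom_fraction=0.97),
    ):
        tight = set(
            run_cascade(
                variants, tighter, consequences=None, nonsyn_mode="off"
            ).candidate_ids
        )
        assert tight <= loose


def test_candidates_sorted_by_transcript_and_position(rng):
    variants = random_variant_table(rng, 800)
    report = run_cascade(variants, TH, consequences=None, nonsyn_mode="off")
    keys = [(v.transcript_id, v.position) for v in report.candidates]
    assert keys == sorted(keys)


def test_noiseless_simulation_recovers_the_planted_variant():
    """With no allele-miscall noise the causal variant survives nearly every
    run; rare losses come from screens 5-6 on unlucky sibling-pool draws
    (a het-heavy sibling pool can realize more alt than ref reads)."""
    recovered = 0
    for seed in range(40):
        model = cross_sim.CrossModel(
            seed=seed, n_background_variants=300, seq_error_rate=0.0
        )
        dataset = cross_sim.simulate_dataset(model)
        consequences = consequence_mod.annotate_variants(
            dataset.variants, dataset.transcripts
        )
        report = run_cascade(dataset.variants, TH, consequences=consequences)
        recovered += dataset.truth.causal_id in report.candidate_ids
    assert recovered >= 38
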