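"""Mendelian structure, noise model and determinism of the cross simulator."""

from __future__ import annotations

import math

import numpy as np
import pytest

from poolscreen import cross_sim
from poolscreen.cross_sim import (
    ConfigurationError,
    CrossModel,
    TruthSet,
    VariantSite,
    build_pools,
    make_transcripts,
    place_variants,
    segregate_selfing,
    sequence_pools,
    simulate_dataset,
)
from poolscreen.variant_io import write_variant_table


# -- model validation ---------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_embryos_per_pool=0),
        dict(residual_het_rate=-0.1),
        dict(seq_error_rate=1.5),
        dict(depth_mean=0),
        dict(depth_dispersion=0),
        dict(residual_het_rate=0.7, enu_het_rate=0.7),
    ],
)
def test_invalid_models_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        CrossModel(seed=1, **kwargs)


# -- selfing segregation ------------------------------------------------------

def test_selfing_requires_heterozygous_founder(rng):
    with pytest.raises(ConfigurationError, match="heterozygous"):
        segregate_selfing("hom_ref", 10, rng)


def test_selfing_zero_offspring_is_empty(rng):
    assert segregate_selfing("het", 0, rng) == []


def test_selfing_fractions_match_one_two_one(rng):
    n = 4000
    offspring = segregate_selfing("het", n, rng)
    for genotype, p in (("hom_ref", 0.25), ("het", 0.5), ("hom_alt", 0.25)):
        fraction = offspring.count(genotype) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(fraction - p) < 3 * se


# -- pools --------------------------------------------------------------------

def _tiny_sites():
    return place_variants(
        make_transcripts(np.random.default_rng(0), 2),
        CrossModel(seed=0, n_background_variants=10),
        np.random.default_rng(1),
    )


def test_mutant_pool_is_hom_alt_and_siblings_never_are():
    model = CrossModel(seed=3, n_background_variants=10)
    sites = _tiny_sites()
    truth = build_pools(model, sites, np.random.default_rng(5))
    i = truth.causal_index
    assert (truth.mut_genotypes[i] == 2).all()
    assert (truth.sib_genotypes[i] != 2).all()
    assert (truth.wt_genotypes[i] == 0).all()
    assert truth.expected_alt_fraction["MUT"][i] == 1.0
    assert truth.expected_alt_fraction["SIB"][i] == pytest.approx(1 / 3)
    assert truth.expected_alt_fraction["WT"][i] == 0.0


def test_homozygous_background_does_not_segregate():
    model = CrossModel(
        seed=3, n_background_variants=20, residual_het_rate=0.0, enu_het_rate=0.0
    )
    transcripts = make_transcripts(np.random.default_rng(0), 2)
    sites = place_variants(transcripts, model, np.random.default_rng(1))
    truth = build_pools(model, sites, np.random.default_rng(5))
    for i, site in enumerate(truth.sites):
        if site.is_causal:
            continue
        expected = {"hom_ref": 0, "hom_alt": 2}[site.founder_genotype]
        assert (truth.mut_genotypes[i] == expected).all()
        assert (truth.sib_genotypes[i] == expected).all()


def test_sibling_genotypes_average_one_third_alt(rng):
    """Across many sibling pools the causal-site dosage converges to 1/3."""
    model = CrossModel(seed=1, n_background_variants=0)
    transcripts = make_transcripts(np.random.default_rng(0), 1)
    sites = place_variants(transcripts, model, np.random.default_rng(1))
    n_pools = 400
    fractions = []
    for _ in range(n_pools):
        truth = build_pools(model, sites, rng)
        fractions.append(truth.sib_genotypes[truth.causal_index].mean() / 2)
    # per-pool variance of the dosage fraction is 1/(18 * n_embryos)
    se = math.sqrt(1 / (18 * model.n_embryos_per_pool) / n_pools)
    assert abs(np.mean(fractions) - 1 / 3) < 3 * se


# -- sequencing ---------------------------------------------------------------

def _single_site_truth(sib_dosages, n_embryos):
    site = VariantSite("v1", "tx1", 5, "A", "G", "causal", "het", "hom_ref")
    geno = np.array([sib_dosages])
    return TruthSet(
        sites=(site,),
        causal_id="v1",
        wt_genotypes=np.zeros((1, n_embryos), dtype=int),
        mut_genotypes=np.full((1, n_embryos), 2),
        sib_genotypes=geno,
        expected_alt_fraction={
            "WT": np.array([0.0]), "MUT": np.array([1.0]),
            "SIB": np.array([geno.mean() / 2]),
        },
    )


def test_noiseless_fixed_sites_have_pure_counts(rng):
    truth = _single_site_truth([0] * 10 + [1] * 10, 20)
    model = CrossModel(seed=1, n_embryos_per_pool=20, seq_error_rate=0.0)
    variants = sequence_pools(truth, model, rng)
    wt_ref, wt_alt = variants[0].counts["WT"]
    mut_ref, mut_alt = variants[0].counts["MUT"]
    assert wt_alt == 0 and wt_ref > 0
    assert mut_ref == 0 and mut_alt > 0


def test_half_het_pool_sequences_at_quarter_dosage(rng):
    """10 hom-ref + 10 het embryos, equal expression: alt fraction 1/4."""
    truth = _single_site_truth([0] * 10 + [1] * 10, 20)
    model = CrossModel(
        seed=1, n_embryos_per_pool=20, seq_error_rate=0.0, depth_mean=20000.0,
        depth_dispersion=1e9,
    )
    variants = sequence_pools(truth, model, rng)
    sib_ref, sib_alt = variants[0].counts["SIB"]
    total = sib_ref + sib_alt
    se = math.sqrt(0.25 * 0.75 / total)
    assert abs(sib_alt / total - 0.25) < 4 * se


def test_causal_signature_is_exact_without_noise():
    model = CrossModel(seed=11, n_background_variants=50, seq_error_rate=0.0)
    dataset = simulate_dataset(model)
    causal = dataset.variants[dataset.truth.causal_index]
    assert causal.counts["WT"][1] == 0
    assert causal.counts["MUT"][0] == 0


# -- whole-dataset properties -------------------------------------------------

def test_identical_seeds_give_byte_identical_tables(tmp_path):
    model = CrossModel(seed=42, n_background_variants=200)
    paths = []
    for name in ("a", "b"):
        dataset = simulate_dataset(model)
        path = tmp_path / f"{name}.tsv"
        write_variant_table(dataset.variants, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_different_seeds_differ(tmp_path):
    t1 = simulate_dataset(CrossModel(seed=1, n_background_variants=50)).variants
    t2 = simulate_dataset(CrossModel(seed=2, n_background_variants=50)).variants
    assert t1 != t2


def test_dataset_is_consistent():
    dataset = simulate_dataset(CrossModel(seed=5, n_background_variants=100))
    assert len(dataset.variants) == 101
    causal = [s for s in dataset.truth.sites if s.is_causal]
    assert len(causal) == 1
    for variant, site in zip(dataset.variants, dataset.truth.sites):
        assert variant.variant_id == site.variant_id
        tx = dataset.transcripts[variant.transcript_id]
        assert tx.cdna[variant.position - 1] == variant.ref


def test_expression_weights_preserve_expected_dosage(rng):
    """Unequal per-embryo expression perturbs, but does not bias, dosage."""
    truth = _single_site_truth([0] * 10 + [2] * 10, 20)
    model = CrossModel(
        seed=1, seq_error_rate=0.0, expression_cv=0.5,
        depth_mean=5000.0, depth_dispersion=1e9,
    )
    fractions = []
    for _ in range(300):
        v = sequence_pools(truth, model, rng)[0]
        sib_ref, sib_alt = v.counts["SIB"]
        fractions.append(sib_alt / (sib_ref + sib_alt))
    assert np.std(fractions) > 0.02  # weights do perturb individual pools
    assert abs(np.mean(fractions) - 0.5) < 0.015  # but are unbiased


# -- planted coverage change --------------------------------------------------

def test_simulated_coverage_marks_downregulated_genes(rng):
    transcripts = make_transcripts(rng, 50)
    frame, down_ids = cross_sim.simulate_coverage(
        transcripts, rng, n_downregulated=5, fold_change=0.1
    )
    assert len(down_ids) == 5
    down = frame[frame["gene_id"].isin(down_ids)]
    up = frame[~frame["gene_id"].isin(down_ids)]
    assert down["mut_depth"].mean() < 0.5 * up["mut_depth"].mean()
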