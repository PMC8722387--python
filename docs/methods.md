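# Methods

## The genetic model

The simulator emulates a forward-genetics screen in a self-fertilizing,
near-isogenic line. A single F1 hermaphrodite, heterozygous for one
recessive lethal/visible mutation, selfs; offspring genotypes at the causal
site follow the 1:2:1 selfing distribution. Phenotype sorting then defines
the pools:

- **mutant pool** — offspring conditioned hom-alt at the causal site
  (expected pool alt-allele fraction 1);
- **sibling pool** — offspring conditioned *not* hom-alt, i.e. hom-ref:het
  in expected ratio 1:2 (expected alt fraction 1/3);
- **WT pool** — the unmutagenized parental strain, hom-ref everywhere
  except residual-polymorphism sites.

Background sites fall into three origin classes, each segregating
independently per embryo:

| origin | founder (mutant lineage) | WT strain | emulates |
|---|---|---|---|
| `residual_het` | het | het | residual strain polymorphism (the ~0.03% non-isogenic fraction) |
| `enu_het` | het | hom-ref | ENU variants still heterozygous in the F1 |
| `enu_hom_ref` / `enu_hom_alt` | hom | hom-ref | ENU variants fixed during line propagation, split evenly |

The `enu_hom_alt` class is what makes the screen's later stages necessary:
such sites look perfectly enriched (100% mutant / 0% WT) but are equally
fixed in the sibling pool, and only the sibling-heterozygosity screen
removes them.

## Pooled sequencing model

Sequencing is modelled at the allele-count level, not the read level. Per
site and pool:

- depth `D ~ NegBin(mean m, dispersion k)` with variance `m + m²/k`
  (overdispersed coverage, standard for RNA-seq; large `k` approaches
  Poisson);
- alt reads `~ Binomial(D, p)` with `p = q(1−e) + (1−q)e`, where `q` is the
  pool's expression-weighted alt-allele dosage and `e` the per-read
  probability of miscalling the allele (a symmetric biallelic flip; third
  alleles are not modelled because the screen is biallelic).

Allele counts from pooled RNA are expression-weighted: by default every
embryo contributes equally (`expression_cv = 0`); setting `expression_cv`
> 0 draws mean-1 gamma weights per embryo, which perturbs individual pool
dosages without biasing their expectation. This knob exists because real
sibling pools can deviate from the 1/3 expectation (unequal expression
among embryos is one candidate cause), but no value is asserted.

## Default parameters

| parameter | default | why |
|---|---|---|
| `n_embryos_per_pool` | 20 | the emulated study design |
| `n_background_variants` | 5000 | order of magnitude of a transcriptome-wide variant list before filtering |
| `residual_het_rate` | 3×10⁻⁴ | matches ~99.97% SNP homozygosity of a long-inbred strain |
| `enu_het_rate` | 0.2 | our own choice: most induced variants fix (hom) during the generations between mutagenesis and screening; a minority remain segregating |
| `depth_mean`, `depth_dispersion` | 50, 10 | our own choice of a desk-scale single-lane coverage model; the real depth distribution of the emulated experiment is unpublished |
| `seq_error_rate` | 0.005 | typical short-read per-base error magnitude |
| seed | mandatory | no silent clock seeding; identical (model, seed) pairs are byte-identical |

## The cascade and its numerical choices

All six screens are pure predicates over one row's counts (see README for
the list). Choices worth recording:

- **"More than" is strict everywhere** (`>`); boundary values fail (WT
  depth 10 fails, 11 passes; mutant 5 fails, 6 passes; sibling (4, x)
  fails; sibling 7:7 ties fail).
- **Screen 1 vs Screen 2.** Screen 1 calls a pool homozygous at alt
  fraction ≥ `screen1_hom_fraction` (default 0.9) or ≤ 1 − that, and
  requires the two pools fixed for different alleles; Screen 2 then demands
  *exact* 0%/100% (any stray read fails). The looser-then-exact structure
  reflects a first pass that tolerates noise followed by the strict
  enrichment definition.
- **Zero-depth pools** have an undefined alt fraction (an explicit
  sentinel, never 0); any screen referencing it fails that variant —
  conservative, and it prevents division-by-zero artefacts.
- **Non-synonymous placement.** The protein-consequence condition can run
  as a final seventh screen (default), as a prefilter before Screen 1, or
  be disabled. Because the screens are conjunctive the final candidate set
  is identical under `final` and `prefilter`; only per-screen survivor
  counts differ.
- No multiple-testing correction: the cascade is a deterministic filter,
  not a family of hypothesis tests.

## Sensitivity of the exact-enrichment screen

Recovery of the planted variant is limited by two stochastic effects, both
measured by `analysis/05_recovery_benchmark.py` and the acceptance script
rather than asserted:

1. **Miscall noise vs exact 0%/100%.** The probability that a pool of
   negative-binomial depth contains *no* miscalled read is
   `E[(1−e)^D] = (k/(k+me))^k` ≈ 0.78 at the defaults, so noise alone caps
   recovery near 0.78² ≈ 0.61 — the dominant loss mode. With
   `seq_error_rate = 0` (arguably closer to assembly-bubble counts, where
   base-call errors rarely create the alternate path) recovery is
   limited only by effect 2.
2. **Sibling-pool draws vs screens 5–6.** A het-heavy sibling pool can
   realize more alt than ref reads (failing the strict ref > alt screen),
   or a het-poor one too few alt reads; together these reject roughly 5%
   of noiseless runs at 20 embryos and depth 50.

Users who want a high-sensitivity variant of the screen can relax
`wt_alt_fraction_max` / `mut_alt_fraction_required`; the defaults stay
faithful to the exact-enrichment definition.

## Consequence annotation

Coordinates are 1-based on the transcript cDNA; the codon index is
`(position − cds_start)//3 + 1` for positions inside the CDS, positions
outside are `noncoding` (a single-base variant cannot span the boundary).
Translation uses the standard nuclear genetic code only. Conservation of a
candidate residue is the fraction of non-gap residues in an orthologue
alignment column matching the reference residue, with reference gap
columns skipped when locating the residue.

## Expression ranking

Per-gene mean depth is normalised to per-million within each pool
(optionally length-normalised first), and genes are ranked by
`log2((mut+pc)/(sib+pc))` with pseudo-count `pc = 1` (configurable). The
ranking is scale-invariant under per-pool depth rescaling and
permutation-invariant (ties break lexicographically by gene id). No
dispersion model and no significance calls — ranking only.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the screen assumes —
Mendelian selfing segregation, phenotype conditioning, isogenic background,
overdispersed pooled counts — so passing tests demonstrate that the cascade
correctly implements its definition and recovers a variant with the
expected signature under those assumptions. It does not model: read-level
artefacts (mapping, assembly chimeras, bubble-collapse of isoforms),
allele-specific or embryo-variable expression beyond the optional gamma
weights, linked selection around the causal site, third alleles, indels, or
real orthologue phylogenies (the conservation panel in
`analysis/03_annotate_candidates.py` is synthetic and labelled as such).
Real-data survivor counts therefore cannot be reproduced from this
simulator, and no attempt is made to do so.

## Problem sizes

Defaults used by the test suite and acceptance script: 100-seed recovery
runs at 5000 background variants; 1000 random tables (up to 1000 rows) for
oracle equivalence; 10,000 offspring and 1,000 sibling pools for the
Mendelian checks; 200 random transcripts for the consequence oracle. These
sizes keep a full run on one CPU within a coffee break while leaving the
Monte-Carlo standard errors far below the assertion tolerances (all
stochastic assertions use 3 standard errors of their analytic
expectation).
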