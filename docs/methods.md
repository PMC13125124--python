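# Methods

This note documents the models, numerical choices and known limitations of
`bsaqtl`: a genotype-count QTL-seq pipeline for biparental RIL populations
with a first-class synthetic-data generator.

## Simulated populations

`simdata` emulates a soybean-style biparental design.

**Genotypes.**  Two fully homozygous parents differ at every simulated SNP
(parent A carries the reference allele, parent B the alternate).  Each RIL
starts as the F1 and is advanced by `generations_selfing` rounds of
self-fertilization.  Meiosis follows the Haldane model: the crossover count
per chromosome per meiosis is Poisson with mean `map_length_cM / 100` and
positions are uniform, with no interference and independent generations.
This is the standard simplification for RIL simulation and is sufficient
for testing a bulk-frequency scan; chiasma interference would slightly
lengthen identity-by-descent blocks but does not change the scan's
contracts.  Residual heterozygosity is `(1/2)^generations` in expectation;
the default of 6 selfing generations gives ≈ 1.6 %, a plausible value for
F4-derived lines advanced to F7 (the residual heterozygosity of the real
populations is not published, so this default is an assumption exposed in
the configuration).  Optional missing-call (default 0.02) and
genotyping-error (default 0.002) rates corrupt the emitted calls last;
the returned truth mosaic is never corrupted.

**Phenotypes.**  Plot-level values decompose as

    y(ril, env, block, trait) = μ_t + Σ_q β_qt·x(ril, q) + g_poly(ril, t)
                                + E(env, t) + GEI(ril, env, t)
                                + B(env, block, t) + ε

with `x` the parent-B origin fraction at the QTL position (0, 0.5, or 1;
QTL are coded 0/1 rather than ±1 so that the planted effect matches the
PVE regression convention), `g_poly` multivariate normal across traits
with covariance `diag(σ_G)·R·diag(σ_G)` for the configured trait
correlation matrix `R`, and the remaining terms independent normals.
Default trait means and scales loosely match published soybean seed
composition (protein ≈ 43.5 %, amino acids 0.5–2.7 % dry seed weight) and
the default variance ratios put entry-mean heritability near 0.85 with
four environments and two blocks.  Defaults include three QTL with
positive effects shared across all five traits, which induces the positive
trait correlations the analysis expects.

**What the generator does not emulate:** segregation distortion, linked
polygenic background (the polygenic term is unlinked to the simulated
markers), locus-specific missingness typical of GBS, multi-allelic sites,
and structural variation.  Passing tests therefore demonstrate the
pipeline's statistical contracts under idealized Mendelian segregation,
not performance on real GBS data.

## Mixed models and heritability

All variance-component estimation is REML.  For balanced factorial layouts
the covariance of every random term is a Kronecker product of identity and
all-ones matrices, so the restricted likelihood separates into independent
ANOVA strata; equating each stratum's mean square to its eigenvalue gives
the exact REML solution in closed form whenever the implied components are
non-negative, and a bounded quasi-Newton maximization of the stratum
likelihood handles boundary cases.  Unbalanced data (missing plots) fall
back to a dense Woodbury-based REML over arbitrary factor codings, with
BLUPs from Henderson's mixed-model equations.  The two engines agree to
optimizer tolerance on balanced data, and both match `statsmodels`
MixedLM (used purely as an independent cross-check in the tests).

Stage 1 fits `y = μ + genotype + block + ε` per environment and reports
μ + genotype BLUP as the environmental BLUPs; a single-block environment
drops the block term with a warning, and with one observation per genotype
the genotype and error variances are confounded, so the raw values are
returned unshrunken.  Stage 2 fits `value = μ + genotype + environment +
ε` on the stage-1 genotype-by-environment estimates; with one value per
cell the interaction is confounded with the stage-2 residual, so the
reported σ²_GEI always comes from the full plot-level model
`y = μ + G + E + GEI + block(E) + ε`, which is also the source of the
heritability components:

    H² = σ²_G / [σ²_G + σ²_GEI/e + σ²_err/(r·e)].

Likelihood-ratio tests of each random term use the boundary-corrected
reference 0.5·χ²₀ + 0.5·χ²₁.  Components are floored at zero; a constant
response returns all-zero components rather than an error.

## Bulk selection

The screening inputs are each environment's BLUPs plus the GEI BLUP.  How
these are combined into "overall lowest/highest" is not prescribed
anywhere, so the default is the mean of ascending ranks across all e + 1
contexts — scale-free, deterministic, and using every stated input — with
`ranking="gei_only"` available as the obvious alternative.  Ties are
broken lexicographically by RIL id so bulk membership is reproducible.

## The scan

* **Bulk frequency.**  `(hom-other-parent + 0.5·het) / non-missing calls`
  per locus, over the informative loci (both parents homozygous for
  different alleles).  The denominator is the number of genotyped bulk
  members rather than a fixed 20, and loci with fewer than `min_calls`
  (default 15 of 20) genotyped members are masked.
* **Low-frequency filter.**  A locus is dropped when the frequency is
  ≤ 0.3 in *both* bulks: where neither bulk carries the non-reference
  allele there is no contrast to measure, whereas a single low-frequency
  bulk is precisely the signal sought.  (Filtering per bulk would erase
  every strong peak and trough.)
* **Windows.**  Starts 1, 1+step, 1+2·step, … while the start does not
  exceed the chromosome end; each window covers `[start, start+width−1]`
  inclusive, holding the width at exactly 2,000,000 bp.  Output equals a
  brute-force per-window scan exactly.
* **Threshold.**  Per chromosome, `upper = |x̄| + t·σ/√n` over unmasked Δ
  with the two-sided Student quantile at the configured confidence
  (default 99.9 %) and df = n−1; a locus is "beyond" when |Δ| > upper, so
  peaks and troughs are treated symmetrically.
* **Region calling.**  Maximal runs of windows with |mean Δ| > upper seed
  candidate intervals.  Because a window (2 Mbp) is 200× wider than the
  step, a run's span smears well past the underlying signal; beyond-
  threshold SNPs inside the span are therefore grouped into clusters,
  with a new cluster whenever more than `max_gap_snps` (default 10)
  consecutive within-threshold loci intervene.  Each cluster spans its
  first to last beyond-threshold SNP, and is kept only when low-noise:
  ≥ `min_run_snps` (default 10) member SNPs beyond the threshold and a
  beyond fraction ≥ `min_beyond_fraction` (default 0.8).  Same-sign
  overlapping regions are merged.  Reported region length is end − start
  (the reporting convention of the tables this format mirrors), and the
  reported mean is the mean of |Δ| over member loci — within a called
  region Δ is essentially single-signed, so this agrees with |mean Δ| to
  rounding.
* **PVE.**  R² of GEI BLUPs regressed on the peak-SNP genotype (the
  member SNP maximizing |Δ|, coded 0/0.5/1 as the non-reference allele
  fraction) across all RILs of the population, not only the bulks.
  Monomorphic peak SNPs yield a missing PVE.
* **Validation.**  A region is validated when the other population has a
  same-trait region overlapping it by ≥ 1 bp; the intersection is
  reported as the putative-QTL interval.

## Specificity of the chromosome-wise threshold (known limitation)

With 20-RIL bulks the per-locus Δ has binomial sampling SD ≈ 0.16 under
the null, and Δ is piecewise constant along a chromosome, changing only at
the bulk members' recombination breakpoints (~80 per 100 cM across 40
RILs).  The threshold formula divides σ by √n over thousands of loci as
if they were independent, so `upper` typically lands near 0.04 — well
inside the null noise band.  Consequently QTL-free chromosomes routinely
produce called regions (a few per chromosome under the defaults), and the
procedure should be read as a *ranking and visualization* device in which
a true large-effect QTL is the strongest signal (mean |Δ| several times
the threshold), not as a calibrated test with controlled false-positive
rates.  The package reports this behavior honestly: the acceptance script
computes both the planted-QTL recovery rate (high) and the null
regions-per-genome rate (far above zero).  Users wanting calibrated
significance should lower the confidence in favour of permutation- or
simulation-based thresholds, which are out of scope here.

## Problem sizes used in tests and the acceptance script

Desk-scale defaults mirror the study's shape at reduced density: 20
chromosomes of 40 Mbp with 1,000 SNPs each (the real data had
1,566–7,409 per chromosome), 150 RILs, four environments × two blocks,
and five traits.  Parameter-recovery checks use 500 genotypes; end-to-end
recovery uses 25 seeds of a single-trait genome with one 0.8·σ_P QTL at
entry-mean H² = 0.85.  These sizes were chosen so the full suite and the
acceptance script each run in minutes on a single core while keeping
Monte-Carlo error well inside the asserted tolerances.
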