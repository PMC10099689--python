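# Methods

This note documents the statistical methods implemented in `tsnscan`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and conventions

All statistics operate on a `HaplotypeMatrix`: phased biallelic SNVs ×
haplotypes, with 1-based inclusive physical coordinates (the VCF
convention; BED input is converted on read), calls in {0 = reference,
1 = alternate, missing}, and a per-variant ancestral state read from the
VCF `AA` INFO tag. A variant whose `AA` is absent or matches neither
allele has unknown polarity: it is excluded from every derived-allele
statistic (DAF, ΔDAF, iHS, Fay & Wu's H) but retained for FST and the HWE
test, which are fold-symmetric. Unphased heterozygous genotypes become
missing haplotypes (we do not re-phase); unphased homozygotes are
unambiguous and kept; half-missing genotypes contribute their called
haplotype only.

## Variant QC

Three screens, applied in a fixed order so that each removed variant is
counted under exactly one rule:

1. **Singletons** — dataset-wide minor allele count ≤ 1 (this also drops
   monomorphic records).
2. **Missingness** — fraction of missing sample genotypes > 3% (default).
3. **HWE** — exact test p < 1e−10 (default), computed within a single
   panmictic cohort (the target population) because pooling
   differentiated populations manufactures heterozygote deficits
   (the Wahlund effect) that look like HWE failures.

Separately from QC, variants with HWE p < 1e−6 *and* FST > 0.2 are
flagged — not removed — as joint HWE-deviation/divergence selection
candidates: a sweep near fixation distorts genotype proportions in a way
that mimics technical HWE failure but co-occurs with high divergence.

## Frequency statistics

**DAF** is the derived-allele fraction among non-missing haplotypes of one
population. **ΔDAF** is the difference between the target population and a
reference; `mean` and `min` modes aggregate over several references (the
`min` mode is the most conservative: the enrichment surviving against the
closest reference). **FST** is the Weir & Cockerham (1984) two-population
θ̂ = a/(a+b+c) from the variance components computed on genotype counts;
estimates are left unclamped (negative values carry information about the
finite-sample null) and are undefined when both populations are
monomorphic. A Hudson-style estimator (1 − Hw/Hb) is provided as an
independent cross-check output only.

**Exact HWE test.** Conditional on the observed allele counts, every
compatible heterozygote count h has probability
P(h) ∝ n! / (n_AA! h! n_aa!) · 2^h; the p-value sums P(h) over all h with
P(h) ≤ P(observed) (two-sided mode test). Computed in log-space with a
normalizing sum, and tested against exact rational enumeration.

## Haplotype statistics

**EHH** at offset x from a core variant is the probability that two
randomly drawn carrier haplotypes are identical at every marker from the
core out to x, computed by incremental partition refinement. A missing
call makes a haplotype a permanent singleton (conservative: missing data
can only destroy homozygosity, never create it). Curves are truncated
once EHH < 0.05 (configurable); the terminal sub-threshold point is kept
as the curve's endpoint.

**iHS** integrates the ancestral- and derived-carrier EHH curves over
physical distance (trapezoids; no genetic map) in both directions:
unstandardized iHS = ln(iHH_A/iHH_D), then standardized within
equal-count derived-frequency bins (50 by default). A core is unusable
when its polarity is unknown, its minor allele frequency is below 0.05,
either carrier class has fewer than two haplotypes, or an EHH curve
reaches a data edge while still above the truncation threshold — the last
rule generalizes the practice of excluding variants whose haplotype
homozygosity never decays inside the available data.

The bin count is reduced so that every bin holds at least 20 scores.
With only a few scores per bin the bin mean tracks the extreme scores
themselves and standardization would subtract the very signal it is meant
to calibrate; 20 per bin keeps the bin mean a stable null estimate while
preserving frequency-dependence correction.

**XPEHH** compares pooled-carrier EHH between two populations at the same
core: ln(iHH_pop1/iHH_pop2), standardized genome-wide (single mean/sd),
positive when the target population carries the longer haplotypes. The
pooled identity tracks flanking markers only (the core allele is not part
of the identity word), which keeps EHH(0) = 1 for every emitted curve; the
sign convention and decay behaviour match the usual cross-population
statistic. Cores where either population's curve fails to decay before an
edge, or where either integral is zero, are reported missing.

**LD.** Pairwise r² is D²/(p₁q₁p₂q₂) from phased haplotype frequencies
over pairwise-complete haplotypes; the LD-decay curve averages r² in
distance bins (1 kb by default, up to 500 kb). No maximum-gap rule is
applied between adjacent markers (`gap_policy: none` is echoed in the run
manifest).

## Window statistics

Windows of 50 kb advancing by 10 kb (both configurable; the window
parameters are a package default, chosen as round numbers at the scale of
the haplotype statistics' reach) tile the observed positions. Per window:
S, θπ (pairwise), θW (Watterson), θH (homozygosity estimator), Tajima's D
with the standard constants, and unnormalized Fay & Wu's H = θπ − θH.
The unnormalized form is used because its magnitude grows with window
diversity, matching the large negative regional values this class of scan
reports; regional summaries report the signed minimum (most negative) H
and D over a query region.

**Simulation p-values.** The null for a window statistic is the fixed-S
Hudson coalescent without recombination, matched on n and S, with the
add-one estimator p = (1 + #{sim ≤ obs})/(reps + 1). Two caveats are
deliberate and documented: conditioning on S (rather than θ) makes the
null conservative and slightly shifts expectations — the true fixed-S
mean of Tajima's D at n=20, S=30 is ≈ −0.10, not 0 (verified against an
independent tree-based oracle) — and the absence of recombination makes
window statistics over-dispersed under the null, again conservative.

## CMS and candidate nomination

Each of the four components — FST, ΔDAF(target−comparator), |iHS|,
XPEHH — is converted to an empirical rank p-value, p = rank/N with rank 1
the most extreme in the adaptive direction, and
CMS = Σ −log₁₀ p. This monotone rank combination is bounded by
4·log₁₀(N) and is this package's documented stand-in for Bayes-factor
composite scores; realized thresholds are data-set specific and not
comparable across cohorts. |iHS| is used because a sweep can ride either
allele polarity; the direction is resolved later by the enrichment
filter. A variant missing any component receives no CMS.

Nomination proceeds: top ⌈N·q⌉ variants by CMS (q = 1‰ by default; ties
broken by FST then position, deterministically) → keep only candidates
whose target-enriched allele (the allele more frequent in the target than
in the comparator population) is *strictly* more frequent in the target
than in every reference population → greedy LD clumping (highest-CMS
unassigned candidate becomes a lead; unassigned candidates within 500 kb
and with r² > 0.2 to the lead join its region; unavailable r² counts as
independence) → the lead gene of each region is the gene nearest the lead
variant, preferring genes whose flanked region (body ± 5 kb) contains it,
with midpoint distance then lexicographic name as tie-breaks.

The SV screen keeps structural variants whose target frequency exceeds
every reference frequency by strictly more than 0.20 (signed divergence:
only target-enriched SVs pass).

## The synthetic-data generator

`simulate_two_pop_sweep` emulates the study design the scan assumes: an
ancestral pool of 2N haplotypes over m standing segregating sites (drawn
from the fixed-S coalescent; no new mutation afterwards, so truth
bookkeeping is exact), split into two Wright–Fisher populations of N
diploids evolving T_split generations with Poisson(r·L) crossovers per
transmitted gamete, and additive selection (fitnesses 1, 1+s, 1+2s) on
the derived allele of one chosen site in the target population from the
split onward.

Defaults are the scaled-down study conditions used throughout the tests:
N = 200 diploids, L = 1 Mb, m = 2000 sites, T_split = 200 generations,
s = 0.1, samples of 100 diploids per population. The recombination rate
default r = 5e−7 /bp/generation preserves the *population-scaled*
recombination rate ρ = 4NrL ≈ 400 per Mb that a human-sized population
(N_e ≈ 10⁴, r ≈ 1.25e−8) has, so haplotype homozygosity decays within
the region roughly as it does in real data. Note the same scaling cannot
be applied to the split time: T_split/2N = 0.5 here, versus ~0.01–0.03
for recently diverged human populations, so the drift component of
frequency divergence is far stronger in these simulations than in the
study system (see Limitations).

**Saturating advantage.** Taken literally, s = 0.1 acting for 200
generations fixes the derived allele by ~generation 120; a fixed core has
no ancestral carriers, so iHS — and hence the composite score — is
undefined exactly at the site the recovery tests need to find. Real
high-altitude sweeps are incomplete (the flagship variant frequency in
the adapted population is ~0.80). The generator therefore treats the
advantage as saturating at `freeze_freq` (default 0.80): the derived
allele is favoured (+s) below that frequency and disfavoured (−s) above
it, an intermediate-optimum model consistent with the antagonistic costs
thought to keep such alleles polymorphic. The sampled frequency then
hovers near 0.8 in every run. Runs in which the selected allele is lost,
or no longer segregates in the target population or sample at sampling,
are resimulated on the same random stream with the attempt count
recorded; for neutral (s = 0) runs the marked coordinate is instead
re-matched post hoc to the nearest site still segregating, which is the
same ascertainment without the wasted replicates.

A toy gene model (2-kb bodies every 50 kb) tiles the region so that
lead-gene assignment can be tested against the gene nearest the true
site.

`simulate_neutral_coalescent` provides the fixed-S null: Kingman
genealogies with mutations placed on branches proportionally to length.
Note that fixed-S sampling weights each tree equally regardless of its
total length, so the expected SFS is E[ℓᵢ/ℓ_tot] — close to, but not
exactly, the classical (1/i)/H spectrum; the generator is validated
against an independent tree-based oracle rather than against the
closed form.

## What passing tests do and do not show

The simulations reproduce the *structure* of the study data (two phased
populations with a recent incomplete sweep, standing variation,
recombination, matched neutral controls) but not its scale: real cohorts
have thousands of samples, millions of variants, weak genome-wide drift
(FST ≈ 0.01–0.1) and fine marker spacing. At the scaled-down conditions
the drift null is extremely heavy-tailed (T_split/2N = 0.5), and
frequency-divergence outliers produced by drift alone compete with the
sweep signal at the top of the CMS ranking; recovery rates measured here
therefore understate what the same pipeline achieves on real-scale data,
where the drift null is orders of magnitude tighter. Passing calibration
tests show the statistics and their normalizations are internally
correct, not that the scan's error rates on real data equal those in the
simulations.

## Numerical choices

- HWE: log-space probabilities normalized by their sum; tie comparison
  P(h) ≤ P(obs)·(1+1e−12) to make floating-point ties deterministic.
- EHH: partition refinement with bincount relabelling; exact equality
  with brute-force string grouping is property-tested.
- Rank p-values use average ranks for ties; all orderings that feed
  selection (top quantile, clumping) break ties by CMS, then FST
  descending, then position ascending, so reruns are byte-identical.
- Degenerate inputs: empty carrier classes, monomorphic pairs and empty
  windows yield missing values (NA in TSV output), never zeros.

## Known limitations

- Two populations only in the generator (no migration, growth or
  admixture); FST is the two-population estimator.
- No genetic map: physical distance stands in for recombination distance
  in the EHH integrals.
- The rank-sum CMS is not the Bayes-factor composite of the original
  formulation; thresholds such as "top 1‰ score > 7.66" are not
  transferable numbers.
- The fixed-S null for window statistics ignores recombination
  (conservative over-dispersion).
- The heterozygosity-ratio statistic sometimes reported alongside these
  scans lacks an unambiguous definition and is not implemented.
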