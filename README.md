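# tsnscan

Selective-sweep scanning and candidate nomination for phased
two-population cohorts — the workflow used to find recent positive
selection in high-altitude human populations, packaged as a tested,
reusable library with a command-line interface and a forward-simulation
module that generates its own matched test data.

`tsnscan` is for population geneticists who have a phased multi-sample
VCF with ancestral-allele annotation, a sample→population panel and a
gene model, and want to go from raw haplotypes to a ranked list of
independent selection signals with lead genes.

## What it computes

**Per-variant statistics.** Derived allele frequency (DAF) per
population and its between-population difference ΔDAF; Weir & Cockerham
(1984) F_ST between the target and a comparator population; the exact
conditional Hardy–Weinberg test (both as a QC screen at p < 10⁻¹⁰ and,
jointly with F_ST > 0.2 at p < 10⁻⁶, as a selection signal); the
integrated haplotype score iHS = ln(iHH_A/iHH_D), standardized within
derived-frequency bins; and the cross-population statistic
XPEHH = ln(iHH_pop1/iHH_pop2), standardized genome-wide. EHH curves are
truncated at 0.05 and integrated by trapezoids over physical distance.

**Composite score and nomination.** Each component (F_ST, ΔDAF, |iHS|,
XPEHH) becomes an empirical rank p-value p = rank/N, and

    CMS = −log₁₀ p_FST − log₁₀ p_ΔDAF − log₁₀ p_|iHS| − log₁₀ p_XPEHH .

The top 1‰ of CMS scores are candidates; candidates whose target-enriched
allele is strictly more frequent in the target than in *every* reference
population survive the enrichment filter; survivors are clumped into
independent signal regions (r² > 0.2 within ±500 kb of the strongest
unassigned candidate, greedily), and each region's lead gene is the gene
(body ± 5 kb) nearest its lead variant. A parallel screen keeps
structural variants whose target frequency exceeds every reference by
more than 20 points.

**Window statistics.** Sliding-window Tajima's D and unnormalized
Fay & Wu's H = θπ − θH, with lower-tail p-values simulated from a
fixed-S neutral coalescent matched on sample size and segregating sites.

**Synthetic data.** A forward Wright–Fisher simulator of two populations
split from a common ancestral pool, with recombination and a saturating
additive advantage on one standing variant in the target population —
producing the incomplete sweeps (≈0.8 sampled frequency) that this class
of scan detects — plus matched neutral controls and ground-truth records.
See `docs/methods.md` for the model and its limitations.

## Worked example

Simulate a sweep dataset (1-Mb region, 2000 standing sites, N = 200
diploids per population, s = 0.1 since the split 200 generations ago,
100 diploids sampled per population), then scan it:

```sh
tsnscan simulate --preset sweep --seed 4 --out demo
# sweep simulation written to demo (selected site 499253,
#   target-sample frequency 0.820, attempts 1)

tsnscan scan --vcf demo/sim.vcf --panel demo/panel.tsv \
    --genes demo/genes.bed --target POP1 --refs POP2 \
    --q 0.01 --seed 4 --out demo_scan
# scan complete: 3 TSNS in 2 regions (CMS threshold 3.923);
#   outputs in demo_scan
```

`demo_scan/regions.tsv` then reads:

```
region_id  lead_pos  lead_cms  n_members  span_start  span_end  lead_gene
1          499253    5.0717    1          499253      499253    GENE010
2          604085    4.1178    2          594467      604085    GENE013
```

The top region's lead variant is exactly the simulated selected site
(`demo/truth.json`: selected_pos 499253, true gene GENE010, sampled
frequency 0.82): the sweep was found, localized, and assigned to the
right gene. The second region is a drift signal — at this deliberately
small population size the drift null is heavy-tailed, which is why
region 2 exists and why recovery is not guaranteed in every replicate
(quantified in `docs/methods.md`). `demo_scan/stats.tsv` holds every
per-variant statistic, rank p-value and flag; `manifest.json` echoes the
full configuration, per-stage counts and seed, and reruns are
byte-identical.

The same stages are available as library calls (`tsnscan.run_full_scan`,
`tsnscan.ihs`, `tsnscan.wc_fst`, `tsnscan.hwe_exact_test`, …) and as the
`stats`, `windows` and `tesv` subcommands.

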