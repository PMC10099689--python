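"""Synthetic inputs: coalescent null samples, forward two-population sweep
simulations, and small worked-example fixtures.

The sweep generator emulates the study design the scan assumes: two
populations of constant diploid size ``N`` descend from a common ancestral
pool, and from the split onward the derived allele at one chosen site is
additively advantageous in the target population only.  Because the
detection statistics (iHS in particular) are undefined at a monomorphic
core, the advantage saturates: selection acts only while the derived
allele is below ``freeze_freq`` in the target population and switches off
above it, so the frequency rises quickly and then hovers near the
saturation value instead of fixing.  This produces the incomplete sweeps
(sampled frequency ~0.8) that high-altitude adaptation studies actually
observe, rather than completed ones.  Runs in which the selected
allele is lost, or is no longer segregating in the target population or
sample at sampling time, are resimulated on the same random stream and the
attempt count is recorded in the truth record.

No new mutation occurs during the forward phase (standing variation only),
so the site set is fixed and truth bookkeeping is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ANC_REF,
    GENE_COLUMNS,
    GeneModel,
    HaplotypeMatrix,
    PopulationPanel,
    write_phased_vcf,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# fixed-S Hudson coalescent (no recombination)
# ---------------------------------------------------------------------------

def simulate_neutral_coalescent(n: int, S: int, reps: int = 1, seed=None, rng=None):
    """Neutral fixed-S coalescent haplotype samples.

    For each replicate a Kingman genealogy of ``n`` lineages is drawn
    (exponential waiting times with rate k(k-1)/2 in coalescent units) and
    ``S`` mutations are placed on branches with probability proportional to
    branch length; leaves below a mutated branch carry the derived allele.

    Returns
    -------
    ndarray of int8, shape (reps, n, S)
        0 = ancestral, 1 = derived.  Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if S < 1:
        raise ValueError("need at least 1 segregating site")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.zeros((reps, n, S), dtype=np.int8)
    for rep in range(reps):
        # active lineages: (leaf-index list, accumulated branch length)
        leafsets = [[i] for i in range(n)]
        lengths = [0.0] * n
        done_sets, done_lens = [], []
        k = n
        while k > 1:
            t = rng.exponential(2.0 / (k * (k - 1)))
            for i in range(k):
                lengths[i] += t
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            done_sets.append(leafsets[i])
            done_lens.append(lengths[i])
            done_sets.append(leafsets[j])
            done_lens.append(lengths[j])
            merged = leafsets[i] + leafsets[j]
            leafsets[i] = merged
            lengths[i] = 0.0
            leafsets.pop(j)
            lengths.pop(j)
            k -= 1
        lens = np.asarray(done_lens)
        branch = rng.choice(len(done_sets), size=S, p=lens / lens.sum())
        for s_idx, b in enumerate(branch):
            out[rep, done_sets[b], s_idx] = 1
    return out


# ---------------------------------------------------------------------------
# forward Wright-Fisher two-population sweep
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Parameters of the two-population sweep simulation.

    Defaults are the scaled-down study conditions used throughout the test
    suite: N=200 diploids per population, a 1-Mb region with 2000 standing
    segregating sites, a 200-generation split, and an additive advantage
    s=0.1 for the derived allele of the chosen site in the target
    population.  The recombination rate default r=5e-7 /bp/generation keeps
    the population-scaled rate rho = 4*N*r*L of the region at the value a
    human-sized population (N_e ~ 1e4, r ~ 1.25e-8) would have, so haplotype
    homozygosity decays within the region as it does in real data.
    """

    N: int = 200
    L: int = 1_000_000
    m: int = 2000
    r: float = 5e-7
    T_split: int = 200
    s: float = 0.1
    n1: int = 100
    n2: int = 100
    seed: int = 0
    freeze_freq: float = 0.8
    sel_init_freq: float = 0.1
    sel_pos: int | None = None
    chrom: str = "chr1"
    pop_labels: tuple = ("POP1", "POP2")
    gene_spacing: int = 50_000
    gene_body: int = 2_000
    max_attempts: int = 200

    def validate(self) -> None:
        if self.N < 10:
            raise ValueError("N must be >= 10")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("s must be in [0, 1]")
        if not (0 < self.m <= self.L):
            raise ValueError("m must satisfy 0 < m <= L")
        if self.n1 > self.N or self.n2 > self.N:
            raise ValueError("sample sizes must not exceed N")
        if not (0.0 < self.freeze_freq <= 1.0):
            raise ValueError("freeze_freq must be in (0, 1]")
        if self.T_split < 1:
            raise ValueError("T_split must be >= 1")
        if self.r < 0:
            raise ValueError("r must be >= 0")


@dataclass
class SweepTruth:
    """Ground truth written alongside every simulated dataset."""

    chrom: str
    selected_pos: int
    s: float
    T_split: int
    freeze_freq: float
    seed: int
    attempts: int
    init_freq: float
    final_freq_target_pop: float
    final_freq_sister_pop: float
    final_freq_target_sample: float
    final_freq_sister_sample: float
    true_gene: str
    paths: dict = field(default_factory=dict)


@dataclass
class SweepSimResult:
    hm: HaplotypeMatrix
    panel: PopulationPanel
    genes: GeneModel
    truth: SweepTruth


def _toy_gene_table(chrom: str, L: int, spacing: int, body: int, flank: int = 5000):
    rows = []
    k = 0
    while (k + 1) * spacing <= L:
        start0 = k * spacing + (spacing - body) // 2  # BED 0-based
        end0 = start0 + body
        body_start, body_end = start0 + 1, end0
        rows.append(
            {
                "gene": f"GENE{k + 1:03d}",
                "chrom": chrom,
                "body_start": body_start,
                "body_end": body_end,
                "strand": "+",
                "region_start": max(1, body_start - flank),
                "region_end": body_end + flank,
            }
        )
        k += 1
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _nearest_gene(table: pd.DataFrame, pos: int) -> str:
    dist = np.maximum(table["body_start"] - pos, 0) + np.maximum(
        pos - table["body_end"], 0
    )
    order = np.lexsort((table["gene"].to_numpy(), dist.to_numpy()))
    return str(table["gene"].iloc[order[0]])


def _transmit(pop_haps, parent, start_hap, positions, L, r, rng):
    """One gamete per parent: copy one haplotype, apply Poisson crossovers."""
    base = pop_haps[2 * parent + start_hap]
    n_cross = rng.poisson(r * L, size=parent.shape[0])
    rows = np.nonzero(n_cross)[0]
    out = base.copy()
    if rows.size == 0:
        return out
    # padded breakpoint matrix; inf pads never switch parity
    cmax = int(n_cross[rows].max())
    bps = np.full((rows.size, cmax), np.inf)
    for j, i in enumerate(rows):
        bps[j, : n_cross[i]] = rng.uniform(0.0, L, n_cross[i])
    parity = (bps[:, None, :] < positions[None, :, None]).sum(axis=2) % 2
    other = pop_haps[2 * parent[rows] + 1 - start_hap[rows]]
    out[rows] = np.where(parity == 0, base[rows], other)
    return out


def _next_generation(pop_haps, positions, L, r, sel_idx, s_eff, rng):
    """Wright-Fisher resampling with recombination and additive selection."""
    N = pop_haps.shape[0] // 2
    if s_eff != 0.0:
        dosage = pop_haps[0::2, sel_idx].astype(np.float64) + pop_haps[
            1::2, sel_idx
        ].astype(np.float64)
        w = 1.0 + s_eff * dosage
        p = w / w.sum()
    else:
        p = None
    children = np.empty_like(pop_haps)
    for slot in (0, 1):  # maternal / paternal gamete
        parent = rng.choice(N, size=N, p=p)
        start = rng.integers(0, 2, size=N)
        children[slot::2] = _transmit(pop_haps, parent, start, positions, L, r, rng)
    return children


def _choose_selected_site(freqs, positions, L, target_freq):
    """Site with initial frequency near ``target_freq``, nearest the centre."""
    lo, hi = 0.5 * target_freq, 1.5 * target_freq
    cand = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    if cand.size == 0:
        cand = np.argsort(np.abs(freqs - target_freq))[:20]
    centre_dist = np.abs(positions[cand] - L // 2)
    return int(cand[np.argmin(centre_dist)])


def simulate_two_pop_sweep(params: SimParams, out_dir=None) -> SweepSimResult:
    """Simulate two phased populations with a recent sweep in the target one.

    An ancestral pool of 2N haplotypes over ``m`` uniformly placed sites is
    drawn from the fixed-S coalescent; both daughter populations then evolve
    ``T_split`` generations of Wright-Fisher resampling with recombination
    (Poisson(r*L) crossovers per transmitted haplotype, uniform breakpoints)
    and fitnesses 1, 1+s, 1+2s by derived-allele dosage at the selected site
    in the target population (population 1).  See the module docstring for
    the saturating-advantage and resimulation-conditioning rules.

    When ``out_dir`` is given, writes ``sim.vcf``, ``panel.tsv``,
    ``genes.bed`` and ``truth.json`` there.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L, m, N = params.L, params.m, params.N

    positions = np.sort(rng.choice(L, size=m, replace=False)) + 1
    pool = simulate_neutral_coalescent(2 * N, m, reps=1, rng=rng)[0]
    pool_freq = pool.mean(axis=0)
    if params.sel_pos is not None:
        sel_idx = int(np.argmin(np.abs(positions - params.sel_pos)))
    else:
        sel_idx = _choose_selected_site(pool_freq, positions, L, params.sel_init_freq)
    init_freq = float(pool_freq[sel_idx])

    attempts = 0
    while True:
        attempts += 1
        if attempts > params.max_attempts:
            raise RuntimeError(
                f"selected allele never segregated at sampling after "
                f"{params.max_attempts} attempts"
            )
        pop1 = pool.copy()
        pop2 = pool.copy()
        lost = False
        for _ in range(params.T_split):
            # saturating advantage with a cost above the optimum: the
            # derived allele is favoured below freeze_freq and disfavoured
            # above it, so the sweep rises fast then hovers there
            f1 = pop1[:, sel_idx].mean()
            s_eff = params.s if f1 < params.freeze_freq else -params.s
            pop1 = _next_generation(
                pop1, positions, L, params.r, sel_idx, s_eff, rng
            )
            pop2 = _next_generation(pop2, positions, L, params.r, sel_idx, 0.0, rng)
            if params.s > 0 and pop1[:, sel_idx].mean() == 0.0:
                lost = True
                break
        if lost:
            continue
        idx1 = rng.choice(N, size=params.n1, replace=False)
        idx2 = rng.choice(N, size=params.n2, replace=False)
        hap1 = pop1[np.stack([2 * idx1, 2 * idx1 + 1], axis=1).ravel()]
        hap2 = pop2[np.stack([2 * idx2, 2 * idx2 + 1], axis=1).ravel()]

        def _segregating(idx):
            return (0.0 < pop1[:, idx].mean() < 1.0) and (
                0.0 < hap1[:, idx].mean() < 1.0
            )

        if _segregating(sel_idx):
            break
        if params.s == 0.0:
            # matched neutral run: the coordinate only marks where the
            # sweep would have been, so re-match it to the nearest site
            # still segregating in the target population and sample
            f_pop = pop1.mean(axis=0)
            f_sam = hap1.mean(axis=0)
            seg = np.nonzero((f_pop > 0) & (f_pop < 1) & (f_sam > 0) & (f_sam < 1))[0]
            if seg.size:
                sel_idx = int(seg[np.argmin(np.abs(positions[seg] - positions[sel_idx]))])
                init_freq = float(pool_freq[sel_idx])
                break
        # otherwise resimulate on the same stream (recorded in attempts)

    calls = np.concatenate([hap1, hap2], axis=0).T.astype(np.int8)  # variants x haps
    keep = (calls.max(axis=1) == 1) & (calls.min(axis=1) == 0)
    sel_pos = int(positions[sel_idx])

    label1, label2 = params.pop_labels
    ids1 = [f"{label1}_{k + 1:03d}" for k in range(params.n1)]
    ids2 = [f"{label2}_{k + 1:03d}" for k in range(params.n2)]
    sample_ids = ids1 + ids2

    ref = _BASES[rng.integers(0, 4, size=m)]
    alt_shift = rng.integers(1, 4, size=m)
    alt = _BASES[(np.char.find("ACGT", ref.astype("U1")) + alt_shift) % 4]

    hm = HaplotypeMatrix(
        chrom=params.chrom,
        positions=positions[keep],
        ref_allele=ref[keep].astype(object),
        alt_allele=alt[keep].astype(object),
        ancestral=np.full(int(keep.sum()), ANC_REF, dtype=np.int8),
        calls=calls[keep],
        sample_ids=sample_ids,
    )
    panel = PopulationPanel(
        {**{s: label1 for s in ids1}, **{s: label2 for s in ids2}}
    )
    gene_table = _toy_gene_table(
        params.chrom, L, params.gene_spacing, params.gene_body
    )
    genes = GeneModel(table=gene_table, flank=5000)

    truth = SweepTruth(
        chrom=params.chrom,
        selected_pos=sel_pos,
        s=params.s,
        T_split=params.T_split,
        freeze_freq=params.freeze_freq,
        seed=params.seed,
        attempts=attempts,
        init_freq=init_freq,
        final_freq_target_pop=float(pop1[:, sel_idx].mean()),
        final_freq_sister_pop=float(pop2[:, sel_idx].mean()),
        final_freq_target_sample=float(hap1[:, sel_idx].mean()),
        final_freq_sister_sample=float(hap2[:, sel_idx].mean()),
        true_gene=_nearest_gene(gene_table, sel_pos),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcf = out / "sim.vcf"
        panel_path = out / "panel.tsv"
        bed = out / "genes.bed"
        truth_path = out / "truth.json"
        write_phased_vcf(hm, vcf)
        with open(panel_path, "w", newline="\n") as fh:
            fh.write("sample_id\tpopulation\n")
            for sid, pop in panel.assignments.items():
                fh.write(f"{sid}\t{pop}\n")
        with open(bed, "w", newline="\n") as fh:
            for _, row in gene_table.iterrows():
                fh.write(
                    f"{row.chrom}\t{row.body_start - 1}\t{row.body_end}\t"
                    f"{row.gene}\t0\t{row.strand}\n"
                )
        truth.paths = {
            "vcf": str(vcf),
            "panel": str(panel_path),
            "genes": str(bed),
            "truth": str(truth_path),
        }
        with open(truth_path, "w", newline="\n") as fh:
            json.dump(asdict(truth), fh, indent=2)
            fh.write("\n")

    return SweepSimResult(hm=hm, panel=panel, genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# hand-worked fixtures
# ---------------------------------------------------------------------------

#: per-population derived-allele frequencies of published highly enriched
#: missense variants (columns: TBN, CHB, JPT, CEU, YRI), used as worked
#: examples for the frequency-difference statistics.
ENRICHED_MISSENSE_ROWS = [
    ("1", 231557623, "rs186996510", "EGLN1", 15.63, 0.53, 0.70, 0.03, 0.06, 0.00, 0.00),
    ("2", 46707674, "rs116983452", "TMEM247", 14.16, 0.54, 0.70, 0.02, 0.04, 0.00, 0.00),
    ("2", 46707886, "rs12612916", "TMEM247", 12.22, 0.32, 0.85, 0.51, 0.54, 0.04, 0.12),
    ("1", 231488524, "rs2437150", "SPRTN", 11.66, 0.23, 0.78, 0.46, 0.48, 0.39, 0.56),
    ("15", 28197037, "rs1800414", "OCA2", 9.76, 0.51, 0.11, 0.59, 0.59, 0.12, 0.11),
    ("1", 42898843, "rs1034268", "ZMYND12", 8.90, 0.17, 0.66, 0.36, 0.48, 0.35, 0.46),
    ("2", 46706765, "rs192690066", "TMEM247", 8.85, 0.16, 0.26, 0.00, 0.00, 0.00, 0.00),
    ("4", 100574821, "rs79703522", "RP11-766F14.2", 8.41, 0.27, 0.87, 0.44, 0.42, 0.14, 0.12),
    ("7", 38284804, "rs4629747", "TRGC2", 8.37, 0.20, 0.39, 0.06, 0.06, 0.07, 0.02),
    ("4", 100239319, "rs1229984", "ADH1B", 8.11, 0.56, 0.86, 0.29, 0.27, 0.02, 0.00),
    ("2", 61385105, "rs1729671", "SANBR", 8.03, 0.21, 0.92, 0.70, 0.65, 0.61, 0.58),
    ("2", 61385100, "rs1665258", "SANBR", 7.72, 0.21, 0.92, 0.70, 0.65, 0.61, 0.58),
    ("12", 113376388, "rs1859330", "OAS3", 7.69, 0.22, 0.92, 0.70, 0.84, 0.62, 0.54),
    ("19", 8000104, "rs3745387", "TIMM44", 7.67, 0.13, 0.73, 0.48, 0.49, 0.44, 0.69),
]

#: top selection signals with Tibetan-enriched-allele (TEA) frequencies.
TOP_SIGNAL_ROWS = [
    ("2", 46589032, "rs74898705", "T", "EPAS1", 17.86, 0.68, 0.80, 0.01, 0.00, 0.03, 0.16),
    ("1", 231557623, "rs186996510", "C", "EGLN1", 15.63, 0.53, 0.70, 0.03, 0.05, 0.00, 0.00),
    ("6", 32629955, "rs1063321", "T", "HLA_DQB1", 13.26, 0.27, 0.82, 0.46, 0.52, 0.39, 0.29),
    ("12", 129084774, "rs7486929", "A", "TMEM132C", 12.71, 0.29, 0.90, 0.60, 0.56, 0.52, 0.57),
    ("3", 194151467, "rs79377418", "A", "ATP13A3", 11.72, 0.13, 0.32, 0.00, 0.02, 0.11, 0.10),
    ("2", 241627775, "rs5751069", "C", "L3MBTL2", 11.60, 0.29, 0.91, 0.61, 0.78, 0.66, 0.45),
    ("2", 61330217, "rs1729672", "A", "SANBR", 11.33, 0.30, 0.94, 0.68, 0.71, 0.72, 0.88),
    ("20", 753310, "rs6117562", "G", "SLC52A3", 11.14, 0.47, 0.97, 0.64, 0.58, 0.77, 0.67),
    ("6", 62431522, "rs12208789", "A", "KHDRBS2", 10.70, 0.42, 0.91, 0.51, 0.50, 0.57, 0.81),
    ("12", 120434838, "rs11064986", "T", "BICDL1", 10.70, 0.27, 0.83, 0.47, 0.46, 0.81, 0.47),
]

REFERENCE_POPS = ("CHB", "JPT", "CEU", "YRI")


def enriched_missense_table() -> pd.DataFrame:
    """Worked-example table of published enriched missense variants (DAF)."""
    return pd.DataFrame(
        ENRICHED_MISSENSE_ROWS,
        columns=["chrom", "pos", "snv", "gene", "cms", "fst",
                 "daf_TBN", "daf_CHB", "daf_JPT", "daf_CEU", "daf_YRI"],
    )


def top_signal_table() -> pd.DataFrame:
    """Worked-example table of top selection signals (TEA frequencies)."""
    return pd.DataFrame(
        TOP_SIGNAL_ROWS,
        columns=["chrom", "pos", "snv", "tea", "gene", "cms", "fst",
                 "freq_TBN", "freq_CHB", "freq_JPT", "freq_CEU", "freq_YRI"],
    )


def qc_toy_matrix() -> HaplotypeMatrix:
    """40-sample, 10-variant QC toy.

    Variants 1-2 are singletons (minor allele count 1), variant 3 has 5%
    missing genotypes, variant 4 has an extreme heterozygote excess (every
    sample heterozygous; exact Hardy-Weinberg p far below 1e-10), variants
    5-10 are clean with genotype counts close to Hardy-Weinberg proportions.
    """
    n_samples = 40
    n_hap = 2 * n_samples
    rng = np.random.default_rng(20240915)
    calls = np.zeros((10, n_hap), dtype=np.int8)
    calls[0, 7] = 1                      # singleton
    calls[1, 60] = 1                     # singleton
    # variant 3: frequency ~0.25, two samples with missing genotypes (5%)
    calls[2, :40] = np.tile([0, 1], 20)
    calls[2, 0:4] = -1
    # variant 4: every sample heterozygous
    calls[3, 0::2] = 0
    calls[3, 1::2] = 1
    # variants 5-10: Hardy-Weinberg draws at p=0.5
    calls[4:10] = (rng.random((6, n_hap)) < 0.5).astype(np.int8)
    # guard against accidental singletons/monomorphism in the clean block
    for v in range(4, 10):
        if calls[v].sum() < 2:
            calls[v, :2] = 1
        if calls[v].sum() > n_hap - 2:
            calls[v, :2] = 0
    positions = np.arange(1, 11) * 1000
    return HaplotypeMatrix(
        chrom="chr1",
        positions=positions,
        ref_allele=np.array(list("ACGTACGTAC"), dtype=object),
        alt_allele=np.array(list("GTACGTACGT"), dtype=object),
        ancestral=np.zeros(10, dtype=np.int8),
        calls=calls,
        sample_ids=[f"S{k + 1:03d}" for k in range(n_samples)],
    )


#: 8-haplotype x 7-marker worked fixture for the haplotype-homozygosity
#: statistics; the core is the 4th marker (position 5000), with haplotypes
#: 0-3 carrying the derived allele.  All ancestral states are the reference
#: allele.  Rows are variants, columns haplotypes.
EHH_FIXTURE_CALLS = [
    [0, 0, 0, 1, 0, 0, 0, 0],
    [0, 1, 0, 0, 0, 1, 0, 1],
    [0, 0, 1, 0, 1, 1, 0, 0],
    [1, 1, 1, 1, 0, 0, 0, 0],
    [0, 0, 1, 1, 0, 0, 0, 1],
    [0, 1, 1, 1, 0, 1, 0, 0],
    [0, 0, 0, 1, 0, 1, 1, 0],
]

EHH_FIXTURE_POSITIONS = [1000, 2000, 3500, 5000, 6500, 8000, 10000]
EHH_FIXTURE_CORE = 3


def ehh_fixture_matrix() -> HaplotypeMatrix:
    """The 8-haplotype hand-worked fixture as a :class:`HaplotypeMatrix`."""
    return HaplotypeMatrix(
        chrom="chr1",
        positions=np.array(EHH_FIXTURE_POSITIONS, dtype=np.int64),
        ref_allele=np.array(list("ACGTACG"), dtype=object),
        alt_allele=np.array(list("TACGTAC"), dtype=object),
        ancestral=np.zeros(7, dtype=np.int8),
        calls=np.array(EHH_FIXTURE_CALLS, dtype=np.int8),
        sample_ids=[f"S{k + 1}" for k in range(4)],
    )


#: SV screen toy: sv_id, chrom, pos, type, then target (TBN) and reference
#: frequencies.  Rows sv1 (the known highly diverged deletion, 0.707 vs
#: 0.07 in the sister population), sv2 and sv3 pass the 20% divergence
#: screen; sv4 sits exactly at 0.20 divergence and must be dropped.
SV_TOY_ROWS = [
    ("sv1", "2", 46588000, "DEL", 0.707, 0.07, 0.05, 0.00, 0.01),
    ("sv2", "8", 110374000, "DEL", 0.495, 0.23, 0.22, 0.18, 0.10),
    ("sv3", "5", 1200000, "INS", 0.60, 0.30, 0.25, 0.35, 0.38),
    ("sv4", "1", 500000, "DEL", 0.50, 0.30, 0.10, 0.10, 0.10),
    ("sv5", "3", 750000, "DUP", 0.40, 0.35, 0.30, 0.30, 0.30),
    ("sv6", "4", 900000, "INV", 0.10, 0.05, 0.05, 0.05, 0.05),
    ("sv7", "6", 1100000, "INS", 0.80, 0.75, 0.70, 0.65, 0.60),
    ("sv8", "7", 1300000, "DEL", 0.25, 0.30, 0.20, 0.15, 0.10),
    ("sv9", "9", 1500000, "INS", 0.33, 0.20, 0.25, 0.30, 0.12),
    ("sv10", "10", 1700000, "DEL", 0.05, 0.50, 0.40, 0.30, 0.20),
]


def sv_toy_table() -> pd.DataFrame:
    return pd.DataFrame(
        SV_TOY_ROWS,
        columns=["sv_id", "chrom", "pos", "sv_type",
                 "freq_TBN", "freq_CHB", "freq_JPT", "freq_CEU", "freq_YRI"],
    )


def make_fixtures(out_dir) -> Path:
    """Write all hand-worked fixture files; byte-identical on every call.

    Writes the enriched-variant and top-signal frequency tables, the
    10-variant QC toy VCF, the 8-haplotype homozygosity fixture (TSV), and
    the SV screen toy table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enriched_missense_table().to_csv(
        out / "enriched_missense.tsv", sep="\t", index=False, lineterminator="\n"
    )
    top_signal_table().to_csv(
        out / "top_signals.tsv", sep="\t", index=False, lineterminator="\n"
    )
    write_phased_vcf(qc_toy_matrix(), out / "qc_toy.vcf")
    ehh = ehh_fixture_matrix()
    with open(out / "ehh_fixture.tsv", "w", newline="\n") as fh:
        fh.write("pos\t" + "\t".join(f"hap{h}" for h in range(8)) + "\n")
        for v in range(ehh.n_variants):
            fh.write(
                f"{ehh.positions[v]}\t"
                + "\t".join(str(int(c)) for c in ehh.calls[v])
                + "\n"
            )
    sv_toy_table().to_csv(
        out / "sv_toy.tsv", sep="\t", index=False, lineterminator="\n"
    )
    return out
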