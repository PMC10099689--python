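"""Allele-frequency statistics: DAF, ΔDAF, Weir–Cockerham FST, the exact
Hardy–Weinberg test, variant QC, and the HWE-deviation selection screen.

All per-variant outputs are float vectors aligned with the input
:class:`~tsnscan.io_formats.HaplotypeMatrix`; undefined values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import PipelineError
from .io_formats import ANC_REF, ANC_UNKNOWN, HaplotypeMatrix, PopulationPanel


# ---------------------------------------------------------------------------
# derived allele frequencies
# ---------------------------------------------------------------------------

def derived_allele_frequency(
    hm: HaplotypeMatrix, panel: PopulationPanel, pop: str
) -> np.ndarray:
    """Per-variant derived-allele frequency within one population.

    DAF = (# derived haplotypes) / (# non-missing haplotypes) among the
    population's samples; NaN where the ancestral state is unknown or all
    calls are missing.
    """
    cols = panel.haplotype_indices(hm, pop)
    calls = hm.calls[:, cols]
    nonmiss = calls >= 0
    n = nonmiss.sum(axis=1)
    alt = np.where(nonmiss, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt / n
    daf = np.where(hm.ancestral == ANC_REF, alt_freq, 1.0 - alt_freq)
    daf[hm.ancestral == ANC_UNKNOWN] = np.nan
    daf[n == 0] = np.nan
    return daf


def delta_daf(daf_target, daf_refs, mode: str = "mean", ref: str | None = None):
    """ΔDAF between a target population and one or more references.

    Parameters
    ----------
    daf_target : array
        Target-population DAF vector.
    daf_refs : dict of {label: array}
        Reference-population DAF vectors, aligned with the target.
    mode : {'per_ref', 'mean', 'min'}
        ``per_ref`` returns DAF_target − DAF_ref for the named ``ref``;
        ``mean``/``min`` aggregate the per-reference differences.
    """
    if not daf_refs:
        raise ValueError("no reference populations supplied")
    t = np.asarray(daf_target, dtype=float)
    if mode == "per_ref":
        if ref is None or ref not in daf_refs:
            raise ValueError(f"per_ref mode needs a reference label, got {ref!r}")
        return t - np.asarray(daf_refs[ref], dtype=float)
    diffs = np.stack([t - np.asarray(v, dtype=float) for v in daf_refs.values()])
    if mode == "mean":
        return diffs.mean(axis=0)
    if mode == "min":
        return diffs.min(axis=0)
    raise ValueError(f"unknown mode: {mode!r}")


# ---------------------------------------------------------------------------
# genotype counts
# ---------------------------------------------------------------------------

def genotype_counts(hm: HaplotypeMatrix, sample_indices) -> np.ndarray:
    """Per-variant genotype counts (hom-ref, het, hom-alt), shape (V, 3).

    A sample contributes only when both of its haplotypes are called.
    """
    cols = hm.haplotype_columns(sample_indices)
    calls = hm.calls[:, cols]
    a = calls[:, 0::2]
    b = calls[:, 1::2]
    ok = (a >= 0) & (b >= 0)
    dosage = a + b
    counts = np.stack(
        [((dosage == g) & ok).sum(axis=1) for g in (0, 1, 2)], axis=1
    )
    return counts


# ---------------------------------------------------------------------------
# Weir & Cockerham FST (two populations)
# ---------------------------------------------------------------------------

def wc_fst(
    hm: HaplotypeMatrix, panel: PopulationPanel, pop_a: str, pop_b: str
) -> np.ndarray:
    """Per-variant Weir & Cockerham (1984) θ̂ between two populations.

    Computed from genotype counts (sample sizes, allele frequencies and
    observed heterozygosity); θ̂ = a/(a+b+c).  NaN where the denominator is
    zero (monomorphic in both populations) or either population has fewer
    than two genotyped samples.  Negative estimates are not clamped.
    """
    if pop_a == pop_b:
        raise ValueError("pop_a and pop_b must differ")
    ga = genotype_counts(hm, panel.sample_indices(hm, pop_a))
    gb = genotype_counts(hm, panel.sample_indices(hm, pop_b))
    return _wc_theta_from_genotypes(ga, gb)


def _wc_theta_from_genotypes(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    r = 2.0
    n1 = ga.sum(axis=1).astype(float)
    n2 = gb.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * ga[:, 2] + ga[:, 1]) / (2 * n1)
        p2 = (2 * gb[:, 2] + gb[:, 1]) / (2 * n2)
        h1 = ga[:, 1] / n1
        h2 = gb[:, 1] / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = a / denom
    theta[(n1 < 2) | (n2 < 2)] = np.nan
    theta[denom == 0] = np.nan
    return theta


def hudson_fst(
    hm: HaplotypeMatrix, panel: PopulationPanel, pop_a: str, pop_b: str
) -> np.ndarray:
    """Hudson-style FST (1 − Hw/Hb from haplotype frequencies); cross-check
    output, not the scan's primary estimator."""
    if pop_a == pop_b:
        raise ValueError("pop_a and pop_b must differ")
    out = np.full(hm.n_variants, np.nan)
    freqs, sizes = [], []
    for pop in (pop_a, pop_b):
        cols = panel.haplotype_indices(hm, pop)
        calls = hm.calls[:, cols]
        nonmiss = calls >= 0
        n = nonmiss.sum(axis=1).astype(float)
        p = np.where(nonmiss, calls, 0).sum(axis=1) / np.where(n > 0, n, np.nan)
        freqs.append(p)
        sizes.append(n)
    p1, p2 = freqs
    n1, n2 = sizes
    with np.errstate(invalid="ignore", divide="ignore"):
        hw = (p1 * (1 - p1) * n1 / (n1 - 1) + p2 * (1 - p2) * n2 / (n2 - 1)) / 2
        hb = p1 * (1 - p2) / 2 + p2 * (1 - p1) / 2
        out = 1 - hw / hb
    out[(n1 < 2) | (n2 < 2)] = np.nan
    out[np.isclose(hb, 0)] = np.nan
    return out


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    n_AA: int
    n_Aa: int
    n_aa: int
    p: float


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Exact conditional Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the exact
    probabilities of all heterozygote counts ``h`` whose probability does
    not exceed that of the observed configuration:
    ``p = Σ_{h: P(h) ≤ P(obs)} P(h)``, with
    ``P(h) ∝ n! / (n_AA! h! n_aa!) · 2^h`` for fixed allele counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    na1 = 2 * n_AA + n_Aa  # count of allele A
    na2 = 2 * n_aa + n_Aa
    h = np.arange(na1 % 2, min(na1, na2) + 1, 2)
    n_hom1 = (na1 - h) // 2
    n_hom2 = (na2 - h) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_hom1 + 1)
        - gammaln(h + 1)
        - gammaln(n_hom2 + 1)
        + h * np.log(2.0)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.nonzero(h == n_Aa)[0][0]]
    p = float(prob[prob <= obs * (1 + 1e-12)].sum())
    return HWEResult(n_AA=n_AA, n_Aa=n_Aa, n_aa=n_aa, p=min(p, 1.0))


def hwe_exact_pvalues(hm: HaplotypeMatrix, sample_indices=None) -> np.ndarray:
    """Per-variant exact HWE p-values within one set of samples.

    The test population should be a single panmictic cohort (pooling
    differentiated populations creates Wahlund artifacts).
    """
    if sample_indices is None:
        sample_indices = np.arange(hm.n_samples)
    counts = genotype_counts(hm, sample_indices)
    out = np.full(hm.n_variants, np.nan)
    for v in range(hm.n_variants):
        n_aa_, n_ab, n_bb = (int(c) for c in counts[v])
        if n_aa_ + n_ab + n_bb >= 1:
            out[v] = hwe_exact_test(n_aa_, n_ab, n_bb).p
    return out


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of variants removed per rule; a variant is counted once,
    under the first failing rule (singleton → missingness → HWE)."""

    n_input: int
    n_retained: int
    removed_singleton: int = 0
    removed_missingness: int = 0
    removed_hwe: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_singleton": self.removed_singleton,
            "removed_missingness": self.removed_missingness,
            "removed_hwe": self.removed_hwe,
        }


def qc_filter(
    hm: HaplotypeMatrix,
    max_missing: float | None = 0.03,
    hwe_floor: float | None = 1e-10,
    drop_singletons: bool = True,
    hwe_samples=None,
):
    """Apply the standard variant QC screens.

    Removes (1) singletons — dataset-wide minor allele count ≤ 1, which
    also drops monomorphic records; (2) variants whose fraction of missing
    genotypes exceeds ``max_missing``; (3) variants with exact HWE p below
    ``hwe_floor``.  Pass ``None`` (or ``drop_singletons=False``) to disable
    a rule.  ``hwe_samples`` restricts the HWE test to one panmictic cohort
    (e.g. the target population) to avoid Wahlund artifacts; default is all
    samples.  Returns the filtered matrix and a :class:`FilterReport`.
    """
    v = hm.n_variants
    fail_singleton = np.zeros(v, dtype=bool)
    fail_missing = np.zeros(v, dtype=bool)
    fail_hwe = np.zeros(v, dtype=bool)

    if drop_singletons:
        nonmiss = hm.calls >= 0
        alt = np.where(nonmiss, hm.calls, 0).sum(axis=1)
        total = nonmiss.sum(axis=1)
        mac = np.minimum(alt, total - alt)
        fail_singleton = mac <= 1

    if max_missing is not None:
        a = hm.calls[:, 0::2]
        b = hm.calls[:, 1::2]
        geno_missing = ((a < 0) | (b < 0)).mean(axis=1)
        fail_missing = geno_missing > max_missing

    if hwe_floor is not None:
        pvals = hwe_exact_pvalues(hm, hwe_samples)
        fail_hwe = np.nan_to_num(pvals, nan=1.0) < hwe_floor

    first = np.full(v, 0, dtype=np.int8)  # 0 keep, 1 singleton, 2 missing, 3 hwe
    first[fail_hwe] = 3
    first[fail_missing] = 2
    first[fail_singleton] = 1
    keep = first == 0
    report = FilterReport(
        n_input=v,
        n_retained=int(keep.sum()),
        removed_singleton=int((first == 1).sum()),
        removed_missingness=int((first == 2).sum()),
        removed_hwe=int((first == 3).sum()),
    )
    return hm.take_variants(keep), report


def flag_hwe_selection_candidates(
    table, hwe_cut: float = 1e-6, fst_cut: float = 0.2
) -> np.ndarray:
    """Flag variants with significant HWE deviation AND high FST.

    Under strong recent selection a genuine sweep inflates both; the flag
    marks candidates rather than removing them.  ``table`` must carry
    ``hwe_p`` and ``fst`` columns.
    """
    for col in ("hwe_p", "fst"):
        if col not in table.columns:
            raise PipelineError(f"statistics table lacks required column {col!r}")
    return ((table["hwe_p"] < hwe_cut) & (table["fst"] > fst_cut)).to_numpy()
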