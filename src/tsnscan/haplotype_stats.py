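"""Extended-haplotype-homozygosity statistics (EHH, iHS, XPEHH), pairwise
r² and LD-decay curves, all computed from phased haplotypes.

EHH at a flanking marker x is the probability that two randomly drawn
carrier haplotypes are identical at every marker from the core out to x.
Identity is tracked by incremental group refinement marker-by-marker; a
missing call breaks homozygosity (the haplotype becomes a permanent
singleton) rather than being imputed.  Curves are truncated once EHH drops
below a threshold (default 0.05); a curve that reaches a data edge while
still above the threshold marks the core as unusable for iHS/XPEHH.

Integrals (iHH) are trapezoids over physical distance in bp; no genetic
map is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ANC_REF, ANC_UNKNOWN, HaplotypeMatrix, PopulationPanel

logger = logging.getLogger(__name__)

DEFAULT_EHH_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

@dataclass
class EHHCurve:
    """One direction of an EHH decay curve.

    ``offsets`` are signed bp offsets from the core (0 first); ``ehh`` the
    matching EHH values (1.0 first); ``decayed`` is False when the scan hit
    the chromosome edge before EHH fell below ``threshold``.
    """

    core: int
    direction: str  # 'upstream' | 'downstream'
    offsets: np.ndarray
    ehh: np.ndarray
    threshold: float
    decayed: bool

    def to_frame(self) -> pd.DataFrame:
        """Curve as a tidy table (offset_bp, ehh) for TSV export/plotting."""
        return pd.DataFrame(
            {
                "core": self.core,
                "direction": self.direction,
                "offset_bp": self.offsets,
                "ehh": self.ehh,
            }
        )


def _ehh_scan(calls, positions, core, hap_cols, direction, threshold):
    """Scan outward from the core refining identity groups.

    ``calls`` is the variant-major int8 matrix; ``hap_cols`` the carrier
    haplotype columns.  Returns (offsets, ehh, decayed).
    """
    K = hap_cols.size
    pairs_total = K * (K - 1) / 2.0
    labels = np.zeros(K, dtype=np.int64)
    offsets = [0]
    values = [1.0]
    decayed = False
    step = -1 if direction == "upstream" else 1
    core_pos = positions[core]
    j = core + step
    while 0 <= j < calls.shape[0]:
        alleles = calls[j, hap_cols].astype(np.int64)
        # group key = (current group, allele); a missing call gets a unique
        # key, making the haplotype a permanent singleton
        codes = labels * 2 + np.where(alleles >= 0, alleles, 0)
        miss = alleles < 0
        if miss.any():
            codes[miss] = 2 * K + np.arange(int(miss.sum()))
        # bincount-based relabelling (codes are small non-negative ints)
        occupancy = np.bincount(codes)
        relabel = np.cumsum(occupancy > 0) - 1
        labels = relabel[codes]
        counts = occupancy[occupancy > 0]
        ehh_val = float((counts * (counts - 1) / 2.0).sum() / pairs_total)
        offsets.append(int(positions[j] - core_pos))
        values.append(ehh_val)
        if ehh_val < threshold:
            decayed = True
            break
        j += step
    return np.array(offsets, dtype=np.int64), np.array(values), decayed


def _carrier_columns(hm, core, allele_class, hap_cols):
    """Haplotype columns carrying the requested core allele class."""
    calls = hm.calls[core, hap_cols]
    if allele_class == "all":
        return hap_cols[calls >= 0]
    if hm.ancestral[core] == ANC_UNKNOWN:
        raise ValueError(
            "ancestral/derived carrier classes need a known ancestral state"
        )
    derived_allele = 1 if hm.ancestral[core] == ANC_REF else 0
    if allele_class == "derived":
        return hap_cols[calls == derived_allele]
    if allele_class == "ancestral":
        return hap_cols[calls == 1 - derived_allele]
    raise ValueError(f"unknown allele class: {allele_class!r}")


def ehh(
    hm: HaplotypeMatrix,
    core: int,
    allele_class: str = "derived",
    panel: PopulationPanel | None = None,
    pop: str | None = None,
    threshold: float = DEFAULT_EHH_THRESHOLD,
):
    """EHH decay curves (upstream, downstream) around a core variant.

    ``allele_class`` is 'ancestral', 'derived', or 'all' (population-
    restricted pooled carriers; identity is then tracked over flanking
    markers only, so EHH(0)=1 holds for every curve).  When ``panel`` and
    ``pop`` are given the carrier set is restricted to that population.
    Returns None when the carrier class holds fewer than two haplotypes.
    """
    if pop is not None:
        hap_cols = panel.haplotype_indices(hm, pop)
    else:
        hap_cols = np.arange(hm.n_haplotypes)
    carriers = _carrier_columns(hm, core, allele_class, hap_cols)
    if carriers.size < 2:
        return None
    out = []
    for direction in ("upstream", "downstream"):
        offsets, values, decayed = _ehh_scan(
            hm.calls, hm.positions, core, carriers, direction, threshold
        )
        out.append(
            EHHCurve(
                core=core,
                direction=direction,
                offsets=offsets,
                ehh=values,
                threshold=threshold,
                decayed=decayed,
            )
        )
    return tuple(out)


def _ihh_one_class(calls, positions, core, carriers, threshold):
    """Integrated EHH (both directions) for one carrier set.

    Returns NaN when either direction reaches a data edge before decaying
    below the threshold.
    """
    total = 0.0
    for direction in ("upstream", "downstream"):
        offsets, values, decayed = _ehh_scan(
            calls, positions, core, carriers, direction, threshold
        )
        if not decayed:
            return np.nan
        x = np.abs(offsets).astype(float)
        total += float(np.trapezoid(values, x))
    return total


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def ihs(
    hm: HaplotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    min_maf: float = 0.05,
    threshold: float = DEFAULT_EHH_THRESHOLD,
    bins: int = 50,
) -> pd.DataFrame:
    """Per-variant integrated haplotype score within one population.

    iHH_A and iHH_D are trapezoidal integrals of the ancestral- and
    derived-carrier EHH curves over physical distance, summed over both
    directions; the unstandardized score is ln(iHH_A/iHH_D), standardized
    within ``bins`` equal-count derived-allele-frequency bins (subtract bin
    mean, divide by bin sd).  A variant is missing when its ancestral state
    is unknown, its minor allele frequency is below ``min_maf``, either
    carrier class has fewer than two haplotypes, either integral is zero,
    or an EHH curve failed to decay below the threshold before a data edge.

    Returns a DataFrame with columns ihh_a, ihh_d, ihs (unstandardized),
    ihs_std, daf, freq_bin.
    """
    hap_cols = panel.haplotype_indices(hm, pop)
    calls = hm.calls
    n_var = hm.n_variants
    ihh_a = np.full(n_var, np.nan)
    ihh_d = np.full(n_var, np.nan)
    daf = np.full(n_var, np.nan)

    sub = calls[:, hap_cols]
    nonmiss = sub >= 0
    n = nonmiss.sum(axis=1)
    alt = np.where(nonmiss, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt / n
    derived_is_alt = hm.ancestral == ANC_REF
    daf_all = np.where(derived_is_alt, alt_freq, 1.0 - alt_freq)
    polarized = hm.ancestral != ANC_UNKNOWN
    maf = np.minimum(alt_freq, 1 - alt_freq)
    usable = polarized & (n > 0) & (maf >= min_maf)

    for core in np.nonzero(usable)[0]:
        derived_allele = 1 if derived_is_alt[core] else 0
        core_calls = calls[core, hap_cols]
        der = hap_cols[core_calls == derived_allele]
        anc = hap_cols[core_calls == 1 - derived_allele]
        if der.size < 2 or anc.size < 2:
            continue
        va = _ihh_one_class(calls, hm.positions, core, anc, threshold)
        vd = _ihh_one_class(calls, hm.positions, core, der, threshold)
        if np.isnan(va) or np.isnan(vd) or va == 0.0 or vd == 0.0:
            continue
        ihh_a[core] = va
        ihh_d[core] = vd
        daf[core] = daf_all[core]

    with np.errstate(invalid="ignore", divide="ignore"):
        unstd = np.log(ihh_a / ihh_d)
    std, bin_id = _standardize_binned(unstd, daf, bins)
    return pd.DataFrame(
        {
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "ihs": unstd,
            "ihs_std": std,
            "daf": daf,
            "freq_bin": bin_id,
        }
    )


MIN_BIN_OCCUPANCY = 20


def _standardize_binned(values, freqs, bins):
    """Standardize within equal-count frequency bins; returns (std, bin_id).

    The bin count is reduced so that each bin holds at least
    ``MIN_BIN_OCCUPANCY`` scores — with only a handful of variants per bin
    the bin mean tracks the signal itself and standardization would erase
    it.
    """
    std = np.full_like(values, np.nan)
    bin_id = np.full(values.shape[0], -1, dtype=np.int64)
    defined = np.nonzero(~np.isnan(values))[0]
    if defined.size == 0:
        return std, bin_id
    n_bins = max(1, min(bins, defined.size // MIN_BIN_OCCUPANCY))
    if n_bins < bins:
        logger.warning(
            "only %d scored variants: reducing frequency bins from %d to %d",
            defined.size, bins, n_bins,
        )
    # equal-count bins by rank of derived frequency
    order = defined[np.argsort(freqs[defined], kind="stable")]
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        if idx.size == 0:
            continue
        v = values[idx]
        mu = v.mean()
        sd = v.std()
        bin_id[idx] = b
        if sd > 0:
            std[idx] = (v - mu) / sd
    return std, bin_id


# ---------------------------------------------------------------------------
# XPEHH
# ---------------------------------------------------------------------------

def xpehh(
    hm: HaplotypeMatrix,
    panel: PopulationPanel,
    pop_a: str,
    pop_b: str,
    threshold: float = DEFAULT_EHH_THRESHOLD,
) -> pd.DataFrame:
    """Cross-population EHH score per variant.

    The unstandardized score is ln(iHH_A/iHH_B) where each iHH integrates
    the pooled-carrier EHH curve within one population at the same core;
    positive values mean longer haplotypes in ``pop_a``.  Standardization
    is genome-wide (single mean/sd).  Returns a DataFrame with columns
    ihh_pop_a, ihh_pop_b, xpehh (unstandardized), xpehh_std.
    """
    cols_a = panel.haplotype_indices(hm, pop_a)
    cols_b = panel.haplotype_indices(hm, pop_b)
    if cols_a.size < 4 or cols_b.size < 4:
        raise ValueError("both populations need at least 4 haplotypes")
    n_var = hm.n_variants
    ihh_1 = np.full(n_var, np.nan)
    ihh_2 = np.full(n_var, np.nan)
    for core in range(n_var):
        ca = cols_a[hm.calls[core, cols_a] >= 0]
        cb = cols_b[hm.calls[core, cols_b] >= 0]
        if ca.size < 2 or cb.size < 2:
            continue
        va = _ihh_one_class(hm.calls, hm.positions, core, ca, threshold)
        if np.isnan(va) or va == 0.0:
            continue
        vb = _ihh_one_class(hm.calls, hm.positions, core, cb, threshold)
        if np.isnan(vb) or vb == 0.0:
            continue
        ihh_1[core] = va
        ihh_2[core] = vb
    with np.errstate(invalid="ignore", divide="ignore"):
        unstd = np.log(ihh_1 / ihh_2)
    defined = ~np.isnan(unstd)
    std = np.full(n_var, np.nan)
    if defined.sum() >= 2 and unstd[defined].std() > 0:
        std[defined] = (unstd[defined] - unstd[defined].mean()) / unstd[
            defined
        ].std()
    return pd.DataFrame(
        {"ihh_pop_a": ihh_1, "ihh_pop_b": ihh_2, "xpehh": unstd, "xpehh_std": std}
    )


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDPair:
    i: int
    j: int
    distance: int
    r2: float


def _r2_from_haplotypes(x: np.ndarray, y: np.ndarray) -> float:
    """r² from two phased 0/1 haplotype vectors over pairwise-complete calls."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    p_i = xs.mean()
    p_j = ys.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        return np.nan
    d = (xs * ys).mean() - p_i * p_j
    return float(d * d / (p_i * (1 - p_i) * p_j * (1 - p_j)))


def pairwise_r2(
    hm: HaplotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    i: int,
    j: int,
) -> LDPair:
    """Haplotype r² between two variants within one population.

    NaN when either variant is monomorphic over the pairwise-complete
    haplotype set.
    """
    if i > j:
        i, j = j, i
    cols = panel.haplotype_indices(hm, pop)
    r2 = _r2_from_haplotypes(hm.calls[i, cols], hm.calls[j, cols])
    return LDPair(
        i=i, j=j, distance=int(hm.positions[j] - hm.positions[i]), r2=r2
    )


def _r2_matrix(calls: np.ndarray) -> np.ndarray:
    """All-pairs r² for a complete (no-missing) variant-major 0/1 matrix.

    Rows that are monomorphic yield NaN against everything.
    """
    x = calls.astype(float)
    p = x.mean(axis=1)
    keep = (p > 0) & (p < 1)
    out = np.full((x.shape[0], x.shape[0]), np.nan)
    if keep.sum() >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x[keep])
        out[np.ix_(np.nonzero(keep)[0], np.nonzero(keep)[0])] = c**2
    return out


def ld_decay_curve(
    hm: HaplotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    max_dist: int = 500_000,
    bin_width: int = 1_000,
):
    """Mean r² as a function of pairwise distance.

    All variant pairs at distance ≤ ``max_dist`` are binned by distance
    (``bin_width`` bp bins); returns (bin midpoints, mean r² per bin) with
    NaN for empty bins.
    """
    if hm.n_variants < 2:
        raise ValueError("need at least 2 variants")
    cols = panel.haplotype_indices(hm, pop)
    sub = hm.calls[:, cols]
    pos = hm.positions
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    if (sub >= 0).all():
        r2 = _r2_matrix(sub)
        iu, ju = np.triu_indices(hm.n_variants, k=1)
        dist = pos[ju] - pos[iu]
        vals = r2[iu, ju]
        ok = (dist <= max_dist) & ~np.isnan(vals)
        b = np.minimum((dist[ok] - 1) // bin_width, n_bins - 1).astype(np.int64)
        np.add.at(sums, b, vals[ok])
        np.add.at(counts, b, 1)
    else:  # missing data: pairwise-complete, pair by pair
        for i in range(hm.n_variants - 1):
            for j in range(i + 1, hm.n_variants):
                dist = int(pos[j] - pos[i])
                if dist > max_dist:
                    break
                val = _r2_from_haplotypes(sub[i], sub[j])
                if np.isnan(val):
                    continue
                b = min((dist - 1) // bin_width, n_bins - 1)
                sums[b] += val
                counts[b] += 1

    mids = (np.arange(n_bins) + 0.5) * bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return mids, means
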