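"""Sliding-window site-frequency-spectrum statistics: Tajima's D and
Fay & Wu's H, with simulation-based p-values from fixed-S neutral
coalescent samples.

Window inputs are variant-major 0/1 matrices (sites × haplotypes, -1 for
missing).  Fay & Wu's H requires derived-coded calls (0 = ancestral); the
windowing driver polarizes from the haplotype matrix's ancestral states and
counts the sites it has to skip.  H is reported unnormalized (θπ − θH),
the form whose magnitudes grow with window diversity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ANC_ALT, ANC_UNKNOWN, HaplotypeMatrix, PopulationPanel
from .synthetic_data import simulate_neutral_coalescent


# ---------------------------------------------------------------------------
# per-site machinery
# ---------------------------------------------------------------------------

def _site_counts(calls: np.ndarray):
    """Per-site (count of 1-alleles, non-missing total) over haplotypes."""
    nonmiss = calls >= 0
    n_i = nonmiss.sum(axis=1)
    d_i = np.where(nonmiss, calls, 0).sum(axis=1)
    return d_i, n_i


def _pi_per_site(d_i, n_i):
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * d_i * (n_i - d_i) / (n_i * (n_i - 1.0))
    return np.where(n_i >= 2, pi, 0.0)


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d(calls: np.ndarray) -> float:
    """Tajima's D for one window of haplotypes (sites × haplotypes).

    D = (θπ − S/a1) / sqrt(e1·S + e2·S(S−1)) with the standard constants
    computed from the number of haplotype columns.  Sites with missing
    calls contribute pairwise-complete θπ.  NaN when S = 0 or n < 4
    (allele polarity is irrelevant: both θπ and S are fold-symmetric).
    """
    calls = np.asarray(calls)
    n = calls.shape[1]
    d_i, n_i = _site_counts(calls)
    seg = (d_i > 0) & (d_i < n_i)
    S = int(seg.sum())
    if S == 0 or n < 4:
        return np.nan
    pi = _pi_per_site(d_i, n_i).sum()
    a1, e1, e2 = _tajima_constants(n)
    return float((pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0)))


def _tajimas_d_from_counts(d: np.ndarray, n: int) -> np.ndarray:
    """Vectorized D over replicate rows of derived counts (reps × S),
    complete data (all sites observed in n haplotypes)."""
    seg = (d > 0) & (d < n)
    S = seg.sum(axis=1)
    pi = np.where(seg, 2.0 * d * (n - d) / (n * (n - 1.0)), 0.0).sum(axis=1)
    a1, e1, e2 = _tajima_constants(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1.0))
    out[S == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Fay & Wu's H
# ---------------------------------------------------------------------------

def fay_wu_h(calls: np.ndarray) -> float:
    """Unnormalized Fay & Wu's H = θπ − θH for derived-coded calls.

    θπ = Σ 2i(n−i)/(n(n−1)) and θH = Σ 2i²/(n(n−1)) over sites, with i the
    derived count; strongly negative when high-frequency derived alleles
    are in excess, the footprint of a recent sweep.  Input must already be
    polarized (0 = ancestral, 1 = derived); NaN when no site is usable.
    """
    calls = np.asarray(calls)
    d_i, n_i = _site_counts(calls)
    usable = n_i >= 2
    if not usable.any():
        return np.nan
    d_i, n_i = d_i[usable], n_i[usable]
    pi = _pi_per_site(d_i, n_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        th = 2.0 * d_i**2 / (n_i * (n_i - 1.0))
    return float((pi - th).sum())


def _fay_wu_h_from_counts(d: np.ndarray, n: int) -> np.ndarray:
    """Vectorized H over replicate rows of derived counts (reps × S)."""
    pi = 2.0 * d * (n - d) / (n * (n - 1.0))
    th = 2.0 * d.astype(float) ** 2 / (n * (n - 1.0))
    return (pi - th).sum(axis=1)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n", "S", "theta_pi", "theta_w", "theta_h",
    "D", "H", "skipped_unpolarized", "p_H",
]


def sliding_windows(
    hm: HaplotypeMatrix,
    panel: PopulationPanel | None = None,
    pop: str | None = None,
    size: int = 50_000,
    step: int = 10_000,
    null_reps: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tile [min pos, max pos] with windows and compute SFS statistics.

    Windows are ``size`` bp wide, advancing by ``step`` (``size`` must be
    ≥ ``step``).  Each window reports n, S, θπ, θW (Watterson), θH, Tajima's
    D and Fay & Wu's H; sites with unknown ancestral state are skipped for
    θH/H and counted in ``skipped_unpolarized``.  When ``null_reps`` ≥ 100,
    a lower-tail simulation p-value for H (``p_H``) is attached per window.
    """
    if size < step:
        raise ValueError("window size must be >= step")
    if pop is not None:
        cols = panel.haplotype_indices(hm, pop)
    else:
        cols = np.arange(hm.n_haplotypes)
    calls = hm.calls[:, cols]
    n = cols.size
    if hm.n_variants == 0:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    # polarize: 0 = ancestral, 1 = derived (flip where alt is ancestral)
    flip = hm.ancestral == ANC_ALT
    polarized = np.where(
        calls >= 0, np.where(flip[:, None], 1 - calls, calls), -1
    )
    unknown = hm.ancestral == ANC_UNKNOWN

    lo, hi = int(hm.positions.min()), int(hm.positions.max())
    span = hi - lo + 1
    n_win = max(1, int(np.ceil(max(span - size, 0) / step)) + 1)
    rows = []
    rng = np.random.default_rng(seed)
    for k in range(n_win):
        start = lo + k * step
        end = start + size - 1
        in_win = (hm.positions >= start) & (hm.positions <= end)
        sub = calls[in_win]
        d_i, n_i = _site_counts(sub)
        seg = (d_i > 0) & (d_i < n_i)
        S = int(seg.sum())
        theta_pi = float(_pi_per_site(d_i, n_i).sum())
        a1, _, _ = _tajima_constants(n) if n >= 2 else (np.nan, None, None)
        theta_w = S / a1 if n >= 2 else np.nan
        d_stat = tajimas_d(sub) if n >= 4 else np.nan

        pol_mask = in_win & ~unknown
        pol = polarized[pol_mask]
        if pol.size:
            dp, np_ = _site_counts(pol)
            with np.errstate(invalid="ignore", divide="ignore"):
                theta_h = float(
                    np.where(np_ >= 2, 2.0 * dp**2 / (np_ * (np_ - 1.0)), 0.0).sum()
                )
            h_stat = fay_wu_h(pol)
        else:
            theta_h, h_stat = np.nan, np.nan

        p_h = np.nan
        if null_reps and not np.isnan(h_stat) and S >= 1:
            p_h = neutral_pvalue(
                h_stat, n=n, S=S, reps=null_reps,
                seed=int(rng.integers(2**31)), tail="lower", stat="H",
            )
        rows.append(
            {
                "chrom": hm.chrom, "start": start, "end": end, "n": n,
                "S": S, "theta_pi": theta_pi, "theta_w": theta_w,
                "theta_h": theta_h, "D": d_stat, "H": h_stat,
                "skipped_unpolarized": int((in_win & unknown).sum()),
                "p_H": p_h,
            }
        )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def region_extremes(windows: pd.DataFrame, start: int, end: int) -> dict:
    """Most negative H and D among windows overlapping [start, end]."""
    sel = windows[(windows["end"] >= start) & (windows["start"] <= end)]
    return {
        "min_H": float(sel["H"].min()) if len(sel) else np.nan,
        "min_D": float(sel["D"].min()) if len(sel) else np.nan,
        "n_windows": int(len(sel)),
    }


# ---------------------------------------------------------------------------
# simulation p-values
# ---------------------------------------------------------------------------

_STAT_FROM_COUNTS = {"H": _fay_wu_h_from_counts, "D": _tajimas_d_from_counts}


def neutral_null_distribution(
    n: int, S: int, reps: int, seed=None, stat: str = "H"
) -> np.ndarray:
    """Null sample of a window statistic under the fixed-S neutral
    coalescent (no recombination), matched on n and S."""
    sims = simulate_neutral_coalescent(n, S, reps=reps, seed=seed)
    counts = sims.sum(axis=1)  # (reps, S) derived counts
    return _STAT_FROM_COUNTS[stat](counts, n)


def neutral_pvalue(
    observed: float,
    n: int,
    S: int,
    reps: int = 1000,
    seed=None,
    tail: str = "lower",
    stat: str = "H",
) -> float:
    """Add-one simulation p-value of an observed window statistic.

    p = (1 + #{simulated ≤ observed}) / (reps + 1) for the lower tail,
    from fixed-S neutral coalescent replicates at matched n and S;
    deterministic given ``seed``.  ``reps`` below 100 is refused (unstable
    p-values).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if stat not in _STAT_FROM_COUNTS:
        raise ValueError(f"unknown statistic {stat!r}")
    null = neutral_null_distribution(n, S, reps, seed=seed, stat=stat)
    null = null[~np.isnan(null)]
    if tail == "lower":
        hits = int((null <= observed).sum())
    elif tail == "upper":
        hits = int((null >= observed).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + hits) / (len(null) + 1)
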