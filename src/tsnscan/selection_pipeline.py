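"""Candidate nomination: CMS composite scoring, top-quantile selection,
target-enrichment filtering, LD clumping into independent signal regions,
lead-gene assignment, and the enriched-SV divergence screen.

The composite-of-multiple-signals (CMS) score combines four per-variant
selection statistics — FST, ΔDAF(target−reference), |iHS| and XPEHH — by
converting each to an empirical rank p-value (rank 1 = most extreme in the
adaptive direction, p = rank/N) and summing −log10 p over the components.
This monotone rank combination is bounded by 4·log10(N) and is the
package's documented stand-in for Bayes-factor composite formulations;
realized thresholds are therefore data-set specific.  A variant missing
any component receives no CMS.

All tie-breaks are deterministic: CMS descending, then FST descending,
then position ascending.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import __version__
from .config import RunConfig
from .errors import PipelineError
from .freq_stats import (
    derived_allele_frequency,
    flag_hwe_selection_candidates,
    hwe_exact_pvalues,
    qc_filter,
    wc_fst,
)
from .haplotype_stats import _r2_from_haplotypes, ihs, xpehh
from .io_formats import (
    GeneModel,
    HaplotypeMatrix,
    PopulationPanel,
    read_gene_model,
    read_phased_vcf,
    read_population_panel,
    write_stats_table,
)

logger = logging.getLogger(__name__)

CMS_COMPONENTS = ("fst", "delta_daf", "abs_ihs", "xpehh")


# ---------------------------------------------------------------------------
# CMS
# ---------------------------------------------------------------------------

def cms_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Attach empirical rank p-values and the CMS score to a stats table.

    ``table`` must carry columns ``fst``, ``delta_daf``, ``ihs`` and
    ``xpehh`` (the haplotype scores standardized).  For each component the
    empirical p of a variant is rank/N with rank 1 the most extreme in the
    adaptive direction: descending FST, descending ΔDAF, descending |iHS|
    (sweeps act on either allele polarity), descending XPEHH with the
    target as the numerator population.  CMS = Σ −log10 p over the four
    components; NaN wherever any component is undefined.
    """
    out = table.copy()
    values = {
        "fst": out["fst"].to_numpy(float),
        "delta_daf": out["delta_daf"].to_numpy(float),
        "abs_ihs": np.abs(out["ihs"].to_numpy(float)),
        "xpehh": out["xpehh"].to_numpy(float),
    }
    logp_total = np.zeros(len(out))
    any_nan = np.zeros(len(out), dtype=bool)
    for comp, vals in values.items():
        defined = ~np.isnan(vals)
        if defined.sum() == 0:
            raise PipelineError(f"CMS component {comp!r} has no defined values")
        n = defined.sum()
        ranks = np.full(len(out), np.nan)
        ranks[defined] = rankdata(-vals[defined], method="average")
        p = ranks / n
        out[f"p_{comp}"] = p
        with np.errstate(invalid="ignore"):
            logp_total = logp_total - np.log10(p)
        any_nan |= ~defined
    logp_total[any_nan] = np.nan
    out["cms"] = logp_total
    return out


def top_quantile(table: pd.DataFrame, q: float = 0.001):
    """Select the ⌈N·q⌉ variants with the highest CMS scores.

    N counts variants with a defined CMS; boundary ties are broken by
    higher FST, then lower position.  Returns (selected row index,
    realized threshold = minimum selected CMS).
    """
    scored = table[~table["cms"].isna()]
    n = len(scored)
    if n < 1.0 / q:
        raise ValueError(f"need at least {int(np.ceil(1 / q))} scored variants, got {n}")
    k = int(np.ceil(n * q))
    order = scored.sort_values(
        ["cms", "fst", "pos"], ascending=[False, False, True], kind="mergesort"
    )
    chosen = order.index[:k]
    threshold = float(order["cms"].iloc[k - 1])
    return chosen, threshold


# ---------------------------------------------------------------------------
# enrichment filter
# ---------------------------------------------------------------------------

def enrichment_filter(
    table: pd.DataFrame,
    target: str,
    refs,
    han: str | None = None,
):
    """Keep candidates whose target-enriched allele dominates every reference.

    The enriched allele is the one with higher frequency in the target than
    in the ``han`` reference (default: first of ``refs``); the candidate is
    kept iff that allele's frequency is strictly greater in the target than
    in every reference population.  Rows lacking a reference DAF are
    dropped with a logged reason.  Returns (boolean mask, report dict).
    """
    refs = list(refs)
    if not refs:
        raise ValueError("no reference populations supplied")
    han = refs[0] if han is None else han
    t = table[f"daf_{target}"].to_numpy(float)
    h = table[f"daf_{han}"].to_numpy(float)
    ref_mat = np.stack([table[f"daf_{r}"].to_numpy(float) for r in refs])

    missing = np.isnan(t) | np.isnan(h) | np.isnan(ref_mat).any(axis=0)
    derived_enriched = t > h
    ancestral_enriched = t < h
    keep_derived = derived_enriched & (t[None, :] > ref_mat).all(axis=0)
    keep_ancestral = ancestral_enriched & ((1 - t[None, :]) > (1 - ref_mat)).all(axis=0)
    keep = (keep_derived | keep_ancestral) & ~missing
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning(
            "enrichment filter dropped %d candidates lacking a reference DAF",
            n_missing,
        )
    report = {
        "n_candidates": int(len(table)),
        "n_kept": int(keep.sum()),
        "n_missing_ref_daf": n_missing,
        "n_no_enriched_allele": int((~missing & (t == h)).sum()),
    }
    return keep, report


# ---------------------------------------------------------------------------
# LD clumping and gene assignment
# ---------------------------------------------------------------------------

@dataclass
class SignalRegion:
    """One independent selection signal after clumping."""

    region_id: int
    lead_vidx: int
    lead_pos: int
    lead_cms: float
    member_vidx: list
    span: tuple
    lead_gene: str | None = None


def ld_clump(
    tsns: pd.DataFrame,
    hm: HaplotypeMatrix,
    panel: PopulationPanel,
    pop: str,
    r2_max: float = 0.2,
    window: int = 500_000,
    r2_lookup=None,
):
    """Greedy LD clumping of candidate variants into independent regions.

    Repeatedly takes the highest-CMS unassigned candidate as a lead
    (ties: FST descending, position ascending) and assigns to its region
    every unassigned candidate within ``window`` bp AND with r² to the lead
    above ``r2_max``.  Unavailable r² (monomorphic pair) is treated as
    independence and counted.  ``tsns`` must carry ``vidx``, ``pos``,
    ``cms`` and ``fst`` columns; ``r2_lookup(i, j)`` may override the
    haplotype-based r² (used for cross-checks).

    Returns (list of :class:`SignalRegion` ordered by lead CMS descending,
    count of unavailable r² pairs).
    """
    if r2_lookup is None:
        cols = panel.haplotype_indices(hm, pop)

        def r2_lookup(i, j):
            return _r2_from_haplotypes(hm.calls[i, cols], hm.calls[j, cols])

    order = tsns.sort_values(
        ["cms", "fst", "pos"], ascending=[False, False, True], kind="mergesort"
    )
    vidx = order["vidx"].to_numpy(np.int64)
    pos = order["pos"].to_numpy(np.int64)
    cms = order["cms"].to_numpy(float)
    assigned = np.zeros(len(order), dtype=bool)
    regions: list[SignalRegion] = []
    n_r2_missing = 0

    for row in range(len(order)):
        if assigned[row]:
            continue
        assigned[row] = True
        members = [row]
        for other in np.nonzero(~assigned)[0]:
            if abs(int(pos[other]) - int(pos[row])) > window:
                continue
            r2 = r2_lookup(int(vidx[row]), int(vidx[other]))
            if r2 is None or np.isnan(r2):
                n_r2_missing += 1
                continue
            if r2 > r2_max:
                assigned[other] = True
                members.append(other)
        member_pos = pos[members]
        regions.append(
            SignalRegion(
                region_id=len(regions) + 1,
                lead_vidx=int(vidx[row]),
                lead_pos=int(pos[row]),
                lead_cms=float(cms[row]),
                member_vidx=[int(v) for v in vidx[members]],
                span=(int(member_pos.min()), int(member_pos.max())),
            )
        )
    if n_r2_missing:
        logger.warning("clumping: %d pairs had unavailable r²", n_r2_missing)
    return regions, n_r2_missing


def assign_lead_gene(region: SignalRegion, genes: GeneModel, chrom: str) -> str | None:
    """Nearest gene of a region's lead variant.

    If the lead falls inside one or more flanked gene regions, the gene
    whose body midpoint is nearest wins; otherwise the gene minimizing the
    distance from the lead to its body interval.  Ties break by smaller
    distance, then lexicographic name.  Returns None when the chromosome
    has no genes.
    """
    table = genes.genes_on(chrom)
    if table.empty:
        return None
    pos = region.lead_pos
    containing = table[
        (table["region_start"] <= pos) & (pos <= table["region_end"])
    ]
    if not containing.empty:
        mid = (containing["body_start"] + containing["body_end"]) / 2.0
        dist = np.abs(mid - pos).to_numpy()
        names = containing["gene"].to_numpy()
    else:
        dist = (
            np.maximum(table["body_start"] - pos, 0)
            + np.maximum(pos - table["body_end"], 0)
        ).to_numpy()
        names = table["gene"].to_numpy()
    order = np.lexsort((names, dist))
    return str(names[order[0]])


# ---------------------------------------------------------------------------
# enriched-SV screen
# ---------------------------------------------------------------------------

def tesv_screen(
    svs: pd.DataFrame,
    target: str,
    refs,
    min_div: float = 0.20,
) -> pd.DataFrame:
    """Keep SVs whose target frequency exceeds every reference by > min_div.

    The divergence is signed (target − reference), so only target-enriched
    SVs pass; a divergence exactly at ``min_div`` is dropped.  Adds a
    ``min_divergence`` column (the smallest of the per-reference
    divergences).
    """
    refs = list(refs)
    if not refs:
        raise ValueError("no reference populations supplied")
    t = svs[f"freq_{target}"].to_numpy(float)
    divs = np.stack([t - svs[f"freq_{r}"].to_numpy(float) for r in refs])
    min_divergence = divs.min(axis=0)
    keep = min_divergence > min_div
    out = svs.loc[keep].copy()
    out["min_divergence"] = min_divergence[keep]
    return out


def low_frequency_fraction(svs: pd.DataFrame, pop: str, cutoff: float = 0.01) -> float:
    """Fraction of SVs whose frequency in ``pop`` is below ``cutoff``."""
    f = svs[f"freq_{pop}"].to_numpy(float)
    return float((f < cutoff).mean())


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    stats: pd.DataFrame
    regions: list
    regions_table: pd.DataFrame
    manifest: dict
    hm: HaplotypeMatrix = None
    panel: PopulationPanel = None


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def scan_matrices(
    hm: HaplotypeMatrix,
    panel: PopulationPanel,
    genes: GeneModel | None,
    cfg: RunConfig,
) -> ScanResult:
    """Run the full nomination pipeline on in-memory inputs.

    Stages: variant QC → per-population DAF/FST/HWE → iHS/XPEHH → CMS →
    top-quantile candidates → enrichment filter (TSNS) → LD clumping →
    lead-gene assignment.  Deterministic given inputs and configuration.
    """
    if cfg.target is None or not cfg.refs:
        raise PipelineError("stage 'config' failed: target and refs are required")
    han = cfg.han or cfg.refs[0]
    counts = {"input_variants": hm.n_variants}

    hwe_samples = panel.sample_indices(hm, cfg.target)
    hm_qc, qc_report = _stage("qc")(
        qc_filter,
        hm,
        max_missing=cfg.max_missing,
        hwe_floor=cfg.hwe_floor,
        drop_singletons=cfg.drop_singletons,
        hwe_samples=hwe_samples,
    )
    counts["after_qc"] = hm_qc.n_variants

    def freq_stage():
        table = pd.DataFrame(
            {
                "chrom": hm_qc.chrom,
                "pos": hm_qc.positions,
                "ref": hm_qc.ref_allele,
                "alt": hm_qc.alt_allele,
                "ancestral": hm_qc.ancestral_state_labels(),
                "vidx": np.arange(hm_qc.n_variants),
            }
        )
        for pop in [cfg.target] + [r for r in cfg.refs if r != cfg.target]:
            table[f"daf_{pop}"] = derived_allele_frequency(hm_qc, panel, pop)
        table["fst"] = wc_fst(hm_qc, panel, cfg.target, han)
        table["delta_daf"] = table[f"daf_{cfg.target}"] - table[f"daf_{han}"]
        table["hwe_p"] = hwe_exact_pvalues(
            hm_qc, panel.sample_indices(hm_qc, cfg.target)
        )
        return table

    table = _stage("frequencies")(freq_stage)

    def hap_stage():
        ihs_df = ihs(
            hm_qc, panel, cfg.target,
            min_maf=cfg.min_maf, threshold=cfg.ehh_threshold, bins=cfg.ihs_bins,
        )
        xp_df = xpehh(hm_qc, panel, cfg.target, han, threshold=cfg.ehh_threshold)
        table["ihs"] = ihs_df["ihs_std"].to_numpy()
        table["xpehh"] = xp_df["xpehh_std"].to_numpy()
        return table

    table = _stage("haplotype_stats")(hap_stage)
    table = _stage("cms")(cms_scores, table)
    counts["cms_scored"] = int(table["cms"].notna().sum())

    chosen, threshold = _stage("top_quantile")(top_quantile, table, cfg.q)
    table["candidate"] = False
    table.loc[chosen, "candidate"] = True
    counts["candidates"] = int(len(chosen))

    keep, enr_report = _stage("enrichment")(
        enrichment_filter, table.loc[chosen], cfg.target, cfg.refs, han
    )
    table["tsns"] = False
    table.loc[chosen[keep], "tsns"] = True
    counts["tsns"] = int(keep.sum())

    table["hwe_selection"] = _stage("hwe_screen")(
        flag_hwe_selection_candidates,
        table, cfg.hwe_selection_cut, cfg.fst_selection_cut,
    )

    tsns_table = table[table["tsns"]]
    regions, n_r2_missing = _stage("clump")(
        ld_clump,
        tsns_table, hm_qc, panel, cfg.target,
        r2_max=cfg.r2_max, window=cfg.clump_window,
    )
    counts["regions"] = len(regions)

    def gene_stage():
        for region in regions:
            region.lead_gene = (
                assign_lead_gene(region, genes, hm_qc.chrom)
                if genes is not None
                else None
            )

    _stage("genes")(gene_stage)

    regions_table = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "lead_pos": r.lead_pos,
                "lead_cms": r.lead_cms,
                "n_members": len(r.member_vidx),
                "span_start": r.span[0],
                "span_end": r.span[1],
                "lead_gene": r.lead_gene,
            }
            for r in regions
        ],
        columns=[
            "region_id", "lead_pos", "lead_cms", "n_members",
            "span_start", "span_end", "lead_gene",
        ],
    )

    manifest = {
        "tool": "tsnscan",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.as_dict(),
        "gap_policy": "none (no maximum marker gap)",
        "counts": counts,
        "qc_report": qc_report.as_dict(),
        "enrichment_report": enr_report,
        "cms_threshold": threshold,
        "clump_r2_unavailable_pairs": n_r2_missing,
    }
    return ScanResult(
        stats=table,
        regions=regions,
        regions_table=regions_table,
        manifest=manifest,
        hm=hm_qc,
        panel=panel,
    )


def run_full_scan(cfg: RunConfig) -> ScanResult:
    """Load inputs from the paths in ``cfg``, run the scan, write outputs.

    Writes ``stats.tsv``, ``tsns.tsv``, ``regions.tsv``, ``genes.tsv`` and
    ``manifest.json`` (timestamp kept in its own field so that reruns are
    otherwise identical) into ``cfg.out_dir``.
    """
    hm = _stage("load_vcf")(read_phased_vcf, cfg.vcf, cfg.region)
    panel = _stage("load_panel")(read_population_panel, cfg.panel)
    genes = (
        _stage("load_genes")(read_gene_model, cfg.genes, cfg.gene_flank)
        if cfg.genes
        else None
    )
    result = scan_matrices(hm, panel, genes, cfg)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stats_table(result.stats, out / "stats.tsv")
        tsns = result.stats[result.stats["tsns"]]
        if len(tsns):
            write_stats_table(tsns, out / "tsns.tsv")
        else:
            (out / "tsns.tsv").write_text("")
        result.regions_table.to_csv(
            out / "regions.tsv", sep="\t", index=False, na_rep="NA",
            lineterminator="\n",
        )
        gene_rows = result.regions_table[["region_id", "lead_gene"]]
        gene_rows.to_csv(
            out / "genes.tsv", sep="\t", index=False, na_rep="NA",
            lineterminator="\n",
        )
        import datetime

        manifest = dict(result.manifest)
        manifest["timestamp"] = datetime.datetime.now().isoformat()
        with open(out / "manifest.json", "w", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, default=str)
            fh.write("\n")
    return result
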