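"""Readers/writers for the standard formats the scan touches, and the in-memory data model.

The central container is :class:`HaplotypeMatrix`: phased biallelic SNVs by
haplotypes, with per-variant physical positions, alleles and ancestral state.
Internal coordinates are 1-based inclusive (the VCF convention); BED input is
converted on read.  Haplotypes ``2k`` and ``2k+1`` belong to sample ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import GeneModelError, PanelError, VcfParseError

MISSING = np.int8(-1)

#: ancestral_state codes: 0 = reference allele is ancestral, 1 = alternate
#: allele is ancestral, -1 = unknown (no usable AA annotation).
ANC_REF, ANC_ALT, ANC_UNKNOWN = np.int8(0), np.int8(1), np.int8(-1)

_NUCLEOTIDES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased biallelic variants × haplotypes.

    Attributes
    ----------
    chrom : str
        Chromosome identifier (one per matrix).
    positions : ndarray of int64
        1-based physical coordinates, strictly increasing.
    ref_allele, alt_allele : ndarray of str
        Single-nucleotide alleles.
    ancestral : ndarray of int8
        Per-variant ancestral state code (``ANC_REF``/``ANC_ALT``/``ANC_UNKNOWN``).
    calls : ndarray of int8, shape (n_variants, n_haplotypes)
        0 = reference, 1 = alternate, -1 = missing.
    sample_ids : list of str
        Haplotype columns ``2k`` and ``2k+1`` belong to ``sample_ids[k]``.
    skip_report : dict
        Counts of records dropped on read, keyed by reason.
    """

    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    ancestral: np.ndarray
    calls: np.ndarray
    sample_ids: list
    skip_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        self.ref_allele = np.asarray(self.ref_allele)
        self.alt_allele = np.asarray(self.alt_allele)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (variants x haplotypes)")
        if self.calls.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and calls disagree on variant count")
        if self.calls.shape[1] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be 2 x sample count")
        if self.n_variants > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls entries must be in {0, 1, missing}")

    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def ancestral_state_labels(self) -> np.ndarray:
        """Per-variant ancestral state as {'ref','alt','unknown'} strings."""
        out = np.full(self.n_variants, "unknown", dtype=object)
        out[self.ancestral == ANC_REF] = "ref"
        out[self.ancestral == ANC_ALT] = "alt"
        return out

    def take_variants(self, index) -> "HaplotypeMatrix":
        """Subset variants by boolean mask or integer index (order preserved)."""
        idx = np.asarray(index)
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            ancestral=self.ancestral[idx],
            calls=self.calls[idx],
            sample_ids=list(self.sample_ids),
        )

    def haplotype_columns(self, sample_indices) -> np.ndarray:
        """Haplotype column indices for the given sample indices."""
        s = np.asarray(sample_indices, dtype=np.int64)
        return np.stack([2 * s, 2 * s + 1], axis=1).ravel()


@dataclass
class PopulationPanel:
    """sample_id → population label assignments."""

    assignments: dict

    def populations(self) -> list:
        seen = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples_for(self, pop: str) -> list:
        return [s for s, p in self.assignments.items() if p == pop]

    def sample_indices(self, hm: HaplotypeMatrix, pop: str) -> np.ndarray:
        """Indices (into hm.sample_ids) of samples assigned to ``pop``."""
        if pop not in self.assignments.values():
            raise PanelError(f"unknown population label: {pop!r}")
        wanted = {s for s, p in self.assignments.items() if p == pop}
        idx = np.array(
            [i for i, s in enumerate(hm.sample_ids) if s in wanted], dtype=np.int64
        )
        if idx.size == 0:
            raise PanelError(
                f"no samples of population {pop!r} present in the matrix"
            )
        return idx

    def haplotype_indices(self, hm: HaplotypeMatrix, pop: str) -> np.ndarray:
        return hm.haplotype_columns(self.sample_indices(hm, pop))


#: canonical gene-model column order
GENE_COLUMNS = [
    "gene", "chrom", "body_start", "body_end", "strand",
    "region_start", "region_end",
]


@dataclass
class GeneModel:
    """Gene bodies plus flanked gene regions (1-based inclusive coordinates).

    The gene region is the body extended by ``flank`` bp on both sides
    (floored at position 1).
    """

    table: pd.DataFrame
    flank: int = 5000

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _parse_region(region):
    if region is None:
        return None, None, None
    if isinstance(region, (tuple, list)):
        return region[0], int(region[1]), int(region[2])
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, None, None
    start, _, end = span.partition("-")
    return chrom, int(start), int(end)


def read_phased_vcf(path, region=None) -> HaplotypeMatrix:
    """Read a phased multi-sample VCF into a :class:`HaplotypeMatrix`.

    Only biallelic SNV records are retained; multi-allelic, indel and
    symbolic records are dropped and counted in ``skip_report``.  The
    ancestral allele is taken from the ``AA`` INFO key; when absent or not
    matching ref/alt (case-insensitive) the variant's ancestral state is
    unknown.  Unphased heterozygous genotypes become missing haplotype
    entries (unphased homozygotes are unambiguous and kept); half-missing
    genotypes contribute their known haplotype only.

    Parameters
    ----------
    path : str or Path
        Plain-text or bgzipped VCF.
    region : str or (chrom, start, end), optional
        ``"chrom:start-end"``; an empty region yields an empty matrix.
    """
    want_chrom, want_start, want_end = _parse_region(region)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vf.header.samples)
    n_hap = 2 * len(sample_ids)
    positions, refs, alts, ancs, rows = [], [], [], [], []
    skip = {"multiallelic": 0, "non_snv": 0, "duplicate_position": 0}
    chrom_seen = want_chrom
    lineno = len(str(vf.header).splitlines())

    iterator = iter(vf)
    while True:
        try:
            rec = next(iterator)
        except StopIteration:
            break
        except Exception as exc:
            raise VcfParseError(
                f"malformed VCF record near line {lineno + 1}: {exc}"
            ) from exc
        lineno += 1
        try:
            if want_chrom is not None and rec.chrom != want_chrom:
                continue
            if want_start is not None and not (want_start <= rec.pos <= want_end):
                continue
            if chrom_seen is None:
                chrom_seen = rec.chrom
            elif rec.chrom != chrom_seen:
                raise VcfParseError(
                    f"line {lineno}: multiple chromosomes in input "
                    f"({chrom_seen!r}, {rec.chrom!r}); read one region at a time"
                )
            if rec.alts is None or len(rec.alts) != 1:
                skip["multiallelic"] += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
                skip["non_snv"] += 1
                continue
            if positions and rec.pos <= positions[-1]:
                if rec.pos == positions[-1]:
                    skip["duplicate_position"] += 1
                    continue
                raise VcfParseError(f"line {lineno}: positions not sorted")

            row = np.full(n_hap, MISSING, dtype=np.int8)
            for k, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or len(gt) != 2:
                    continue
                a, b = gt
                het = a is not None and b is not None and a != b
                if het and not sample.phased:
                    continue  # unphased het: haplotype assignment unknown
                if a is not None:
                    row[2 * k] = a
                if b is not None:
                    row[2 * k + 1] = b

            aa = rec.info.get("AA")
            if isinstance(aa, (tuple, list)):
                aa = aa[0]
            if aa is not None:
                aa = str(aa).upper().rstrip(".|")
            if aa == ref:
                anc = ANC_REF
            elif aa == alt:
                anc = ANC_ALT
            else:
                anc = ANC_UNKNOWN

            positions.append(rec.pos)
            refs.append(ref)
            alts.append(alt)
            ancs.append(anc)
            rows.append(row)
        except VcfParseError:
            raise
        except Exception as exc:  # malformed record content
            raise VcfParseError(f"line {lineno}: {exc}") from exc

    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, n_hap), dtype=np.int8)
    )
    hm = HaplotypeMatrix(
        chrom=chrom_seen if chrom_seen is not None else "",
        positions=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        ancestral=np.array(ancs, dtype=np.int8),
        calls=calls,
        sample_ids=sample_ids,
    )
    hm.skip_report = skip
    return hm


def write_phased_vcf(hm: HaplotypeMatrix, path) -> None:
    """Write a :class:`HaplotypeMatrix` as a minimal phased VCF 4.2 file.

    Ancestral states are emitted as ``AA=`` INFO entries (omitted when
    unknown); missing haplotypes become ``.`` alleles.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hm.sample_ids)
            + "\n"
        )
        code = {0: "0", 1: "1", -1: "."}
        for v in range(hm.n_variants):
            ref, alt = hm.ref_allele[v], hm.alt_allele[v]
            if hm.ancestral[v] == ANC_REF:
                info = f"AA={ref}"
            elif hm.ancestral[v] == ANC_ALT:
                info = f"AA={alt}"
            else:
                info = "."
            gts = "\t".join(
                f"{code[int(hm.calls[v, 2 * k])]}|{code[int(hm.calls[v, 2 * k + 1])]}"
                for k in range(hm.n_samples)
            )
            fh.write(
                f"{hm.chrom}\t{hm.positions[v]}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# panel / gene model / SV table
# ---------------------------------------------------------------------------

def read_population_panel(path) -> PopulationPanel:
    """Read a two-column TSV (sample_id, population); header row optional."""
    assignments = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise PanelError(f"empty panel file: {path}")
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise PanelError(f"panel line {i + 1}: expected 2 tab-separated columns")
        sid, pop = parts[0].strip(), parts[1].strip()
        if i == 0 and sid.lower() in {"sample", "sample_id"}:
            continue
        if not pop:
            raise PanelError(f"panel line {i + 1}: empty population label")
        if sid in assignments:
            raise PanelError(f"duplicate sample id in panel: {sid!r}")
        assignments[sid] = pop
    if not assignments:
        raise PanelError(f"no assignments in panel file: {path}")
    return PopulationPanel(assignments)


def read_gene_model(path, flank: int = 5000) -> GeneModel:
    """Read a BED4(+) gene file into a :class:`GeneModel`.

    BED is 0-based half-open; bodies are converted to 1-based inclusive and
    the gene region is the body ± ``flank`` bp, floored at 1.
    """
    rows = []
    names_per_chrom = {}
    with open(path) as fh:
        for i, ln in enumerate(fh):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 4 or not parts[3].strip():
                raise GeneModelError(f"BED line {i + 1}: missing name column")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start > end:
                raise GeneModelError(f"BED line {i + 1}: start > end")
            seen = names_per_chrom.setdefault(chrom, set())
            if name in seen:
                raise GeneModelError(f"BED line {i + 1}: duplicate gene name {name!r}")
            seen.add(name)
            strand = parts[5] if len(parts) > 5 else "."
            body_start, body_end = start + 1, end
            rows.append(
                {
                    "gene": name,
                    "chrom": chrom,
                    "body_start": body_start,
                    "body_end": body_end,
                    "strand": strand,
                    "region_start": max(1, body_start - flank),
                    "region_end": body_end + flank,
                }
            )
    table = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return GeneModel(table=table, flank=flank)


SV_TYPES = frozenset({"DEL", "DUP", "INS", "INV"})


def read_sv_table(path) -> pd.DataFrame:
    """Read an SV per-population frequency TSV.

    Columns: sv_id, chrom, pos, sv_type, then one ``freq_<POP>`` column per
    population, each in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sv_id", "chrom", "pos", "sv_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SV table missing required columns: {sorted(missing)}")
    bad_types = set(df["sv_type"]) - SV_TYPES
    if bad_types:
        raise ValueError(f"unknown sv_type values: {sorted(bad_types)}")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    for c in freq_cols:
        vals = df[c].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"frequencies in column {c} outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# per-variant statistics table
# ---------------------------------------------------------------------------

#: canonical leading column order for the per-variant statistics TSV;
#: population-specific DAF columns (daf_<POP>) and any extras follow.
STATS_LEAD_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ancestral",
    "fst", "delta_daf", "hwe_p", "ihs", "xpehh",
    "p_fst", "p_delta_daf", "p_ihs", "p_xpehh", "cms",
    "tsns", "hwe_selection",
]


def write_stats_table(table: pd.DataFrame, path) -> None:
    """Write a per-variant statistics table as TSV.

    Fixed column order (canonical columns first, extras after), tab
    separator, ``NA`` for missing, LF line ends, 6-significant-digit floats.
    """
    if table.empty:
        raise ValueError("refusing to write an empty statistics table")
    lead = [c for c in STATS_LEAD_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in lead]
    out = table[lead + extra]
    out.to_csv(
        path, sep="\t", index=False, na_rep="NA",
        float_format="%.6g", lineterminator="\n",
    )


def read_stats_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_stats_table`."""
    return pd.read_csv(path, sep="\t", na_values="NA")
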