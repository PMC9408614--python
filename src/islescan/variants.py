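"""VCF input/output, genotype and site filtering, Ts/Tv, polarization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from islescan.genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
_BASES = frozenset("ACGT")


def read_vcf(path) -> GenotypeMatrix:
    """Load biallelic SNV records from a VCF 4.2 file.

    Multi-allelic or non-SNV records are skipped (count logged).
    Half-missing diploid genotypes are treated as missing. DP and GQ
    default to 0 when the FORMAT fields are absent.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt = [], [], [], []
    calls_cols, dp_cols, gq_cols = [], [], []
    n_skipped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or rec.REF not in _BASES
            or rec.ALT[0] not in _BASES
        ):
            n_skipped += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # decode from allele pairs so half-missing (./x) counts as missing
        alleles = np.asarray(rec.genotypes, dtype=np.int64)[:, :2]
        gt = alleles.sum(axis=1).astype(np.int8)
        gt[(alleles < 0).any(axis=1)] = MISSING
        calls_cols.append(gt)
        dp_cols.append(_format_field(rec, "DP", len(samples)))
        gq_cols.append(_format_field(rec, "GQ", len(samples)))
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNV records", n_skipped)
    m = len(pos)
    n = len(samples)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=np.column_stack(calls_cols) if m else np.empty((n, 0), np.int8),
        depth=np.column_stack(dp_cols) if m else np.empty((n, 0), np.int32),
        gq=np.column_stack(gq_cols) if m else np.empty((n, 0), np.int32),
    )


def _format_field(rec, key: str, n: int) -> np.ndarray:
    try:
        vals = rec.format(key)
    except KeyError:
        vals = None
    if vals is None:
        return np.zeros(n, dtype=np.int32)
    out = np.asarray(vals).reshape(n, -1)[:, 0].astype(np.int64)
    out[out < 0] = 0  # cyvcf2 encodes missing as a negative sentinel
    return out.astype(np.int32)


def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file with GT:DP:GQ."""
    gt_strings = np.array(["0/0", "0/1", "1/1"], dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=islescan\n")
        for c in gm.chromosomes():
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_sites):
            col = gm.calls[:, j]
            fields = [
                f"{gt_strings[g] if g != MISSING else './.'}:{dp}:{gq}"
                for g, dp, gq in zip(col, gm.depth[:, j], gm.gq[:, j])
            ]
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}"
                "\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(fields) + "\n"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for per-call masking and per-site removal."""

    depth_lo_frac: float = 0.60
    depth_hi_frac: float = 2.50
    min_gq: int = 20
    min_call_rate: float = 0.95
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.depth_lo_frac < self.depth_hi_frac:
            raise ValueError("need 0 <= depth_lo_frac < depth_hi_frac")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0, 1]")


@dataclass
class FilterReport:
    """Tallies of the effect of each filtering rule."""

    sites_input: int
    calls_masked_depth: int
    calls_masked_gq: int
    sites_dropped_callrate: int
    sites_dropped_maf: int
    sites_retained: int

    def __post_init__(self) -> None:
        removed = self.sites_dropped_callrate + self.sites_dropped_maf
        if removed + self.sites_retained != self.sites_input:
            raise ValueError("report tallies do not reconcile")

    def to_tsv(self, path) -> None:
        items = asdict(self)
        pd.DataFrame({"rule": list(items), "count": list(items.values())}).to_csv(
            path, sep="\t", index=False
        )


def filter_genotypes_and_sites(
    gm: GenotypeMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply per-call depth/GQ masking, then per-site call-rate/MAF removal.

    Rule order:

    1. mask calls whose DP is strictly below ``depth_lo_frac`` or strictly
       above ``depth_hi_frac`` times the individual's mean DP (mean taken
       over all input sites, once, before any masking);
    2. mask calls with GQ strictly below ``min_gq``;
    3. drop sites whose call rate (over all samples) falls below
       ``min_call_rate``, or whose minor allele frequency, computed from
       the surviving calls, falls below ``min_maf``.
    """
    calls = gm.calls.copy()
    called0 = calls != MISSING

    mean_dp = gm.depth.mean(axis=1, keepdims=True)  # per individual, all sites
    lo = cfg.depth_lo_frac * mean_dp
    hi = cfg.depth_hi_frac * mean_dp
    bad_depth = called0 & ((gm.depth < lo) | (gm.depth > hi))
    calls[bad_depth] = MISSING

    bad_gq = (calls != MISSING) & (gm.gq < cfg.min_gq)
    calls[bad_gq] = MISSING

    called = calls != MISSING
    call_rate = called.mean(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)

    fail_rate = call_rate < cfg.min_call_rate
    fail_maf = ~fail_rate & (maf < cfg.min_maf)
    keep = ~(fail_rate | fail_maf)

    out = gm.copy()
    out.calls = calls
    out = out.take_sites(keep)
    report = FilterReport(
        sites_input=gm.n_sites,
        calls_masked_depth=int(bad_depth.sum()),
        calls_masked_gq=int(bad_gq.sum()),
        sites_dropped_callrate=int(fail_rate.sum()),
        sites_dropped_maf=int(fail_maf.sum()),
        sites_retained=int(keep.sum()),
    )
    return out, report


def ts_tv_ratio(gm: GenotypeMatrix) -> float:
    """Transition/transversion ratio over sites (A<->G, C<->T are Ts)."""
    if gm.n_sites == 0:
        raise ValueError("empty matrix")
    is_ts = np.fromiter(
        ((r, a) in _TRANSITIONS for r, a in zip(gm.ref, gm.alt)),
        dtype=bool,
        count=gm.n_sites,
    )
    n_tv = int((~is_ts).sum())
    if n_tv == 0:
        raise ValueError("no transversion sites; Ts/Tv undefined")
    return float(is_ts.sum()) / n_tv


def polarize(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Mark the reference allele as ancestral at every site.

    The reference is the outgroup base by construction of the alignment,
    so the derived allele frequency equals the alt-allele frequency.
    Idempotent.
    """
    out = gm.copy()
    out.ancestral_is_ref = np.ones(gm.n_sites, dtype=bool)
    return out


def derived_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site derived (alt) allele frequency from called alleles."""
    alt, tot = gm.allele_counts()
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
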