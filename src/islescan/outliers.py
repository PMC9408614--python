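"""Top-percentile window selection, peak merging, three-statistic
intersection, per-SNV differentiation with flanks, and annotation.

All intervals here are 1-based inclusive (matching the scan table);
gene/TFBS tracks arrive as BED (0-based half-open) and are converted on
entry via :mod:`islescan.bedio`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from islescan.bedio import bed_to_inclusive
from islescan.genotypes import CohortDesign, GenotypeMatrix
from islescan.winstats import site_theta


@dataclass(frozen=True)
class Peak:
    """Maximal union of overlapping/abutting outlier windows."""

    chrom: str
    start: int
    end: int
    statistic: str
    max_z: float
    n_windows: int


@dataclass(frozen=True)
class CandidateRegion:
    """Intersection interval of mutually overlapping per-statistic peaks."""

    chrom: str
    start: int
    end: int
    score: float  # summed per-statistic z maxima
    rank: int = 0


def top_windows(
    scan: pd.DataFrame, statistic: str, q: float = 0.99, min_finite: int = 100
) -> pd.DataFrame:
    """Windows in the upper tail: value >= the empirical q-quantile of
    finite entries of ``statistic`` (ties included)."""
    vals = scan[statistic].to_numpy(dtype=np.float64)
    finite = np.isfinite(vals)
    if finite.sum() < min_finite:
        raise ValueError(
            f"only {int(finite.sum())} finite windows for {statistic!r}; "
            f"need >= {min_finite}"
        )
    cut = np.quantile(vals[finite], q)
    return scan[finite & (vals >= cut)].copy()


def merge_peaks(windows: pd.DataFrame, statistic: str) -> list[Peak]:
    """Merge outlier windows that overlap or abut (gap 0) per chromosome."""
    if windows.empty:
        return []
    zcol = f"z_{statistic}" if f"z_{statistic}" in windows.columns else statistic
    df = windows.sort_values(["chrom", "start", "end"])
    peaks: list[Peak] = []
    cur = None
    for row in df.itertuples(index=False):
        z = float(getattr(row, zcol))
        if cur is not None and row.chrom == cur[0] and row.start <= cur[2] + 1:
            cur = (cur[0], cur[1], max(cur[2], int(row.end)),
                   max(cur[3], z), cur[4] + 1)
        else:
            if cur is not None:
                peaks.append(Peak(cur[0], cur[1], cur[2], statistic, cur[3], cur[4]))
            cur = (row.chrom, int(row.start), int(row.end), z, 1)
    peaks.append(Peak(cur[0], cur[1], cur[2], statistic, cur[3], cur[4]))
    return peaks


def intersect_peaks(
    peaks_fst: list[Peak],
    peaks_dpi: list[Peak],
    peaks_dtajd: list[Peak],
) -> list[CandidateRegion]:
    """Candidate regions: intersection intervals of triples of mutually
    overlapping peaks (one per statistic); overlapping candidates are
    merged and ranked by summed per-statistic z maxima (descending)."""
    raw: list[tuple[str, int, int, float]] = []
    for pf in peaks_fst:
        for pp in peaks_dpi:
            if pp.chrom != pf.chrom or pp.start > pf.end or pp.end < pf.start:
                continue
            for pt in peaks_dtajd:
                if pt.chrom != pf.chrom:
                    continue
                start = max(pf.start, pp.start, pt.start)
                end = min(pf.end, pp.end, pt.end)
                if start <= end:
                    raw.append((pf.chrom, start, end, pf.max_z + pp.max_z + pt.max_z))
    if not raw:
        return []
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[list] = []
    for chrom, start, end, score in raw:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3] = max(merged[-1][3], score)
        else:
            merged.append([chrom, start, end, score])
    merged.sort(key=lambda t: (-t[3], t[0], t[1]))
    return [
        CandidateRegion(chrom=c, start=s, end=e, score=sc, rank=i + 1)
        for i, (c, s, e, sc) in enumerate(merged)
    ]


def per_snv_diff(
    gm: GenotypeMatrix,
    design: CohortDesign,
    region: CandidateRegion,
    flank: int = 150_000,
    case: str = "case",
    control: str = "control_a",
) -> pd.DataFrame:
    """Allelic Fst (single-site Weir theta) and absolute allele-frequency
    difference for every SNV within ``flank`` bp of the region."""
    lo = max(1, region.start - flank)
    hi = region.end + flank
    in_reg = (gm.chrom == region.chrom) & (gm.pos >= lo) & (gm.pos <= hi)
    sub = gm.take_sites(in_reg)
    cols = ["chrom", "pos", "allelic_fst", "daf"]
    if sub.n_sites == 0:
        return pd.DataFrame(columns=cols)
    idx_case = sub.sample_index(design.members(case))
    idx_ctl = sub.sample_index(design.members(control))
    theta = site_theta(sub, idx_case, idx_ctl)

    def freq(idx):
        alt, tot = sub.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    daf = np.abs(freq(idx_case) - freq(idx_ctl))
    return pd.DataFrame(
        {"chrom": sub.chrom, "pos": sub.pos, "allelic_fst": theta, "daf": daf}
    )


def select_differentiated(records: pd.DataFrame, min_daf: float = 0.45) -> pd.DataFrame:
    """SNVs whose allele-frequency difference strictly exceeds ``min_daf``."""
    if records.empty:
        return records.copy()
    return records[records["daf"] > min_daf].copy()


def annotate(
    records: pd.DataFrame, genes: pd.DataFrame, tfbs: pd.DataFrame
) -> pd.DataFrame:
    """Attach nearest gene (id + bp distance, 0 if inside; lexicographic
    tie-break) and a within-TFBS membership flag. Tracks are BED."""
    out = records.copy()
    if out.empty:
        out["gene"] = pd.Series(dtype=object)
        out["gene_dist"] = pd.Series(dtype="int64")
        out["in_tfbs"] = pd.Series(dtype=bool)
        return out

    g1 = bed_to_inclusive(genes) if len(genes) else genes
    t1 = bed_to_inclusive(tfbs) if len(tfbs) else tfbs

    names, dists, flags = [], [], []
    for row in out.itertuples(index=False):
        pos = int(row.pos)
        best = None
        if len(g1):
            gc = g1[g1["chrom"] == row.chrom]
            for grow in gc.itertuples(index=False):
                d = max(0, grow.start - pos, pos - grow.end)
                key = (d, str(grow.name))
                if best is None or key < best:
                    best = key
        if best is None:
            names.append(None)
            dists.append(-1)
        else:
            dists.append(best[0])
            names.append(best[1])
        if len(t1):
            tc = t1[t1["chrom"] == row.chrom]
            flags.append(bool(((tc["start"] <= pos) & (pos <= tc["end"])).any()))
        else:
            flags.append(False)
    out["gene"] = names
    out["gene_dist"] = dists
    out["in_tfbs"] = flags
    return out


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.rank, r.chrom, r.start, r.end, r.score) for r in regions],
        columns=["rank", "chrom", "start", "end", "score"],
    )
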