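"""Sliding-window runs of homozygosity, FROH, sharing tracks, and
cohort-differential candidate ROH regions.

The caller mirrors a window-based ROH scan: a fixed-size SNV window
slides one SNV at a time, each window is classified homozygous if it
holds at most ``max_het_per_window`` heterozygous and
``max_miss_per_window`` missing calls, and a SNV is in-run when the
proportion of windows covering it that are homozygous-classified
reaches ``min_prop_hom_windows``. Runs are SNV-delimited, split at
gaps, and filtered by count, length and density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from islescan.genotypes import MISSING, CohortDesign, GenotypeMatrix


@dataclass(frozen=True)
class ROHParams:
    window_snv: int = 50
    min_prop_hom_windows: float = 0.05
    max_het_per_window: int = 1
    max_miss_per_window: int = 2
    min_snv_in_run: int = 2
    min_length_bp: int = 100_000
    min_density_bp_per_snv: int = 50_000  # at least one SNV per this many bp
    max_gap_bp: int = 100_000

    def __post_init__(self) -> None:
        if min(self.window_snv, self.min_snv_in_run, self.min_length_bp,
               self.min_density_bp_per_snv, self.max_gap_bp) <= 0:
            raise ValueError("ROH parameters must be positive")
        if not 0 < self.min_prop_hom_windows <= 1:
            raise ValueError("min_prop_hom_windows must be in (0, 1]")


@dataclass(frozen=True)
class ROHRun:
    sample: str
    chrom: str
    start: int  # position of first member SNV, 1-based
    end: int    # position of last member SNV
    n_snv: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(gm: GenotypeMatrix, sample: str, params: ROHParams = ROHParams()) -> list[ROHRun]:
    """Call ROH runs for one sample over an (LD-pruned) genotype track."""
    si = gm.sample_index([sample])[0]
    runs: list[ROHRun] = []
    for chrom in gm.chromosomes():
        idx = np.flatnonzero(gm.chrom == chrom)
        if len(idx) < params.window_snv:
            warnings.warn(
                f"chromosome {chrom} has {len(idx)} SNVs "
                f"(< window of {params.window_snv}); skipped",
                stacklevel=2,
            )
            continue
        calls = gm.calls[si, idx]
        pos = gm.pos[idx]
        in_run = _in_run_snvs(calls, params)
        runs.extend(_snvs_to_runs(sample, chrom, pos, in_run, params))
    return runs


def _in_run_snvs(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNV flag: fraction of covering windows classified homozygous
    is >= min_prop_hom_windows (edge SNVs have fewer covering windows)."""
    w = params.window_snv
    n = len(calls)
    het = np.cumsum(np.concatenate([[0], calls == 1]))
    mis = np.cumsum(np.concatenate([[0], calls == MISSING]))
    starts = np.arange(n - w + 1)
    hom_win = (
        (het[starts + w] - het[starts] <= params.max_het_per_window)
        & (mis[starts + w] - mis[starts] <= params.max_miss_per_window)
    )
    hw = np.cumsum(np.concatenate([[0], hom_win]))
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n - w)
    n_cover = hi - lo + 1
    n_hom = hw[hi + 1] - hw[lo]
    return n_hom / n_cover >= params.min_prop_hom_windows


def _snvs_to_runs(sample, chrom, pos, in_run, params) -> list[ROHRun]:
    runs = []
    member = np.flatnonzero(in_run)
    if len(member) == 0:
        return runs
    # break at non-consecutive SNV indices or at oversized physical gaps
    breaks = np.flatnonzero(
        (np.diff(member) > 1) | (np.diff(pos[member]) > params.max_gap_bp)
    )
    for seg in np.split(member, breaks + 1):
        n_snv = len(seg)
        start, end = int(pos[seg[0]]), int(pos[seg[-1]])
        length = end - start + 1
        if n_snv < params.min_snv_in_run or length < params.min_length_bp:
            continue
        if length > n_snv * params.min_density_bp_per_snv:
            continue  # fails minimum SNV density
        runs.append(ROHRun(sample=sample, chrom=chrom, start=start, end=end, n_snv=n_snv))
    return runs


def detect_roh_all(
    gm: GenotypeMatrix, params: ROHParams = ROHParams()
) -> dict[str, list[ROHRun]]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {s: detect_roh(gm, s, params) for s in gm.samples}


def froh(runs: list[ROHRun], gm: GenotypeMatrix) -> float:
    """Genomic inbreeding coefficient: summed run length over the SNV map
    length (per-chromosome first-to-last SNV spans)."""
    if gm.n_sites == 0:
        raise ValueError("empty SNV map")
    total = 0
    for c in gm.chromosomes():
        p = gm.pos[gm.chrom == c]
        total += int(p.max() - p.min() + 1)
    return sum(r.length for r in runs) / total


def runs_to_frame(runs_by_sample: dict[str, list[ROHRun]]) -> pd.DataFrame:
    rows = [
        (s, r.chrom, r.start, r.end, r.n_snv, r.length)
        for s, runs in runs_by_sample.items()
        for r in runs
    ]
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_snv", "length"])


def roh_sharing(
    runs_by_sample: dict[str, list[ROHRun]],
    design: CohortDesign,
    gm: GenotypeMatrix,
) -> pd.DataFrame:
    """Per SNV and cohort, the proportion of cohort members whose run
    covers the SNV. Columns: chrom, pos, then one column per cohort."""
    out = pd.DataFrame({"chrom": gm.chrom, "pos": gm.pos})
    for cohort in design.cohorts():
        members = design.members(cohort)
        covered = np.zeros(gm.n_sites, dtype=np.int64)
        for s in members:
            mask = np.zeros(gm.n_sites, dtype=bool)
            for r in runs_by_sample.get(s, []):
                mask |= (gm.chrom == r.chrom) & (gm.pos >= r.start) & (gm.pos <= r.end)
            covered += mask
        out[cohort] = covered / len(members)
    return out


def candidate_roh(
    track: pd.DataFrame,
    case: str = "case",
    controls: tuple[str, ...] = ("control_a", "control_b"),
    hi: float = 0.75,
    lo: float = 0.75,
) -> pd.DataFrame:
    """Maximal stretches of consecutive SNVs shared by > ``hi`` of cases
    and < ``lo`` of every control cohort; 1-based inclusive intervals."""
    ok = track[case].to_numpy() > hi
    for ctl in controls:
        ok &= track[ctl].to_numpy() < lo
    rows = []
    chrom = track["chrom"].to_numpy()
    pos = track["pos"].to_numpy()
    member = np.flatnonzero(ok)
    if len(member):
        breaks = np.flatnonzero(
            (np.diff(member) > 1) | (chrom[member][1:] != chrom[member][:-1])
        )
        for seg in np.split(member, breaks + 1):
            rows.append((chrom[seg[0]], int(pos[seg[0]]), int(pos[seg[-1]]), len(seg)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snv"])
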