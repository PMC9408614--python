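"""Genotypic r-squared, LD pruning, and LD-decay estimation.

r-squared is the squared Pearson correlation of alt-allele dosages
(0/1/2) over pairwise-complete samples; missing dosages are never
imputed. All heavy paths share :func:`_r2_matrix`, a masked-matrix
formulation that computes pairwise-complete correlations with a handful
of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from islescan.genotypes import GenotypeMatrix


def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 between rows of a (sites x samples) dosage
    block with NaN missing values. Entries with < 2 shared samples or a
    zero-variance member are NaN."""
    m = (~np.isnan(dos)).astype(np.float64)
    x = np.nan_to_num(dos)
    n = m @ m.T
    sx = x @ m.T                 # sum of x over jointly-called samples
    sxy = x @ x.T
    sxx = (x * x) @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        r2 = cov * cov / (varx * varx.T)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def pairwise_r2(gm: GenotypeMatrix, site_i: int, site_j: int) -> float:
    """r^2 between two sites; NaN if either has zero variance over the
    jointly-called samples."""
    dos = gm.dosage()[:, [site_i, site_j]].T
    joint = ~np.isnan(dos).any(axis=0)
    if joint.sum() < 2:
        raise ValueError("fewer than 2 samples called at both sites")
    return float(_r2_matrix(dos)[0, 1])


def ld_prune(
    gm: GenotypeMatrix,
    window_snv: int = 50,
    step_snv: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy within-window LD pruning; returns retained site indices.

    In each ``window_snv``-site window (advanced by ``step_snv``), every
    retained pair exceeding ``r2_max`` loses its later member (position
    order). The strong-prune variant is obtained with ``r2_max=0.90``.
    """
    dos = gm.dosage()
    keep = np.ones(gm.n_sites, dtype=bool)
    for c in gm.chromosomes():
        idx = np.flatnonzero(gm.chrom == c)
        nloc = len(idx)
        start = 0
        while True:
            win = idx[start : start + window_snv]
            live = win[keep[win]]
            if len(live) > 1:
                r2 = _r2_matrix(dos[:, live].T)
                alive = np.ones(len(live), dtype=bool)
                for a in range(len(live)):
                    if not alive[a]:
                        continue
                    for b in range(a + 1, len(live)):
                        if alive[b] and r2[a, b] > r2_max:
                            alive[b] = False
                keep[live[~alive]] = False
            if start + window_snv >= nloc:
                break
            start += step_snv
    return np.flatnonzero(keep)


@dataclass
class LDDecayCurve:
    """Mean r^2 by physical-distance bin, with the 0.2-crossing distance."""

    bin_start: np.ndarray
    bin_end: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    crossing_bp: float | None  # midpoint of the first stably sub-0.2 bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_end": self.bin_end,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_bp: int = 5_000,
    r2_threshold: float = 0.2,
) -> LDDecayCurve:
    """Mean r^2 per distance bin over all intra-chromosomal pairs within
    ``max_dist``; the crossing distance is the midpoint of the first bin
    whose mean falls below ``r2_threshold`` with every later non-empty
    bin also below it."""
    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    dos = gm.dosage()
    any_pair = False
    for c in gm.chromosomes():
        idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[idx]
        block = dos[:, idx].T
        for a in range(len(idx) - 1):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            any_pair = True
            r2 = _r2_matrix(np.vstack([block[a : a + 1], block[a + 1 : hi]]))[0, 1:]
            dist = pos[a + 1 : hi] - pos[a]
            bins = np.minimum((dist - 1) // bin_bp, n_bins - 1)
            ok = np.isfinite(r2)
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)
    if not any_pair:
        raise ValueError("no intra-chromosomal pairs within max_dist")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    crossing = None
    below = np.where(np.isnan(mean_r2), True, mean_r2 < r2_threshold)
    for b in range(n_bins):
        if counts[b] > 0 and below[b:].all():
            crossing = float(b * bin_bp + bin_bp / 2)
            break
    return LDDecayCurve(
        bin_start=np.arange(n_bins, dtype=np.int64) * bin_bp + 1,
        bin_end=(np.arange(n_bins, dtype=np.int64) + 1) * bin_bp,
        mean_r2=mean_r2,
        n_pairs=counts,
        crossing_bp=crossing,
    )


def verify_pruned(
    gm: GenotypeMatrix,
    retained: np.ndarray,
    window_snv: int = 50,
    step_snv: int = 5,
    r2_max: float = 0.2,
) -> bool:
    """Post-hoc check: no retained pair inside any sliding window exceeds
    ``r2_max``. Windows are taken over the original site order."""
    retained = set(np.asarray(retained).tolist())
    dos = gm.dosage()
    for c in gm.chromosomes():
        idx = np.flatnonzero(gm.chrom == c)
        for start in range(0, max(1, len(idx)), step_snv):
            win = [i for i in idx[start : start + window_snv] if i in retained]
            if len(win) > 1:
                r2 = _r2_matrix(dos[:, win].T)
                iu = np.triu_indices(len(win), k=1)
                if np.any(r2[iu] > r2_max):
                    return False
            if start + window_snv >= len(idx):
                break
    return True
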