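"""Sliding-window nucleotide diversity, Weir-Cockerham Fst, Tajima's D,
and genome-wide z-score transformation.

Window convention: 1-based inclusive intervals starting at 1, 1+step,
2*step+1, ...; a site belongs to window ``[start, start + size - 1]``.
A chromosome-end window is truncated to the chromosome length for
per-bp normalization. Chromosome lengths default to the last observed
site position unless supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from islescan.genotypes import MISSING, CohortDesign, GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    size: int
    step: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("window size must be > 0")
        if not 0 < self.step <= self.size:
            raise ValueError("need 0 < step <= size")


def _chrom_lengths(gm: GenotypeMatrix, given: dict[str, int] | None) -> dict[str, int]:
    out = {}
    for c in gm.chromosomes():
        out[c] = int(gm.pos[gm.chrom == c].max())
    if given:
        out.update(given)
    return out


def window_frame(
    gm: GenotypeMatrix, spec: WindowSpec, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Window tiling with per-window half-open site index ranges [lo, hi)."""
    lengths = _chrom_lengths(gm, chrom_lengths)
    parts = []
    for c in gm.chromosomes():
        clen = lengths[c]
        idx = np.flatnonzero(gm.chrom == c)
        if len(idx) > 1 and np.any(np.diff(idx) != 1):
            raise ValueError(f"sites of chromosome {c} are not contiguous")
        pos = gm.pos[idx]
        starts = np.arange(1, clen + 1, spec.step, dtype=np.int64)
        ends = starts + spec.size - 1
        covered = np.minimum(ends, clen) - starts + 1
        lo = idx[0] + np.searchsorted(pos, starts, side="left")
        hi = idx[0] + np.searchsorted(pos, ends, side="right")
        parts.append(
            pd.DataFrame(
                {"chrom": c, "start": starts, "end": ends,
                 "covered_bp": covered, "lo": lo, "hi": hi}
            )
        )
    return pd.concat(parts, ignore_index=True)


def _window_sum(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sum of a per-site array over each [lo, hi) index range via cumsum."""
    cum = np.concatenate([[0.0], np.cumsum(values)])
    return cum[hi] - cum[lo]


# -- nucleotide diversity ----------------------------------------------------


def site_pi(alt_count, called_alleles):
    """Per-site diversity 2c(n-c)/(n(n-1)); NaN when n < 2."""
    c = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(called_alleles, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def window_pi(
    gm: GenotypeMatrix,
    cohort: list[str],
    spec: WindowSpec,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sum of site diversity per window, divided by covered window bp."""
    if not cohort:
        raise ValueError("cohort is empty")
    idx = gm.sample_index(cohort)
    alt, tot = gm.allele_counts(idx)
    per_site = np.nan_to_num(site_pi(alt, tot))  # skipped sites add 0
    wf = window_frame(gm, spec, chrom_lengths)
    wf = wf[wf["covered_bp"] > 0].reset_index(drop=True)
    pi = _window_sum(per_site, wf["lo"].to_numpy(), wf["hi"].to_numpy())
    wf["pi"] = pi / wf["covered_bp"].to_numpy()
    wf["n_sites"] = (wf["hi"] - wf["lo"]).astype(int)
    return wf[["chrom", "start", "end", "n_sites", "pi"]]


# -- Weir & Cockerham Fst ----------------------------------------------------


def weir_components(
    gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site variance components (a, b, c) for two populations (r=2).

    ``a`` is the among-population component, ``b`` among individuals
    within populations, ``c`` within individuals. Sites where either
    cohort has no called genotype, or with fewer than 3 called
    individuals in total, are NaN in all three outputs.
    """
    comps = []
    for idx in (idx_a, idx_b):
        calls = gm.calls[idx]
        called = calls != MISSING
        n = called.sum(axis=0).astype(np.float64)          # individuals
        alt = np.where(called, calls, 0).sum(axis=0).astype(np.float64)
        nhet = (calls == 1).sum(axis=0).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = nhet / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1 * n1 + n2 * n2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        inner = pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    bad = ~valid
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_theta(gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Per-site theta = a / (a + b + c); NaN when a + b + c == 0 or the
    site is undefined."""
    a, b, c = weir_components(gm, idx_a, idx_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    theta[~np.isfinite(theta)] = np.nan
    return theta


def weir_fst(
    gm: GenotypeMatrix,
    cohort_a: list[str],
    cohort_b: list[str],
    spec: WindowSpec,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-site theta plus windowed weighted theta = sum(a)/sum(a+b+c)."""
    idx_a = gm.sample_index(cohort_a)
    idx_b = gm.sample_index(cohort_b)
    a, b, c = weir_components(gm, idx_a, idx_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    theta[~np.isfinite(theta)] = np.nan

    a0 = np.nan_to_num(a)      # undefined sites contribute zeros to sums
    d0 = np.nan_to_num(denom)
    wf = window_frame(gm, spec, chrom_lengths)
    lo, hi = wf["lo"].to_numpy(), wf["hi"].to_numpy()
    sa = _window_sum(a0, lo, hi)
    sd = _window_sum(d0, lo, hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        wtheta = np.where(sd != 0, sa / np.where(sd != 0, sd, 1.0), np.nan)
    wf["fst"] = wtheta
    wf["n_sites"] = (wf["hi"] - wf["lo"]).astype(int)
    return theta, wf[["chrom", "start", "end", "n_sites", "fst"]]


# -- Tajima's D --------------------------------------------------------------


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d(
    gm: GenotypeMatrix,
    cohort: list[str],
    spec: WindowSpec,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window Tajima's D for one cohort.

    The allele-count dimension n is fixed at twice the cohort size;
    sites with missing cohort calls contribute through the called-allele
    frequency (pi_site = 2 p(1-p) n/(n-1)), an approximation that is
    exact when call rates are complete. Windows with no segregating
    site, or a non-positive variance term, are NaN.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n = 2 * len(cohort)
    if n < 4:
        raise ValueError("need at least 2 individuals for Tajima's D")
    idx = gm.sample_index(cohort)
    alt, tot = gm.allele_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    seg = np.isfinite(p) & (p > 0) & (p < 1) & (tot >= 2)
    pi_site = np.where(seg, 2.0 * p * (1.0 - p) * n / (n - 1.0), 0.0)

    k = _tajima_constants(n)
    wf = window_frame(gm, spec, chrom_lengths)
    lo, hi = wf["lo"].to_numpy(), wf["hi"].to_numpy()
    s = _window_sum(seg.astype(np.float64), lo, hi)
    pihat = _window_sum(pi_site, lo, hi)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where((s > 0) & (var > 0), (pihat - s / k["a1"]) / np.sqrt(var), np.nan)
    wf["n_seg"] = s.astype(int)
    wf["tajd"] = d
    wf["n_sites"] = (wf["hi"] - wf["lo"]).astype(int)
    return wf[["chrom", "start", "end", "n_sites", "n_seg", "tajd"]]


# -- z-scores and the assembled scan table -----------------------------------


def z_transform(values) -> np.ndarray:
    """Standardize to zero mean, unit sample SD over finite entries;
    non-finite entries propagate as NaN."""
    x = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def scan_table(
    gm: GenotypeMatrix,
    design: CohortDesign,
    spec: WindowSpec,
    case: str = "case",
    control: str | list[str] = "control_a",
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Fst, per-cohort pi and Tajima's D, their control-minus-case
    deltas, and genome-wide z-scores, for one comparison pair.

    ``control`` may be a single label or a list (pooled controls).
    Deltas are oriented control minus case so that reduced case
    diversity lands in the upper tail.
    """
    case_ids = design.members(case)
    if isinstance(control, str):
        control_ids = design.members(control)
    else:
        control_ids = design.members_of(control)
        if not control_ids:
            raise ValueError("pooled control cohort is empty")

    _, fst = weir_fst(gm, case_ids, control_ids, spec, chrom_lengths)
    pi_case = window_pi(gm, case_ids, spec, chrom_lengths)
    pi_ctl = window_pi(gm, control_ids, spec, chrom_lengths)
    d_case = tajimas_d(gm, case_ids, spec, chrom_lengths)
    d_ctl = tajimas_d(gm, control_ids, spec, chrom_lengths)

    tab = fst.copy()
    tab["pi_case"] = pi_case["pi"].to_numpy()
    tab["pi_control"] = pi_ctl["pi"].to_numpy()
    tab["delta_pi"] = tab["pi_control"] - tab["pi_case"]
    tab["tajd_case"] = d_case["tajd"].to_numpy()
    tab["tajd_control"] = d_ctl["tajd"].to_numpy()
    tab["delta_tajd"] = tab["tajd_control"] - tab["tajd_case"]
    for col in ("fst", "delta_pi", "delta_tajd"):
        tab[f"z_{col}"] = z_transform(tab[col].to_numpy())
    return tab
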