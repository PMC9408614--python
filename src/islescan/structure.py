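"""PCA on variance-standardized dosages over neutral, LD-pruned sites."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from islescan.bedio import bed_to_inclusive
from islescan.genotypes import GenotypeMatrix


@dataclass
class PCAResult:
    samples: list[str]
    scores: np.ndarray           # (n_samples, k)
    variance_fraction: np.ndarray
    sites_used: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "sample", self.samples)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def pca(
    gm: GenotypeMatrix,
    neutral: pd.DataFrame | None = None,
    pruned_sites: np.ndarray | None = None,
    k: int = 10,
) -> PCAResult:
    """Top-k principal components of the standardized dosage matrix.

    Sites are restricted to the intersection of the neutral track (BED)
    and the pruned site-index set when given; monomorphic sites are
    dropped. Dosages are centered by twice the alt frequency and scaled
    by ``sqrt(2 p (1 - p))``; missing dosages are mean-imputed (zero
    after centering). Each component's sign is fixed so its
    largest-magnitude site loading is positive.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    keep = np.ones(gm.n_sites, dtype=bool)
    if pruned_sites is not None:
        mask = np.zeros(gm.n_sites, dtype=bool)
        mask[np.asarray(pruned_sites)] = True
        keep &= mask
    if neutral is not None and len(neutral):
        n1 = bed_to_inclusive(neutral)
        in_neutral = np.zeros(gm.n_sites, dtype=bool)
        for row in n1.itertuples(index=False):
            in_neutral |= (
                (gm.chrom == row.chrom) & (gm.pos >= row.start) & (gm.pos <= row.end)
            )
        keep &= in_neutral

    sub = gm.take_sites(keep)
    alt, tot = sub.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    sub = sub.take_sites(poly)
    p = p[poly]
    if sub.n_sites < k:
        raise ValueError(f"only {sub.n_sites} informative sites; need >= k={k}")

    dos = sub.dosage()
    x = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[~np.isfinite(x)] = 0.0  # mean imputation of missing dosages

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k_eff = min(k, len(s))
    # deterministic sign: largest-|loading| entry of each component positive
    for comp in range(k_eff):
        j = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    scores = u[:, :k_eff] * s[:k_eff]
    var = s**2
    return PCAResult(
        samples=list(sub.samples),
        scores=scores,
        variance_fraction=var[:k_eff] / var.sum(),
        sites_used=sub.n_sites,
    )
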