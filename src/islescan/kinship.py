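"""Pairwise KING-robust kinship and exact maximum-unrelated-set selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from islescan.genotypes import MISSING, GenotypeMatrix

#: 2nd-degree relatedness cutoff (KING convention).
DEFAULT_THRESHOLD = 0.0884


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship estimates with the underlying counts."""

    samples: list[str]
    phi: np.ndarray          # (n, n), NaN where undefined
    n_het_het: np.ndarray
    n_opp_hom: np.ndarray
    n_het: np.ndarray        # (n, n): het count of sample i over sites shared with j

    def to_tsv(self, path) -> None:
        rows = []
        n = len(self.samples)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (self.samples[i], self.samples[j],
                     int(self.n_het_het[i, j]), int(self.n_opp_hom[i, j]),
                     self.phi[i, j])
                )
        pd.DataFrame(
            rows, columns=["sample_i", "sample_j", "n_het_het", "n_opp_hom", "kinship"]
        ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def king_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust kinship over sites called in both members of each pair.

    phi_ij = 1/2 - (N_het_i + N_het_j - 2 N_het_het + 4 N_opp_hom)
                   / (4 min(N_het_i, N_het_j))

    where all counts are restricted to jointly-called sites. A pair
    where either member has no heterozygous call among shared sites is
    undefined (NaN, warning emitted). The diagonal is computed
    self-vs-self and equals 0.5.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = gm.calls
    called = (calls != MISSING).astype(np.float64)
    het = (calls == 1).astype(np.float64)
    hom_ref = (calls == 0).astype(np.float64)
    hom_alt = (calls == 2).astype(np.float64)

    # pairwise counts via matrix products over sites
    n_het_het = het @ het.T
    n_opp_hom = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    n_het_i = het @ called.T       # hets of i at sites where j is called

    min_het = np.minimum(n_het_i, n_het_i.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = 0.5 - (n_het_i + n_het_i.T - 2.0 * n_het_het + 4.0 * n_opp_hom) / (
            4.0 * min_het
        )
    phi[min_het == 0] = np.nan

    n_undef = int(np.isnan(phi[np.triu_indices_from(phi, k=1)]).sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} sample pair(s) have an undefined kinship estimate "
            "(a member with zero heterozygous calls); they are excluded "
            "from unrelated-set constraints",
            stacklevel=2,
        )
    return KinshipMatrix(
        samples=list(gm.samples),
        phi=phi,
        n_het_het=n_het_het.astype(np.int64),
        n_opp_hom=n_opp_hom.astype(np.int64),
        n_het=n_het_i.astype(np.int64),
    )


def max_unrelated(km: KinshipMatrix, threshold: float = DEFAULT_THRESHOLD) -> list[str]:
    """Maximum-cardinality subset with all pairwise kinship <= threshold.

    Exact branch-and-bound over the complement of the "related" graph
    (an edge joins pairs with phi > threshold; undefined pairs impose no
    constraint). Ties in cardinality break toward the lexicographically
    smallest set of sample ids, so the result is independent of input
    order.
    """
    order = sorted(range(len(km.samples)), key=lambda i: km.samples[i])
    ids = [km.samples[i] for i in order]
    n = len(ids)
    phi = km.phi[np.ix_(order, order)]
    related = np.zeros((n, n), dtype=bool)
    with np.errstate(invalid="ignore"):
        mask = np.nan_to_num(phi, nan=-np.inf) > threshold
    related |= mask
    np.fill_diagonal(related, False)

    best: list[tuple[int, ...]] = [()]

    def consider(chosen: tuple[int, ...]) -> None:
        cur = best[0]
        if len(chosen) > len(cur) or (
            len(chosen) == len(cur)
            and tuple(ids[i] for i in chosen) < tuple(ids[i] for i in cur)
        ):
            best[0] = chosen

    def extend(chosen: tuple[int, ...], start: int) -> None:
        # bound: even taking every remaining vertex cannot beat best
        if len(chosen) + (n - start) < len(best[0]):
            return
        consider(chosen)
        for v in range(start, n):
            if any(related[v, u] for u in chosen):
                continue
            extend(chosen + (v,), v + 1)

    extend((), 0)
    return [ids[i] for i in best[0]]
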