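"""Shared containers: diploid genotype matrix and cohort design.

Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with
``MISSING`` (-1) for uncalled genotypes. Sites carry 1-based positions
and are strictly increasing within each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for an uncalled genotype.
MISSING = -1

COHORT_LABELS = ("case", "control_a", "control_b")


@dataclass
class GenotypeMatrix:
    """Samples x sites matrix of diploid genotype calls with metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    chrom, pos, ref, alt
        Per-site metadata arrays. ``pos`` is 1-based and strictly
        increasing within each chromosome; ``ref != alt`` everywhere.
    calls
        ``(n_samples, n_sites)`` int8 array of dosages in
        ``{0, 1, 2, MISSING}``.
    depth, gq
        Per-call read depth and genotype quality, same shape as
        ``calls``; zero when absent from the source VCF.
    ancestral_is_ref
        Per-site flag set by :func:`islescan.variants.polarize`.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    ancestral_is_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        self.validate()

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def validate(self) -> None:
        n, m = self.n_samples, self.n_sites
        for name in ("chrom", "ref", "alt"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} has wrong length")
        for name in ("calls", "depth", "gq"):
            if getattr(self, name).shape != (n, m):
                raise ValueError(f"{name} must have shape ({n}, {m})")
        if np.any(self.ref == self.alt):
            raise ValueError("ref must differ from alt at every site")
        bad = (self.calls < MISSING) | (self.calls > 2)
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc}") from exc

    # -- subsetting ----------------------------------------------------------

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        anc = None if self.ancestral_is_ref is None else self.ancestral_is_ref[idx]
        return GenotypeMatrix(
            samples=self.samples,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
            depth=self.depth[:, idx],
            gq=self.gq[:, idx],
            ancestral_is_ref=anc,
        )

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            calls=self.calls[idx],
            depth=self.depth[idx],
            gq=self.gq[idx],
            ancestral_is_ref=self.ancestral_is_ref,
        )

    # -- summaries -----------------------------------------------------------

    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Per-site ``(alt_count, called_alleles)`` over a sample subset."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        called = calls != MISSING
        alt = np.where(called, calls, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def dosage(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Float dosage matrix with NaN at missing calls."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx]
        d = calls.astype(np.float64)
        d[calls == MISSING] = np.nan
        return d

    def copy(self) -> "GenotypeMatrix":
        anc = None if self.ancestral_is_ref is None else self.ancestral_is_ref.copy()
        return replace(
            self,
            samples=list(self.samples),
            calls=self.calls.copy(),
            depth=self.depth.copy(),
            gq=self.gq.copy(),
            ancestral_is_ref=anc,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.gq, other.gq)
        )


@dataclass
class CohortDesign:
    """Mapping of sample id to cohort label."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = dict(self.assignments)

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        out = [s for s, lab in self.assignments.items() if lab == label]
        if not out:
            raise ValueError(f"cohort {label!r} has no members")
        return out

    def members_of(self, labels: Iterable[str]) -> list[str]:
        """Union of several cohorts, preserving sample order."""
        wanted = set(labels)
        return [s for s, lab in self.assignments.items() if lab in wanted]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "CohortDesign":
        return cls(dict(mapping))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": self.samples, "cohort": [self.assignments[s] for s in self.samples]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["sample"], df["cohort"])))
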