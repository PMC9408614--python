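"""Synthetic two-island case/control cohort generator with known truth.

Two island populations diverge from shared ancestral allele frequencies
under a Balding-Nichols beta model with a single drift parameter F.
Cases and same-island controls share island-A frequencies except at
planted causal loci, where the case frequency is shifted by a target
amount; second-island controls follow island-B frequencies. Autozygous
tracts can be planted per cohort, and per-call depth/quality plus
missingness emulate ~10x short-read genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from islescan.genotypes import MISSING, CohortDesign, GenotypeMatrix

_CAUSAL_RETRIES = 100


@dataclass(frozen=True)
class PlantedROH:
    """A homozygous tract to overwrite in a fraction of one cohort."""

    cohort: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    carrier_frac: float


@dataclass
class SimConfig:
    n_case: int = 12
    n_control_a: int = 11
    n_control_b: int = 9
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_sites: int = 5_000
    island_divergence: float = 0.05  # Balding-Nichols F
    n_causal: int = 0
    causal_delta: float = 0.6
    causal_span_bp: int = 50_000       # sweep footprint width around the focal site
    causal_sweep_strength: float = 0.8  # case-frequency pull toward the swept allele
    roh_planted: list[PlantedROH] = field(default_factory=list)
    missing_rate: float = 0.02
    mean_depth: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control_a", "n_control_b", "n_chrom",
                     "chrom_length", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.island_divergence < 0:
            raise ValueError("island_divergence must be >= 0")
        if not 0 <= self.causal_delta <= 1:
            raise ValueError("causal_delta must be in [0, 1]")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.causal_span_bp < 0:
            raise ValueError("causal_span_bp must be >= 0")
        if not 0 <= self.causal_sweep_strength < 1:
            raise ValueError("causal_sweep_strength must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for r in self.roh_planted:
            if not (1 <= r.start <= r.end <= self.chrom_length):
                raise ValueError(f"planted ROH {r} outside chromosome bounds")
            if not 0 < r.carrier_frac <= 1:
                raise ValueError("carrier_frac must be in (0, 1]")


@dataclass
class TruthTable:
    """Generating truth for planted features.

    ``loci`` has one row per causal locus (chrom, pos, p_case,
    p_control_a, p_control_b); ``roh`` one row per planted tract
    (cohort, chrom, start, end, carriers as comma-joined ids).
    """

    loci: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "p_case", "p_control_a", "p_control_b"]))
    roh: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cohort", "chrom", "start", "end", "carriers"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthTable):
            return NotImplemented
        return self.loci.reset_index(drop=True).equals(
            other.loci.reset_index(drop=True)
        ) and self.roh.reset_index(drop=True).equals(other.roh.reset_index(drop=True))


@dataclass
class SimResult:
    gm: GenotypeMatrix
    design: CohortDesign
    truth: TruthTable
    genes: pd.DataFrame    # BED, 0-based half-open
    tfbs: pd.DataFrame
    neutral: pd.DataFrame


def simulate_study(config: SimConfig) -> SimResult:
    """Generate genotypes, cohort design, truth table and BED tracks."""
    rng = np.random.default_rng(config.seed)

    samples, design = _make_design(config)
    chrom, pos = _draw_sites(config, rng)
    m = len(pos)

    anc = rng.uniform(0.05, 0.95, size=m)
    p_a = _balding_nichols(anc, config.island_divergence, rng)
    p_b = _balding_nichols(anc, config.island_divergence, rng)

    p_case = p_a.copy()
    causal_idx = np.array([], dtype=np.intp)
    if config.n_causal > 0:
        causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
        for j in causal_idx:
            # partial-sweep footprint: case frequencies near the focal site
            # are pulled toward a swept allele, lowering case diversity
            near = (
                (chrom == chrom[j])
                & (np.abs(pos - pos[j]) <= config.causal_span_bp // 2)
            )
            near[j] = False
            swept = rng.binomial(1, p_a[near]).astype(np.float64)
            w = config.causal_sweep_strength
            p_case[near] = p_a[near] + w * (swept - p_a[near])
            p_case[j], p_a[j], p_b[j] = _shift_causal(
                p_a[j], p_b[j], config, rng
            )

    cohort_p = {"case": p_case, "control_a": p_a, "control_b": p_b}
    calls = np.empty((len(samples), m), dtype=np.int8)
    for label in ("case", "control_a", "control_b"):
        idx = [i for i, s in enumerate(samples) if design.assignments[s] == label]
        p = cohort_p[label]
        calls[idx] = rng.binomial(2, p, size=(len(idx), m)).astype(np.int8)

    roh_rows = _plant_roh(config, rng, samples, design, chrom, pos, cohort_p, calls)

    depth = rng.poisson(config.mean_depth, size=calls.shape).astype(np.int32)
    gq = np.minimum(99, np.round(10.0 * depth / 3.0)).astype(np.int32)
    miss = rng.random(calls.shape) < config.missing_rate
    calls[miss] = MISSING

    ref, alt = _draw_alleles(m, rng)
    gm = GenotypeMatrix(
        samples=samples, chrom=chrom, pos=pos, ref=ref, alt=alt,
        calls=calls, depth=depth, gq=gq,
    )

    truth = TruthTable(
        loci=pd.DataFrame(
            {
                "chrom": chrom[causal_idx],
                "pos": pos[causal_idx],
                "p_case": np.round(p_case[causal_idx], 6),
                "p_control_a": np.round(p_a[causal_idx], 6),
                "p_control_b": np.round(p_b[causal_idx], 6),
            }
        )
        if len(causal_idx)
        else TruthTable().loci,
        roh=pd.DataFrame(roh_rows, columns=["cohort", "chrom", "start", "end", "carriers"])
        if roh_rows
        else TruthTable().roh,
    )

    genes, tfbs, neutral = _make_tracks(config, rng)
    return SimResult(gm=gm, design=design, truth=truth, genes=genes,
                     tfbs=tfbs, neutral=neutral)


# -- internals ---------------------------------------------------------------


def _make_design(config: SimConfig) -> tuple[list[str], CohortDesign]:
    mapping: dict[str, str] = {}
    for i in range(config.n_case):
        mapping[f"case{i + 1:02d}"] = "case"
    for i in range(config.n_control_a):
        mapping[f"ctlA{i + 1:02d}"] = "control_a"
    for i in range(config.n_control_b):
        mapping[f"ctlB{i + 1:02d}"] = "control_b"
    return list(mapping), CohortDesign(mapping)


def _draw_sites(config: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    per = np.full(config.n_chrom, config.n_sites // config.n_chrom)
    per[: config.n_sites % config.n_chrom] += 1
    chrom_parts, pos_parts = [], []
    for k, n in enumerate(per, start=1):
        p = np.sort(rng.choice(config.chrom_length, size=n, replace=False)) + 1
        chrom_parts.append(np.full(n, f"chr{k}", dtype=object))
        pos_parts.append(p.astype(np.int64))
    return np.concatenate(chrom_parts), np.concatenate(pos_parts)


def _balding_nichols(anc: np.ndarray, f: float, rng) -> np.ndarray:
    if f == 0:
        return anc.copy()
    scale = (1.0 - f) / f
    return rng.beta(anc * scale, (1.0 - anc) * scale)


def _shift_causal(p_a: float, p_b: float, config: SimConfig, rng):
    """Re-draw the locus frequency until a +-delta shift stays in [0.01, 0.99]."""
    delta = config.causal_delta
    for _ in range(_CAUSAL_RETRIES):
        if p_a + delta <= 0.99:
            return p_a + delta, p_a, p_b
        if p_a - delta >= 0.01:
            return p_a - delta, p_a, p_b
        u = rng.uniform(0.05, 0.95)
        p_a = float(_balding_nichols(np.array([u]), config.island_divergence, rng)[0])
        p_b = float(_balding_nichols(np.array([u]), config.island_divergence, rng)[0])
    raise RuntimeError(f"causal_delta {delta} infeasible after {_CAUSAL_RETRIES} redraws")


def _plant_roh(config, rng, samples, design, chrom, pos, cohort_p, calls):
    """Overwrite carrier genotypes with a shared homozygous haplotype."""
    rows = []
    for tract in config.roh_planted:
        members = design.members(tract.cohort)
        n_carriers = max(1, int(round(tract.carrier_frac * len(members))))
        carriers = sorted(rng.choice(members, size=n_carriers, replace=False))
        in_tract = (chrom == tract.chrom) & (pos >= tract.start) & (pos <= tract.end)
        site_idx = np.flatnonzero(in_tract)
        hom = 2 * rng.binomial(1, cohort_p[tract.cohort][site_idx]).astype(np.int8)
        lookup = {s: i for i, s in enumerate(samples)}
        for s in carriers:
            calls[lookup[s], site_idx] = hom
        rows.append((tract.cohort, tract.chrom, tract.start, tract.end,
                     ",".join(carriers)))
    return rows


def _draw_alleles(m: int, rng) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    return bases[ref_i], bases[alt_i]


def _make_tracks(config: SimConfig, rng):
    """Gene / TFBS / neutral BED tracks (0-based half-open), deterministic."""
    genes, tfbs, neutral = [], [], []
    gid = 0
    for k in range(1, config.n_chrom + 1):
        c = f"chr{k}"
        n_genes = max(3, config.chrom_length // 250_000)
        starts = np.sort(rng.choice(config.chrom_length - 60_000, n_genes, replace=False))
        prev_end = -1
        for s in starts:
            length = int(rng.integers(5_000, 50_000))
            if s <= prev_end:
                continue
            e = min(s + length, config.chrom_length)
            gid += 1
            genes.append((c, int(s), int(e), f"gene{gid:04d}"))
            # a short TFBS upstream of roughly half the genes
            if rng.random() < 0.5:
                t0 = max(0, int(s) - int(rng.integers(200, 2_000)))
                tfbs.append((c, t0, min(t0 + int(rng.integers(100, 500)),
                                        config.chrom_length), f"tfbs{gid:04d}"))
            if prev_end >= 0 and s - prev_end > 20_000:
                mid = (prev_end + s) // 2
                neutral.append((c, int(mid - 5_000), int(mid + 5_000), f"neut{gid:04d}"))
            prev_end = e
    cols = ["chrom", "start", "end", "name"]
    return (
        pd.DataFrame(genes, columns=cols),
        pd.DataFrame(tfbs, columns=cols),
        pd.DataFrame(neutral, columns=cols),
    )


# -- truth-table persistence -------------------------------------------------


def write_truth(truth: TruthTable, path) -> None:
    """Serialize the truth table to a single TSV (typed rows)."""
    rows = []
    for _, r in truth.loci.iterrows():
        rows.append(("locus", "", r["chrom"], int(r["pos"]), "", r["p_case"],
                     r["p_control_a"], r["p_control_b"], ""))
    for _, r in truth.roh.iterrows():
        rows.append(("roh", r["cohort"], r["chrom"], int(r["start"]),
                     int(r["end"]), "", "", "", r["carriers"]))
    pd.DataFrame(
        rows,
        columns=["record", "cohort", "chrom", "a", "b", "p_case",
                 "p_control_a", "p_control_b", "carriers"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    loci = df[df["record"] == "locus"]
    roh = df[df["record"] == "roh"]
    return TruthTable(
        loci=pd.DataFrame(
            {
                "chrom": loci["chrom"].to_numpy(dtype=object),
                "pos": loci["a"].astype(np.int64).to_numpy(),
                "p_case": loci["p_case"].astype(float).to_numpy(),
                "p_control_a": loci["p_control_a"].astype(float).to_numpy(),
                "p_control_b": loci["p_control_b"].astype(float).to_numpy(),
            }
        )
        if len(loci)
        else TruthTable().loci,
        roh=pd.DataFrame(
            {
                "cohort": roh["cohort"].to_numpy(dtype=object),
                "chrom": roh["chrom"].to_numpy(dtype=object),
                "start": roh["a"].astype(np.int64).to_numpy(),
                "end": roh["b"].astype(np.int64).to_numpy(),
                "carriers": roh["carriers"].to_numpy(dtype=object),
            }
        )
        if len(roh)
        else TruthTable().roh,
    )
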