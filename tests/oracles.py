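"""Independent brute-force reference implementations used only by tests.

Every function here is written straight from first principles (explicit
loops, allele enumeration, scalar arithmetic) and shares no code with
the package's vectorized paths.
"""

from itertools import combinations
from math import sqrt

from islescan.genotypes import MISSING


def brute_site_pi(alleles):
    """Mean pairwise difference over an explicit allele list."""
    pairs = list(combinations(range(len(alleles)), 2))
    if not pairs:
        return float("nan")
    diff = sum(1 for i, j in pairs if alleles[i] != alleles[j])
    return diff / len(pairs)


def alleles_at(gm, site, sample_idx):
    """Explicit allele list for one site over a sample subset."""
    out = []
    for i in sample_idx:
        g = int(gm.calls[i, site])
        if g == MISSING:
            continue
        out.extend([1] * g + [0] * (2 - g))
    return out


def brute_window_pi(gm, sample_idx, sites, window_bp):
    """Sum of per-site mean pairwise differences over sites, per bp."""
    total = 0.0
    for s in sites:
        alleles = alleles_at(gm, s, sample_idx)
        if len(alleles) >= 2:
            total += brute_site_pi(alleles)
    return total / window_bp


def brute_weir_site(gm, site, idx_a, idx_b):
    """Weir & Cockerham (1984) components for one site, scalar arithmetic.

    Returns (a, b, c) or None when undefined.
    """
    stats = []
    for idx in (idx_a, idx_b):
        gts = [int(gm.calls[i, site]) for i in idx if gm.calls[i, site] != MISSING]
        n = len(gts)
        if n == 0:
            return None
        p = sum(gts) / (2 * n)
        h = sum(1 for g in gts if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    if n1 + n2 <= 2:
        return None
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def brute_weighted_theta(gm, sites, idx_a, idx_b):
    num = den = 0.0
    for s in sites:
        comp = brute_weir_site(gm, s, idx_a, idx_b)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def brute_tajimas_d(gm, sites, sample_idx):
    """Tajima's D straight from the published formula, fixed n."""
    n = 2 * len(sample_idx)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    s_count = 0
    pihat = 0.0
    for s in sites:
        alleles = alleles_at(gm, s, sample_idx)
        if len(alleles) < 2:
            continue
        p = sum(alleles) / len(alleles)
        if 0 < p < 1:
            s_count += 1
            pihat += 2 * p * (1 - p) * n / (n - 1)
    if s_count == 0:
        return float("nan")
    var = e1 * s_count + e2 * s_count * (s_count - 1)
    if var <= 0:
        return float("nan")
    return (pihat - s_count / a1) / sqrt(var)


def brute_roh_in_run(calls, positions, params):
    """Exhaustive per-SNV in-run classification for the ROH caller."""
    w = params.window_snv
    n = len(calls)
    windows = []
    for start in range(0, n - w + 1):
        block = calls[start : start + w]
        het = sum(1 for g in block if g == 1)
        mis = sum(1 for g in block if g == MISSING)
        windows.append(het <= params.max_het_per_window
                       and mis <= params.max_miss_per_window)
    flags = []
    for j in range(n):
        covering = [windows[i] for i in range(max(0, j - w + 1), min(j, n - w) + 1)]
        flags.append(sum(covering) / len(covering) >= params.min_prop_hom_windows)
    return flags


def brute_max_independent_sets(samples, related_pairs):
    """All maximum independent sets by exhaustive subset enumeration."""
    from itertools import combinations as comb

    related = set(frozenset(p) for p in related_pairs)
    best_size = -1
    best = []
    for k in range(len(samples), -1, -1):
        for subset in comb(samples, k):
            if any(frozenset((a, b)) in related for a, b in comb(subset, 2)):
                continue
            if k > best_size:
                best_size = k
                best = [set(subset)]
            elif k == best_size:
                best.append(set(subset))
        if best_size >= 0:
            break
    return best
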