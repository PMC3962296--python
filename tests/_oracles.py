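"""Independent brute-force oracles used by the test suite.

Each function here re-derives a quantity from first principles with plain
Python loops and exact arithmetic where feasible, deliberately sharing no
code with the package implementations it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def wc_theta_brute(counts_per_pop):
    """Weir-Cockerham a, b, c for one biallelic locus, written longhand.

    ``counts_per_pop`` is a list of (n_AA, n_Aa, n_aa) genotype counts, one
    tuple per population. Populations with zero individuals are dropped.
    Returns (a, b, c) or None when fewer than two populations have data.
    """
    pops = [c for c in counts_per_pop if sum(c) > 0]
    r = len(pops)
    if r < 2:
        return None
    n = [sum(c) for c in pops]
    p = [(2 * c[0] + c[1]) / (2 * ni) for c, ni in zip(pops, n)]
    h = [c[1] / ni for c, ni in zip(pops, n)]
    nbar = sum(n) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def hwe_exact_fraction(n_AA, n_Aa, n_aa):
    """Exact two-sided Hardy-Weinberg p-value with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A

    def prob(het):
        aa = (n_A - het) // 2
        bb = (n_a - het) // 2
        return Fraction(
            math.factorial(n) * 2**het * math.factorial(n_A) * math.factorial(n_a),
            math.factorial(aa) * math.factorial(het) * math.factorial(bb)
            * math.factorial(2 * n),
        )

    hets = range(n_A % 2, min(n_A, n_a) + 1, 2)
    p_obs = prob(n_Aa)
    total = Fraction(0)
    for het in hets:
        ph = prob(het)
        if ph <= p_obs:
            total += ph
    return float(total)


def r2_dosage_brute(da, db):
    """Squared Pearson correlation of two dosage vectors, plain loops."""
    pairs = [(a, b) for a, b in zip(da, db) if not (math.isnan(a) or math.isnan(b))]
    if len(pairs) < 2:
        return float("nan")
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    n = len(pairs)
    mx, my = sum(xs) / n, sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    if vx <= 1e-12 or vy <= 1e-12:
        return float("nan")
    cov = sum((x - mx) * (y - my) for x, y in pairs) / n
    return cov**2 / (vx * vy)


def burrows_r2_brute(da, db):
    """Composite Burrows r^2 for two dosage vectors, plain loops.

    Returns (S, r2) over the individuals non-missing at both loci, or None
    when fewer than two such individuals or zero allele variance.
    """
    pairs = [(a, b) for a, b in zip(da, db) if not (math.isnan(a) or math.isnan(b))]
    S = len(pairs)
    if S < 2:
        return None
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    pa = sum(xs) / (2 * S)
    pb = sum(ys) / (2 * S)
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return None
    mx, my = sum(xs) / S, sum(ys) / S
    cov = sum((x - mx) * (y - my) for x, y in pairs) / (S - 1)
    return S, min(1.0, (cov / 2) ** 2 / denom)


def window_members_brute(positions, lg, start, width):
    """Loci on linkage group ``lg`` with start <= cM < start + width."""
    return sorted(
        lid
        for lid, (g, cm) in positions.items()
        if g == lg and start <= cm < start + width
    )


def merge_intervals_brute(intervals, resolution=0.25):
    """Merge overlap-or-touch intervals per group via a coverage grid."""
    out = []
    by_lg = {}
    for lg, lo, hi in intervals:
        by_lg.setdefault(lg, []).append((lo, hi))
    for lg in sorted(by_lg):
        spans = by_lg[lg]
        hi_all = max(h for _, h in spans)
        n = int(round(hi_all / resolution)) + 1
        covered = np.zeros(n + 1, dtype=bool)
        for lo, hi in spans:
            covered[int(round(lo / resolution)) : int(round(hi / resolution))] = True
        i = 0
        while i <= n:
            if covered[i]:
                j = i
                while j <= n and covered[j]:
                    j += 1
                out.append((lg, i * resolution, j * resolution))
                i = j
            else:
                i += 1
    return out


def amova_brute(allele_values_by_group):
    """Nested ANOVA variance components on explicit 0/1 allele copies.

    ``allele_values_by_group`` is {group: {pop: list of allele values}}.
    Returns (sigma2_among_groups, sigma2_among_pops, sigma2_within_pops).
    """
    groups = list(allele_values_by_group)
    G = len(groups)
    pops = [(g, p) for g in groups for p in allele_values_by_group[g]]
    P = len(pops)
    m = {gp: len(allele_values_by_group[gp[0]][gp[1]]) for gp in pops}
    s = {gp: sum(allele_values_by_group[gp[0]][gp[1]]) for gp in pops}
    M = sum(m.values())
    S = sum(s.values())
    Mg = {g: sum(m[gp] for gp in pops if gp[0] == g) for g in groups}
    Sg = {g: sum(s[gp] for gp in pops if gp[0] == g) for g in groups}

    ss_within = sum(s[gp] - s[gp] ** 2 / m[gp] for gp in pops)
    ss_pops = sum(
        sum(s[gp] ** 2 / m[gp] for gp in pops if gp[0] == g) - Sg[g] ** 2 / Mg[g]
        for g in groups
    )
    ss_groups = sum(Sg[g] ** 2 / Mg[g] for g in groups) - S**2 / M

    df_c, df_b, df_a = M - P, P - G, G - 1
    ms_c = ss_within / df_c
    ms_b = ss_pops / df_b
    n_prime = (M - sum(
        sum(m[gp] ** 2 for gp in pops if gp[0] == g) / Mg[g] for g in groups
    )) / df_b
    sigma_c = ms_c
    sigma_b = (ms_b - ms_c) / n_prime
    if df_a == 0:
        return 0.0, sigma_b, sigma_c
    ms_a = ss_groups / df_a
    n_dprime = (
        sum(sum(m[gp] ** 2 for gp in pops if gp[0] == g) / Mg[g] for g in groups)
        - sum(m[gp] ** 2 for gp in pops) / M
    ) / df_a
    n_tprime = (M - sum(Mg[g] ** 2 for g in groups) / M) / df_a
    sigma_a = (ms_a - sigma_c - n_dprime * sigma_b) / n_tprime
    return sigma_a, sigma_b, sigma_c
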