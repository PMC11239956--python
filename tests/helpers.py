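"""Independent oracles used by the test suite.

Everything here is written from the definitions, with plain loops, and
deliberately shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ----------------------------------------------------------------------
# AMOVA from definitional double sums
# ----------------------------------------------------------------------

def amova_oracle(D2: np.ndarray, pops: list, groups: list | None = None) -> dict:
    """Variance components and Φ statistics from explicit double sums."""
    N = len(pops)
    pop_levels = sorted(set(pops))

    def pair_sum(members):
        s = 0.0
        for i, j in itertools.combinations(members, 2):
            s += D2[i, j]
        return s

    everyone = list(range(N))
    ssd_total = pair_sum(everyone) / N

    ssd_wp = 0.0
    for p in pop_levels:
        members = [i for i in everyone if pops[i] == p]
        ssd_wp += pair_sum(members) / len(members)

    if groups is None:
        P = len(pop_levels)
        ssd_ap = ssd_total - ssd_wp
        ms_ap = ssd_ap / (P - 1)
        ms_wp = ssd_wp / (N - P)
        sizes = [sum(1 for x in pops if x == p) for p in pop_levels]
        n_c = (N - sum(s * s for s in sizes) / N) / (P - 1)
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / n_c
        return {
            "ssd_among_populations": ssd_ap,
            "ssd_within_populations": ssd_wp,
            "sigma": {"among_populations": sigma_b, "within_populations": sigma_c},
            "phi_st": sigma_b / (sigma_b + sigma_c),
        }

    group_levels = sorted(set(groups))
    G = len(group_levels)
    P = len(pop_levels)
    ssd_wg = 0.0
    for gname in group_levels:
        members = [i for i in everyone if groups[i] == gname]
        ssd_wg += pair_sum(members) / len(members)
    ssd_ag = ssd_total - ssd_wg
    ssd_ap = ssd_wg - ssd_wp

    ms_ag = ssd_ag / (G - 1)
    ms_ap = ssd_ap / (P - G)
    ms_wp = ssd_wp / (N - P)

    group_of_pop = {}
    for i in everyone:
        group_of_pop[pops[i]] = groups[i]
    size_of_pop = {p: sum(1 for x in pops if x == p) for p in pop_levels}
    size_of_group = {gname: sum(1 for x in groups if x == gname)
                     for gname in group_levels}

    term_a = 0.0
    for gname in group_levels:
        s = sum(size_of_pop[p] ** 2 for p in pop_levels if group_of_pop[p] == gname)
        term_a += s / size_of_group[gname]
    term_b = sum(size_of_pop[p] ** 2 for p in pop_levels) / N
    term_c = sum(size_of_group[gname] ** 2 for gname in group_levels) / N

    n1 = (N - term_a) / (P - G)
    n2 = (term_a - term_b) / (G - 1)
    n3 = (N - term_c) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return {
        "ssd_among_groups": ssd_ag,
        "ssd_among_populations": ssd_ap,
        "ssd_within_populations": ssd_wp,
        "sigma": {
            "among_groups": sigma_a,
            "among_populations": sigma_b,
            "within_populations": sigma_c,
        },
        "phi_st": (sigma_a + sigma_b) / total,
        "phi_ct": sigma_a / total,
        "phi_sc": sigma_b / (sigma_b + sigma_c),
    }


# ----------------------------------------------------------------------
# HWE exact test by full enumeration
# ----------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value via brute-force enumeration of genotype tables."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A

    def prob(h: int) -> float:
        # unnormalized weight of a table with h heterozygotes and the
        # same allele counts
        aa = (n_A - h) // 2
        bb = (n_a - h) // 2
        if aa < 0 or bb < 0 or (n_A - h) % 2:
            return 0.0
        return (2.0**h) * math.factorial(n) / (
            math.factorial(aa) * math.factorial(h) * math.factorial(bb)
        )

    weights = {h: prob(h) for h in range(0, min(n_A, n_a) + 1) if prob(h) > 0}
    total = sum(weights.values())
    if not weights:
        return 1.0
    p_obs = weights.get(n_Aa, 0.0)
    return sum(w for w in weights.values() if w <= p_obs * (1 + 1e-12)) / total


# ----------------------------------------------------------------------
# Weir–Cockerham F_ST (multi-locus ratio-of-averages)
# ----------------------------------------------------------------------

def weir_cockerham_fst(G: np.ndarray, pops: list) -> float:
    """Two-level Weir & Cockerham θ from a dosage matrix (no missing)."""
    pop_levels = sorted(set(pops))
    r = len(pop_levels)
    num = den = 0.0
    for locus in range(G.shape[1]):
        n_i, p_i, h_i = [], [], []
        for p in pop_levels:
            rows = [k for k in range(len(pops)) if pops[k] == p]
            gl = G[rows, locus]
            n_i.append(len(gl))
            p_i.append(gl.sum() / (2 * len(gl)))
            h_i.append(np.mean(gl == 1))
        n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
        n_bar = n_i.mean()
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        num += a
        den += a + b + c
    return num / den


# ----------------------------------------------------------------------
# Statistical-parsimony probability by Monte-Carlo placement
# ----------------------------------------------------------------------

def parsimony_mc_oracle(
    seq_len: int, j: int, n_draws: int = 200_000, seed: int = 0
) -> float:
    """P(no site hit twice | j sites differ) by simulating the model.

    Per-site substitution counts are Poisson with the Jukes–Cantor rate
    whose expected differing-site fraction equals j/m; a site differs with
    probability 3/4·(1 - (-1/3)^k) given k hits.  Conditioning on exactly
    j differing sites by rejection.
    """
    m = seq_len
    p = j / m
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    rng = np.random.default_rng(seed)
    hits = rng.poisson(lam, size=(n_draws, m))
    differs = np.zeros_like(hits, dtype=bool)
    nonzero = hits > 0
    u = rng.random(hits.shape)
    p_diff_given_k = 0.75 * (1.0 - (-1.0 / 3.0) ** hits[nonzero])
    differs[nonzero] = u[nonzero] < p_diff_given_k
    match = differs.sum(axis=1) == j
    if match.sum() == 0:
        return float("nan")
    parsimonious = (hits[match] <= 1).all(axis=1)
    return parsimonious.mean()
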