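"""SNP population statistics: diversity, HWE, AMOVA / Φ statistics, pairwise F_ST.

The central machinery is an Excoffier-style analysis of molecular variance
(AMOVA): squared pairwise genetic distances between individuals are
decomposed into hierarchical variance components — among groups (σ²_a),
among populations within groups (σ²_b), and within populations (σ²_c) —
with unequal-sample-size coefficients.  Φ statistics are ratios of these
components and their significance is assessed by permuting labels at the
matching hierarchical level:

* Φ_ST — individuals permuted among populations;
* Φ_CT — whole populations permuted among groups;
* Φ_SC — individuals permuted among populations within groups.

Negative variance-component estimates are retained by default (classical
AMOVA behaviour); a truncate-at-zero option is provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = [
    "AmovaResult",
    "FstMatrix",
    "locus_statistics",
    "hwe_exact_test",
    "completeness_filter",
    "pairwise_difference_matrix",
    "allele_mismatch_matrix",
    "squared_distance_matrix",
    "amova",
    "pairwise_phi_st",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Per-locus statistics
# ----------------------------------------------------------------------

def locus_statistics(
    g: GenotypeMatrix, by_population: bool = False
) -> pd.DataFrame:
    """Per-locus allele frequency, H_o, unbiased H_e, π and F_IS.

    H_e uses the unbiased estimator ``2 p (1 - p) n / (n - 1)`` on the
    allele count ``n`` (twice the number of non-missing genotypes); π per
    variant site equals unbiased H_e.  F_IS = 1 - H_o / H_e where H_e > 0
    and is NaN (flagged ``monomorphic``) otherwise.  Loci with no calls at
    all are skipped with a logged count.

    Returns a DataFrame with one row per locus (or per population × locus
    when ``by_population`` is true; the HWE exact p-value is included in
    both layouts).
    """
    if by_population:
        frames = []
        for pop in g.populations:
            sub = g.subset_individuals(g.population_of(pop))
            frame = locus_statistics(sub, by_population=False)
            frame.insert(0, "population", pop)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    G = g.genotypes
    called = ~np.isnan(G)
    n_called = called.sum(axis=0)
    keep = n_called > 0
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("skipping %d loci with no non-missing genotypes", n_skipped)

    G = G[:, keep]
    called = called[:, keep]
    n_called = n_called[keep]
    n_alleles = 2.0 * n_called

    alt = np.nansum(G, axis=0)
    p_hat = alt / n_alleles
    ho = (G == 1).sum(axis=0) / n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        he = np.where(
            n_alleles > 1, 2.0 * p_hat * (1.0 - p_hat) * n_alleles / (n_alleles - 1.0), 0.0
        )
        fis = np.where(he > 0, 1.0 - ho / he, np.nan)

    counts_het = (G == 1).sum(axis=0)
    counts_hom_alt = (G == 2).sum(axis=0)
    counts_hom_ref = n_called - counts_het - counts_hom_alt
    hwe_p = np.array(
        [
            hwe_exact_test(int(aa), int(ab), int(bb))
            for aa, ab, bb in zip(counts_hom_ref, counts_het, counts_hom_alt)
        ]
    )

    return pd.DataFrame(
        {
            "locus_id": [lid for lid, k in zip(g.locus_ids, keep) if k],
            "n_called": n_called.astype(int),
            "p_hat": p_hat,
            "ho": ho,
            "he": he,
            "pi": he,
            "fis": fis,
            "hwe_p": hwe_p,
            "monomorphic": he == 0.0,
        }
    )


# ----------------------------------------------------------------------
# Hardy–Weinberg exact test
# ----------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _het_probabilities(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of heterozygote counts given n diploids, n_a minor
    alleles (conditional on allele counts; Levene/Haldane)."""
    n_b = 2 * n - n_a
    h_max = min(n_a, n_b)
    hs = np.arange(n_a % 2, h_max + 1, 2)
    log_w = (
        hs * math.log(2.0)
        - gammaln((n_a - hs) / 2 + 1)
        - gammaln(hs + 1)
        - gammaln((n_b - hs) / 2 + 1)
    )
    log_w -= log_w.max()
    probs = np.exp(log_w)
    probs /= probs.sum()
    return hs, probs


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy–Weinberg equilibrium.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count (two-sided, full tail mass — no mid-p correction).
    Monomorphic samples return p = 1.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1 or min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative with n >= 1")
    n_alt = 2 * n_aa + n_Aa
    n_a = min(n_alt, 2 * n - n_alt)
    if n_a == 0:
        return 1.0
    hs, probs = _het_probabilities(n, n_a)
    p_obs = probs[np.searchsorted(hs, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# Locus completeness filter
# ----------------------------------------------------------------------

def completeness_filter(
    g: GenotypeMatrix,
    min_call_fraction: float = 0.5,
    min_populations: int = 6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep loci called in ≥ ``min_call_fraction`` of individuals and present
    in ≥ ``min_populations`` populations (capped at the number available).

    Emulates Stacks' *populations* ``-R`` / ``-p`` filters.  Returns the
    filtered matrix and a per-locus report.
    """
    called = ~np.isnan(g.genotypes)
    frac = called.mean(axis=0)
    pops = np.asarray(g.population)
    present_in = np.zeros(g.n_loci, dtype=int)
    for pop in g.populations:
        present_in += called[pops == pop].any(axis=0)
    p_req = min(min_populations, len(g.populations))
    keep = (frac >= min_call_fraction) & (present_in >= p_req)
    report = pd.DataFrame(
        {
            "locus_id": g.locus_ids,
            "call_fraction": frac,
            "populations_present": present_in,
            "kept": keep,
        }
    )
    return g.subset_loci(keep), report


# ----------------------------------------------------------------------
# Pairwise differences and AMOVA
# ----------------------------------------------------------------------

def pairwise_difference_matrix(
    g: GenotypeMatrix, rescale_missing: bool = True
) -> np.ndarray:
    """Pairwise-difference distances d(i, j) = Σ_loci |g_i - g_j|.

    Loci missing in either member of a pair are excluded; with
    ``rescale_missing`` the partial sum is rescaled by L / L_shared so
    distances stay comparable across pairs with different completeness.
    """
    G = g.genotypes
    called = ~np.isnan(G)
    n, L = G.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    G0 = np.where(called, G, 0.0)
    D = np.zeros((n, n))
    for i in range(n):
        shared = called[i] & called
        diff = np.abs(G0[i] - G0) * shared
        L_shared = shared.sum(axis=1)
        zero = np.flatnonzero(L_shared == 0)
        zero = zero[zero != i]
        if zero.size:
            j = int(zero[0])
            raise ValueError(
                f"individuals {g.individual_ids[i]!r} and {g.individual_ids[j]!r} "
                "share no called loci"
            )
        d = diff.sum(axis=1)
        if rescale_missing:
            d = d * (L / L_shared)
        D[i] = d
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def allele_mismatch_matrix(
    g: GenotypeMatrix, rescale_missing: bool = True
) -> np.ndarray:
    """Expected allele-difference counts between unphased diploids.

    Per locus, the expected number of differences between one random
    allele of i and one of j is [g_i (2 - g_j) + g_j (2 - g_i)] / 4;
    summed over loci this is the squared molecular distance that makes the
    AMOVA Φ statistics estimate the allele-frequency differentiation (F)
    directly.  Missing handling matches
    :func:`pairwise_difference_matrix`.
    """
    G = g.genotypes
    called = ~np.isnan(G)
    n, L = G.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    G0 = np.where(called, G, 0.0)
    D2 = np.zeros((n, n))
    for i in range(n):
        shared = called[i] & called
        mism = (G0[i] * (2.0 - G0) + G0 * (2.0 - G0[i])) / 4.0 * shared
        L_shared = shared.sum(axis=1)
        zero = np.flatnonzero(L_shared == 0)
        zero = zero[zero != i]
        if zero.size:
            j = int(zero[0])
            raise ValueError(
                f"individuals {g.individual_ids[i]!r} and {g.individual_ids[j]!r} "
                "share no called loci"
            )
        d = mism.sum(axis=1)
        if rescale_missing:
            d = d * (L / L_shared)
        D2[i] = d
    np.fill_diagonal(D2, 0.0)
    return (D2 + D2.T) / 2.0


def squared_distance_matrix(
    g: GenotypeMatrix, metric: str = "allele_mismatch", rescale_missing: bool = True
) -> np.ndarray:
    """Squared molecular distances feeding the AMOVA decomposition.

    ``allele_mismatch`` (default) is calibrated so Φ estimates F directly;
    ``manhattan`` treats the dosage-difference count Σ|g_i - g_j| itself
    as the squared distance (the classical treat-the-count-as-d²
    convention for molecular data).
    """
    if metric == "allele_mismatch":
        return allele_mismatch_matrix(g, rescale_missing=rescale_missing)
    if metric == "manhattan":
        return pairwise_difference_matrix(g, rescale_missing=rescale_missing)
    raise ValueError("metric must be 'allele_mismatch' or 'manhattan'")


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition of squared pairwise distances."""

    levels: int
    ssd: dict[str, float]
    df: dict[str, int]
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    phi_st: float
    phi_ct: float | None = None
    phi_sc: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum in self.ssd:
            rows.append(
                {
                    "stratum": stratum,
                    "df": self.df[stratum],
                    "ssd": self.ssd[stratum],
                    "variance_component": self.variance_components.get(stratum, np.nan),
                    "percent_variation": self.percent_variation.get(stratum, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _codes(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    uniq = list(dict.fromkeys(labels))
    lookup = {lab: k for k, lab in enumerate(uniq)}
    return np.array([lookup[lab] for lab in labels]), uniq


def _pair_sum_within(D2: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Σ_{i<j in level} d², per level (ordered double sum halved)."""
    out = np.empty(n_levels)
    for k in range(n_levels):
        idx = np.flatnonzero(codes == k)
        out[k] = D2[np.ix_(idx, idx)].sum() / 2.0
    return out


def _amova_components(
    D2: np.ndarray,
    pop_codes: np.ndarray,
    group_codes: np.ndarray | None,
) -> dict:
    """Variance components and Φ statistics for one permuted/observed layout."""
    N = D2.shape[0]
    P = int(pop_codes.max()) + 1
    n_p = np.bincount(pop_codes, minlength=P).astype(float)

    ssd_total = D2.sum() / (2.0 * N)
    within_pop_sums = _pair_sum_within(D2, pop_codes, P)
    ssd_wp = float((within_pop_sums / n_p).sum())

    if group_codes is None:
        ssd_ap = ssd_total - ssd_wp
        df_ap, df_wp = P - 1, N - P
        ms_ap = ssd_ap / df_ap
        ms_wp = ssd_wp / df_wp
        n_c = (N - (n_p**2).sum() / N) / (P - 1)
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / n_c
        total = sigma_b + sigma_c
        if total == 0:
            raise ValueError("total molecular variance is zero; Φ undefined")
        return {
            "ssd": {"among_populations": ssd_ap, "within_populations": ssd_wp,
                    "total": ssd_total},
            "df": {"among_populations": df_ap, "within_populations": df_wp,
                   "total": N - 1},
            "sigma": {"among_populations": sigma_b, "within_populations": sigma_c},
            "phi_st": sigma_b / total,
        }

    G = int(group_codes.max()) + 1
    pop_group = np.empty(P, dtype=int)
    for k in range(P):
        pop_group[k] = group_codes[np.flatnonzero(pop_codes == k)[0]]
    N_g = np.bincount(group_codes, minlength=G).astype(float)

    within_group_sums = _pair_sum_within(D2, group_codes, G)
    ssd_within_groups_total = float((within_group_sums / N_g).sum())
    ssd_ag = ssd_total - ssd_within_groups_total
    ssd_ap = ssd_within_groups_total - ssd_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P

    ms_ag = ssd_ag / df_ag
    ms_ap = ssd_ap / df_ap
    ms_wp = ssd_wp / df_wp

    # Unequal-sample-size coefficients for the two-level nested design.
    sum_np2_by_group = np.zeros(G)
    for k in range(P):
        sum_np2_by_group[pop_group[k]] += n_p[k] ** 2
    n1 = (N - (sum_np2_by_group / N_g).sum()) / (P - G)
    n2 = ((sum_np2_by_group / N_g).sum() - (n_p**2).sum() / N) / (G - 1)
    n3 = (N - (N_g**2).sum() / N) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        raise ValueError("total molecular variance is zero; Φ undefined")
    return {
        "ssd": {"among_groups": ssd_ag, "among_populations": ssd_ap,
                "within_populations": ssd_wp, "total": ssd_total},
        "df": {"among_groups": df_ag, "among_populations": df_ap,
               "within_populations": df_wp, "total": N - 1},
        "sigma": {"among_groups": sigma_a, "among_populations": sigma_b,
                  "within_populations": sigma_c},
        "phi_st": (sigma_a + sigma_b) / total,
        "phi_ct": sigma_a / total,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan,
    }


def amova(
    g: GenotypeMatrix,
    hierarchy: str = "pops",
    n_permutations: int = 10_000,
    seed: int | None = None,
    rescale_missing: bool = True,
    truncate_negative: bool = False,
    metric: str = "allele_mismatch",
    squared_distances: np.ndarray | None = None,
) -> AmovaResult:
    """One- or two-level AMOVA on pairwise-difference distances.

    Parameters
    ----------
    hierarchy
        ``"pops"`` for a one-level decomposition (among / within
        populations) or ``"groups/pops"`` for the nested two-level design.
    n_permutations
        Label permutations per Φ statistic; 0 skips permutation testing.
        p = (#{perm ≥ observed} + 1) / (n_perm + 1).
    truncate_negative
        Truncate negative variance components at zero before forming Φ
        (default keeps raw estimates).
    metric
        Squared-distance convention, see :func:`squared_distance_matrix`.
    squared_distances
        Optional precomputed squared-distance matrix (overrides
        ``metric``).
    """
    if hierarchy not in ("pops", "groups/pops"):
        raise ValueError("hierarchy must be 'pops' or 'groups/pops'")
    two_level = hierarchy == "groups/pops"
    pop_codes, _ = _codes(g.population)
    if pop_codes.max() < 1:
        raise ValueError("AMOVA needs at least two populations")
    group_codes = None
    if two_level:
        if g.group is None:
            raise ValueError("two-level AMOVA needs group labels")
        group_codes, _ = _codes(g.group)
        if group_codes.max() < 1:
            raise ValueError("two-level AMOVA needs at least two groups")

    D2 = squared_distances
    if D2 is None:
        D2 = squared_distance_matrix(g, metric=metric, rescale_missing=rescale_missing)

    obs = _amova_components(D2, pop_codes, group_codes)
    sigma = dict(obs["sigma"])
    if truncate_negative:
        sigma = {k: max(0.0, v) for k, v in sigma.items()}
    total = sum(sigma.values())
    percent = {k: 100.0 * v / total for k, v in sigma.items()}

    if truncate_negative:
        if two_level:
            phi_st = (sigma["among_groups"] + sigma["among_populations"]) / total
            phi_ct = sigma["among_groups"] / total
            bc = sigma["among_populations"] + sigma["within_populations"]
            phi_sc = sigma["among_populations"] / bc if bc else np.nan
        else:
            phi_st = sigma["among_populations"] / total
            phi_ct = phi_sc = None
    else:
        phi_st = obs["phi_st"]
        phi_ct = obs.get("phi_ct")
        phi_sc = obs.get("phi_sc")

    p_values: dict[str, float] = {}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        N = len(pop_codes)

        def _count(stat_key: str, permute) -> float:
            hits = 0
            for _ in range(n_permutations):
                try:
                    stat = permute()[stat_key]
                except ValueError:  # degenerate permuted layout
                    stat = np.inf
                if stat >= obs[stat_key] - 1e-12:
                    hits += 1
            return (hits + 1) / (n_permutations + 1)

        def _perm_phi_st():
            perm = rng.permutation(N)
            return _amova_components(D2, pop_codes[perm], group_codes)

        p_values["phi_st"] = _count("phi_st", _perm_phi_st)

        if two_level:
            P = int(pop_codes.max()) + 1
            pop_group = np.empty(P, dtype=int)
            for k in range(P):
                pop_group[k] = group_codes[np.flatnonzero(pop_codes == k)[0]]

            def _perm_phi_ct():
                shuffled = rng.permutation(pop_group)
                return _amova_components(D2, pop_codes, shuffled[pop_codes])

            def _perm_phi_sc():
                new_pops = pop_codes.copy()
                for grp in range(int(group_codes.max()) + 1):
                    idx = np.flatnonzero(group_codes == grp)
                    new_pops[idx] = new_pops[idx[rng.permutation(idx.size)]]
                return _amova_components(D2, new_pops, group_codes)

            p_values["phi_ct"] = _count("phi_ct", _perm_phi_ct)
            p_values["phi_sc"] = _count("phi_sc", _perm_phi_sc)

    return AmovaResult(
        levels=2 if two_level else 1,
        ssd=obs["ssd"],
        df=obs["df"],
        variance_components=sigma,
        percent_variation=percent,
        phi_st=phi_st,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        p_values=p_values,
        n_permutations=n_permutations,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Pairwise Φ_ST / F_ST
# ----------------------------------------------------------------------

@dataclass
class FstMatrix:
    """Pairwise Φ_ST between populations with permutation p-values."""

    populations: list[str]
    fst: np.ndarray                 # raw estimates (may be negative)
    fst_floored: np.ndarray         # negatives floored at zero for display
    linearized: np.ndarray          # Slatkin linearization F / (1 - F)
    p_values: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_values <= self.alpha

    def to_frame(self, which: str = "fst") -> pd.DataFrame:
        return pd.DataFrame(
            getattr(self, which), index=self.populations, columns=self.populations
        )


def pairwise_phi_st(
    g: GenotypeMatrix,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    rescale_missing: bool = True,
    metric: str = "allele_mismatch",
) -> FstMatrix:
    """Pairwise Φ_ST: one-level AMOVA restricted to each population pair.

    Raw estimates are reported as computed (negatives permitted); a
    floored copy and the Slatkin linearization F/(1-F) accompany them.
    Populations with fewer than two individuals are skipped (NaN entries)
    with a warning.
    """
    pops = g.populations
    P = len(pops)
    if P < 2:
        raise ValueError("need at least two populations")
    D2 = squared_distance_matrix(g, metric=metric, rescale_missing=rescale_missing)
    pop_codes, _ = _codes(g.population)
    sizes = np.bincount(pop_codes, minlength=P)

    fst = np.full((P, P), np.nan)
    pvals = np.full((P, P), np.nan)
    np.fill_diagonal(fst, 0.0)
    np.fill_diagonal(pvals, 1.0)
    ss = np.random.SeedSequence(seed)
    for a in range(P):
        for b in range(a + 1, P):
            if sizes[a] < 2 or sizes[b] < 2:
                logger.warning(
                    "skipping pair (%s, %s): population with < 2 individuals",
                    pops[a], pops[b],
                )
                continue
            idx = np.flatnonzero((pop_codes == a) | (pop_codes == b))
            sub_codes = (pop_codes[idx] == b).astype(int)
            subD2 = D2[np.ix_(idx, idx)]
            try:
                obs = _amova_components(subD2, sub_codes, None)
            except ValueError:
                fst[a, b] = fst[b, a] = 0.0
                pvals[a, b] = pvals[b, a] = 1.0
                continue
            fst[a, b] = fst[b, a] = obs["phi_st"]
            if n_permutations > 0:
                rng = np.random.default_rng(ss.spawn(1)[0])
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(idx.size)
                    try:
                        stat = _amova_components(subD2, sub_codes[perm], None)["phi_st"]
                    except ValueError:
                        stat = np.inf
                    if stat >= obs["phi_st"] - 1e-12:
                        hits += 1
                pvals[a, b] = pvals[b, a] = (hits + 1) / (n_permutations + 1)

    floored = np.where(np.isnan(fst), np.nan, np.maximum(fst, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        linearized = np.where(fst < 1.0, fst / (1.0 - fst), np.inf)
    return FstMatrix(
        populations=pops,
        fst=fst,
        fst_floored=floored,
        linearized=linearized,
        p_values=pvals,
        alpha=alpha,
    )
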