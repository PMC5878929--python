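"""Per-locus and pairwise population statistics.

Covers the marker-characterisation stage of a panel-validation workflow:
allele frequencies, polymorphic information content (PIC, Botstein et al.),
Weir & Cockerham's multi-allelic theta estimator of F_ST, Shannon mutual
information between allele identity and population label, a Monte Carlo
exact test of Hardy-Weinberg equilibrium, and PIC-based locus ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import GenotypeTable

HIGHEST_FIRST = "highest_first"
LOWEST_FIRST = "lowest_first"


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class FrequencyModel:
    """Per-population, per-locus allele counts over a global allele inventory.

    ``inventories[l]`` is the sorted array of distinct allele codes observed
    at locus ``l`` pooled over ALL populations; ``counts[pop][l]`` is the
    vector of called-allele counts in that population aligned to the
    inventory.  ``k`` for the Bayesian assignment prior is
    ``len(inventories[l])``.
    """

    populations: list[str]
    locus_names: list[str]
    inventories: list[np.ndarray]
    counts: dict[str, list[np.ndarray]]
    zero_count_flags: list[tuple[str, str]] = field(default_factory=list)

    def total(self, population: str, locus_index: int) -> int:
        """Total called alleles (2 x called genotypes) for one pop-locus."""
        return int(self.counts[population][locus_index].sum())

    def frequencies(self, population: str, locus_index: int) -> np.ndarray:
        n = self.total(population, locus_index)
        c = self.counts[population][locus_index]
        return c / n if n > 0 else np.zeros_like(c, dtype=float)

    def pooled_counts(self, locus_index: int) -> np.ndarray:
        out = np.zeros(len(self.inventories[locus_index]), dtype=np.int64)
        for pop in self.populations:
            out += self.counts[pop][locus_index]
        return out

    def k(self, locus_index: int) -> int:
        return len(self.inventories[locus_index])


def allele_frequencies(table: GenotypeTable) -> FrequencyModel:
    """Count alleles per population and locus, excluding missing genotypes.

    A population with zero called alleles at a locus is recorded with an
    all-zero count vector and flagged in ``zero_count_flags``.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("empty genotype table")
    pops = table.populations
    inventories: list[np.ndarray] = []
    for l in range(table.n_loci):
        codes = table.alleles[:, l, :].ravel()
        inventories.append(np.unique(codes[codes > 0]))
    counts: dict[str, list[np.ndarray]] = {}
    flags: list[tuple[str, str]] = []
    labels = np.array(table.population_labels)
    for pop in pops:
        rows = labels == pop
        per_locus: list[np.ndarray] = []
        for l in range(table.n_loci):
            inv = inventories[l]
            codes = table.alleles[rows, l, :].ravel()
            codes = codes[codes > 0]
            c = np.zeros(len(inv), dtype=np.int64)
            if codes.size:
                idx = np.searchsorted(inv, codes)
                np.add.at(c, idx, 1)
            else:
                flags.append((pop, table.locus_names[l]))
            per_locus.append(c)
        counts[pop] = per_locus
    return FrequencyModel(
        populations=list(pops),
        locus_names=list(table.locus_names),
        inventories=inventories,
        counts=counts,
        zero_count_flags=flags,
    )


def encode_alleles(table: GenotypeTable, model: FrequencyModel) -> np.ndarray:
    """Map allele codes to inventory indices; -1 marks missing genotypes.

    Returns an ``(n_individuals, n_loci, 2)`` int array used by the fast
    likelihood machinery.
    """
    out = np.full(table.alleles.shape, -1, dtype=np.int64)
    for l in range(table.n_loci):
        inv = model.inventories[l]
        codes = table.alleles[:, l, :]
        called = codes[:, 0] > 0
        if called.any():
            out[called, l, :] = np.searchsorted(inv, codes[called])
    return out


# ---------------------------------------------------------------------------
# PIC and heterozygosity


def pic(frequencies: np.ndarray) -> float:
    """Polymorphic information content of one locus.

    ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``; 0 for a monomorphic
    locus, and always strictly below 1.
    """
    p = np.asarray(frequencies, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty allele frequency vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("allele frequencies must sum to 1")
    sq = float(np.sum(p**2))
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return 1.0 - sq - (sq**2 - float(np.sum(p**4)))


def expected_heterozygosity(frequencies: np.ndarray) -> float:
    p = np.asarray(frequencies, dtype=float)
    return 1.0 - float(np.sum(p**2))


@dataclass
class LocusStats:
    """Summary of one locus: informativeness and HWE screening inputs."""

    locus: str
    pic: float
    observed_heterozygosity: float
    expected_heterozygosity: float
    hwe_pvalues: dict[str, float]
    sample_sizes: dict[str, int]


def locus_statistics(
    table: GenotypeTable,
    n_permutations: int = 2000,
    seed: int = 0,
) -> list[LocusStats]:
    """Per-locus PIC (pooled over populations), heterozygosities, and
    per-population HWE Monte Carlo p-values."""
    model = allele_frequencies(table)
    out: list[LocusStats] = []
    rng = np.random.default_rng(seed)
    for l, locus in enumerate(table.locus_names):
        pooled = model.pooled_counts(l)
        n = pooled.sum()
        freqs = pooled / n if n > 0 else pooled.astype(float)
        called = ~table.missing_mask[:, l]
        n_called = int(called.sum())
        het = table.alleles[called, l, 0] != table.alleles[called, l, 1]
        obs_het = float(het.mean()) if n_called else float("nan")
        pvals: dict[str, float] = {}
        sizes: dict[str, int] = {}
        labels = np.array(table.population_labels)
        for pop in model.populations:
            rows = (labels == pop) & called
            sizes[pop] = int(rows.sum())
            if sizes[pop] >= 2:
                sub_seed = int(rng.integers(2**31 - 1))
                pvals[pop] = hwe_test(
                    table, pop, locus, n_permutations=n_permutations, seed=sub_seed
                )
            else:
                pvals[pop] = float("nan")
        out.append(
            LocusStats(
                locus=locus,
                pic=pic(freqs) if n > 0 else 0.0,
                observed_heterozygosity=obs_het,
                expected_heterozygosity=expected_heterozygosity(freqs),
                hwe_pvalues=pvals,
                sample_sizes=sizes,
            )
        )
    return out


def rank_loci(locus_stats: list[LocusStats], direction: str) -> list[str]:
    """Order loci by PIC; ties keep input order (stable sort).

    ``highest_first`` is the ordering used when the most informative markers
    are genotyped first; ``lowest_first`` is the pessimistic ordering.
    """
    if direction not in (HIGHEST_FIRST, LOWEST_FIRST):
        raise ValueError(f"direction must be {HIGHEST_FIRST!r} or {LOWEST_FIRST!r}")
    reverse = direction == HIGHEST_FIRST
    ordered = sorted(
        locus_stats, key=lambda s: -s.pic if reverse else s.pic
    )
    return [s.locus for s in ordered]


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (F_ST)


def _wc_components(table: GenotypeTable, pops: list[str]) -> tuple[float, float]:
    """Sums of the W&C (1984) a and a+b+c variance components over all loci
    and alleles, for the given populations."""
    labels = np.array(table.population_labels)
    r = len(pops)
    sum_a = 0.0
    sum_abc = 0.0
    any_locus = False
    for l in range(table.n_loci):
        # per-pop called genotypes at this locus
        geno = table.alleles[:, l, :]
        called = geno[:, 0] > 0
        n_i = np.array([int(((labels == p) & called).sum()) for p in pops], float)
        if np.any(n_i < 1):
            continue
        codes = np.unique(geno[called])
        if codes.size < 2:
            # monomorphic locus contributes nothing
            any_locus = True
            continue
        any_locus = True
        nbar = n_i.mean()
        n_tot = n_i.sum()
        nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
        if nbar <= 1 or nc <= 0:
            continue
        # allele freqs and het carrier freqs per pop
        p_mat = np.zeros((r, codes.size))
        h_mat = np.zeros((r, codes.size))
        for i, pop in enumerate(pops):
            rows = (labels == pop) & called
            g = geno[rows]
            for a_idx, code in enumerate(codes):
                carry = (g == code).sum(axis=1)
                p_mat[i, a_idx] = carry.sum() / (2 * n_i[i])
                h_mat[i, a_idx] = ((carry == 1).sum()) / n_i[i]
        pbar = (n_i[:, None] * p_mat).sum(axis=0) / n_tot
        s2 = (n_i[:, None] * (p_mat - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_mat).sum(axis=0) / n_tot
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        sum_a += a.sum()
        sum_abc += (a + b + c).sum()
    if not any_locus:
        raise ValueError("no locus typed in all requested populations")
    return sum_a, sum_abc


def pairwise_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir & Cockerham theta between two populations.

    Computed as ``sum_loci,alleles a / sum_loci,alleles (a+b+c)`` with the
    standard variance components; may be slightly negative when
    differentiation is near zero.
    """
    for p in (pop_a, pop_b):
        if p not in table.populations:
            raise KeyError(f"unknown population {p!r}")
    sum_a, sum_abc = _wc_components(table, [pop_a, pop_b])
    if sum_abc == 0.0:
        return 0.0
    return sum_a / sum_abc


# ---------------------------------------------------------------------------
# Shannon mutual information


def mutual_information(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Mean per-locus mutual information (nats) between allele identity and
    population label for two populations.

    ``I = H(allele) - sum_s w_s H(allele | pop s)`` with weights ``w_s``
    proportional to called allele counts; zero iff both populations have
    identical allele frequencies at every locus.
    """
    model = allele_frequencies(table)
    for p in (pop_a, pop_b):
        if p not in model.populations:
            raise KeyError(f"unknown population {p!r}")
    vals: list[float] = []
    for l in range(table.n_loci):
        ca = model.counts[pop_a][l].astype(float)
        cb = model.counts[pop_b][l].astype(float)
        na, nb = ca.sum(), cb.sum()
        if na == 0 or nb == 0:
            continue
        pooled = ca + cb
        q = pooled / pooled.sum()
        h_tot = -float(np.sum(q[q > 0] * np.log(q[q > 0])))
        h_within = 0.0
        for c, n in ((ca, na), (cb, nb)):
            f = c / n
            h_within += (n / (na + nb)) * -float(np.sum(f[f > 0] * np.log(f[f > 0])))
        vals.append(max(h_tot - h_within, 0.0))
    if not vals:
        raise ValueError("no locus typed in both populations")
    return float(np.mean(vals))


def pairwise_differentiation(table: GenotypeTable) -> pd.DataFrame:
    """Theta and mutual information for every population pair."""
    rows = []
    for a, b in itertools.combinations(table.populations, 2):
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "theta_fst": pairwise_fst(table, a, b),
                "mutual_information": mutual_information(table, a, b),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)


def _genotype_array_logprob(pairs: np.ndarray) -> float:
    """Log conditional probability (Levene) of a genotype array given its
    allele counts: n! / prod(n_g!) * 2^h * prod(m_a!) / (2n)!."""
    n = pairs.shape[0]
    ordered = np.sort(pairs, axis=1)
    _, geno_counts = np.unique(ordered, axis=0, return_counts=True)
    h = int((pairs[:, 0] != pairs[:, 1]).sum())
    _, allele_counts = np.unique(pairs.ravel(), return_counts=True)
    return float(
        gammaln(n + 1)
        - gammaln(geno_counts + 1).sum()
        + h * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
    )


def hwe_test(
    table: GenotypeTable,
    population: str,
    locus: str,
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Monte Carlo exact test for Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts: alleles are repeatedly
    re-paired at random and the conditional probability of each permuted
    genotype array is compared with the observed one.  The p-value uses the
    ``(1 + r) / (1 + N)`` estimator; a monomorphic locus returns 1.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    try:
        l = table.locus_names.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    labels = np.array(table.population_labels)
    rows = (labels == population) & ~table.missing_mask[:, l]
    pairs = table.alleles[rows, l, :]
    if pairs.shape[0] < 2:
        raise ValueError("need at least 2 called genotypes for the HWE test")
    if np.unique(pairs).size < 2:
        return 1.0
    obs = _genotype_array_logprob(pairs)
    alleles = pairs.ravel().copy()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(alleles)
        perm = alleles.reshape(-1, 2)
        if _genotype_array_logprob(perm) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def hwe_screen(
    table: GenotypeTable,
    n_permutations: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """HWE screening report over all locus x population cells.

    Applies a Bonferroni correction across all tested cells and flags loci
    that depart from equilibrium in two or more populations; exclusion of
    flagged loci is left to the user.
    """
    stats = locus_statistics(table, n_permutations=n_permutations, seed=seed)
    cells = [
        (s.locus, pop, p)
        for s in stats
        for pop, p in s.hwe_pvalues.items()
        if not np.isnan(p)
    ]
    n_tests = len(cells)
    rows = []
    fails: dict[str, int] = {}
    for locus, pop, p in cells:
        sig = p < alpha / n_tests
        if sig:
            fails[locus] = fails.get(locus, 0) + 1
        rows.append(
            {
                "locus": locus,
                "population": pop,
                "p_value": p,
                "bonferroni_significant": sig,
            }
        )
    df = pd.DataFrame(rows)
    df["flagged_for_exclusion"] = df["locus"].map(
        lambda x: fails.get(x, 0) >= 2
    )
    return df
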