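"""SNP-validation cascade: ordered, configurable filters with an audit trail.

The filters mirror standard RAD-seq SNP validation practice: per-locus call
rate, minor allele frequency across populations, 3'-end tag positions, one
SNP per RAD tag, paralog screening against a haploid panel, Hardy-Weinberg
exact tests, linkage-disequilibrium pruning, per-individual missingness, and
duplicate-individual removal. Each step records exactly what it removed, so
the report replayed against the input reproduces the output.

Boundary semantics (documented, configurable): "genotyped in >80%" keeps a
locus when call rate >= 0.80; "tag position >87 bp" removes position >= 88;
">15% missing" removes an individual when missing > 0.15; ">10% haploid
heterozygosity" removes a locus when the fraction > 0.10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from radpopgen.genio import HAP_HET, HAP_MISSING, GenotypeDataset, HaploidPanel
from radpopgen import popstruct

logger = logging.getLogger(__name__)


@dataclass
class FilterStep:
    rule: str
    params: dict
    removed_loci: list[str]
    removed_individuals: list[str]
    n_loci_before: int
    n_loci_after: int
    n_ind_before: int
    n_ind_after: int


@dataclass
class FilterReport:
    """Ordered record of every filter step applied to a dataset."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, rule: str, params: dict, before: GenotypeDataset, after: GenotypeDataset) -> None:
        removed_loci = sorted(set(before.locus_ids) - set(after.locus_ids))
        removed_inds = sorted(set(before.individuals) - set(after.individuals))
        self.steps.append(
            FilterStep(
                rule=rule,
                params=params,
                removed_loci=removed_loci,
                removed_individuals=removed_inds,
                n_loci_before=before.n_loci,
                n_loci_after=after.n_loci,
                n_ind_before=before.n_individuals,
                n_ind_after=after.n_individuals,
            )
        )

    def total_removed_loci(self) -> list[str]:
        return [lid for s in self.steps for lid in s.removed_loci]

    def total_removed_individuals(self) -> list[str]:
        return [i for s in self.steps for i in s.removed_individuals]

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": i + 1,
                "rule": s.rule,
                "params": ";".join(f"{k}={v}" for k, v in s.params.items()),
                "n_loci_before": s.n_loci_before,
                "n_loci_removed": len(s.removed_loci),
                "n_loci_after": s.n_loci_after,
                "n_ind_before": s.n_ind_before,
                "n_ind_removed": len(s.removed_individuals),
                "n_ind_after": s.n_ind_after,
                "removed_loci": ",".join(s.removed_loci),
                "removed_individuals": ",".join(s.removed_individuals),
            }
            for i, s in enumerate(self.steps)
        ]


# ---------------------------------------------------------------------------
# Locus-level filters
# ---------------------------------------------------------------------------

def filter_call_rate(
    ds: GenotypeDataset, min_rate: float = 0.8
) -> tuple[GenotypeDataset, list[str]]:
    """Keep loci genotyped in at least ``min_rate`` of individuals."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    rate = ds.call_rate()
    keep = np.flatnonzero(rate >= min_rate)
    removed = [ds.locus_ids[i] for i in np.flatnonzero(rate < min_rate)]
    return ds.subset_loci(keep), removed


def per_population_maf(ds: GenotypeDataset) -> np.ndarray:
    """Minor allele frequency per (population, locus); NaN where no data."""
    labels = ds.pop_labels()
    idx = ds.pop_indices()
    n, x, _ = popstruct._pop_locus_counts(ds.dosage, ds.called, [idx[p] for p in labels])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, x / np.maximum(2 * n, 1), np.nan)
    return np.minimum(p, 1 - p)


def filter_maf(
    ds: GenotypeDataset, threshold: float = 0.05
) -> tuple[GenotypeDataset, list[str]]:
    """Remove loci whose minor allele frequency is below threshold in every
    population; one population at or above the threshold keeps the locus.

    A population with no genotyped individuals at a locus contributes no
    evidence and counts as below threshold there.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    maf = per_population_maf(ds)
    no_data = np.isnan(maf)
    if no_data.any():
        logger.info(
            "%d (population, locus) cells with no genotypes treated as below the MAF threshold",
            int(no_data.sum()),
        )
    passes = np.where(no_data, False, maf >= threshold)
    keep_mask = passes.any(axis=0)
    removed = [ds.locus_ids[i] for i in np.flatnonzero(~keep_mask)]
    return ds.subset_loci(np.flatnonzero(keep_mask)), removed


def filter_tag_position(
    ds: GenotypeDataset, max_pos: int = 87
) -> tuple[GenotypeDataset, list[str]]:
    """Remove loci at tag positions beyond ``max_pos`` (error-prone read tail)."""
    pos = np.array([l.tag_position for l in ds.loci])
    keep = np.flatnonzero(pos <= max_pos)
    removed = [ds.locus_ids[i] for i in np.flatnonzero(pos > max_pos)]
    return ds.subset_loci(keep), removed


def select_one_snp_per_tag(
    ds: GenotypeDataset, fst_per_locus: Mapping[str, float]
) -> tuple[GenotypeDataset, list[str]]:
    """Keep, per RAD tag, only the SNP with the highest overall theta.

    Exact theta ties break to the lowest tag position, then lexicographic
    locus ID, so the result is invariant under input permutation. Loci with
    undefined theta rank below every defined value.
    """
    best: dict[str, int] = {}
    for j, loc in enumerate(ds.loci):
        f = fst_per_locus.get(loc.locus_id, np.nan)
        key = (-(f if not (f is None or np.isnan(f)) else -np.inf), loc.tag_position, loc.locus_id)
        if loc.tag_id not in best or key < best[loc.tag_id][0]:
            best[loc.tag_id] = (key, j)
    keep = sorted(j for _, j in best.values())
    keep_set = set(keep)
    removed = [ds.locus_ids[j] for j in range(ds.n_loci) if j not in keep_set]
    return ds.subset_loci(keep), removed


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_log_probs(n_A: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Log probabilities of each possible heterozygote count given allele counts.

    Conditional on ``n`` diploids and ``n_A`` copies of allele A, the exact
    distribution of the heterozygote count under random mating is

        P(n_Aa) = n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa * n_A! n_a! / (2n)!
    """
    n_a = 2 * n - n_A
    max_het = min(n_A, n_a)
    hets = np.arange(n_A % 2, max_het + 1, 2)
    n_AA = (n_A - hets) // 2
    n_aa = (n_a - hets) // 2
    lg = math.lgamma
    base = lg(n + 1) + lg(n_A + 1) + lg(n_a + 1) - lg(2 * n + 1)
    logp = np.array(
        [
            base + h * math.log(2) - lg(aa + 1) - lg(h + 1) - lg(bb + 1)
            for h, aa, bb in zip(hets, n_AA, n_aa)
        ]
    )
    return hets, logp


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for a biallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (with a tiny relative tolerance so exact ties survive
    floating-point rounding).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_A = 2 * n_AA + n_Aa
    hets, logp = _hwe_log_probs(n_A, n)
    obs = np.flatnonzero(hets == n_Aa)[0]
    include = logp <= logp[obs] + 1e-9
    # normalize in probability space for numerical robustness
    m = logp.max()
    probs = np.exp(logp - m)
    return float(min(1.0, probs[include].sum() / probs.sum()))


def filter_hwe(
    ds: GenotypeDataset, alpha: float = 0.05, min_pops: int = 3
) -> tuple[GenotypeDataset, list[str]]:
    """Remove loci out of Hardy-Weinberg equilibrium in >= min_pops populations.

    Exact p-values are computed per population on non-missing genotypes;
    a population with no genotyped individuals at a locus is excluded from
    that locus's tally.
    """
    idx = ds.pop_indices()
    cache: dict[tuple[int, int, int], float] = {}
    n_signif = np.zeros(ds.n_loci, dtype=int)
    for rows in idx.values():
        sub = ds.dosage[rows]
        called = ~np.isnan(sub)
        n_aa = ((sub == 0) & called).sum(axis=0)
        n_het = ((sub == 1) & called).sum(axis=0)
        n_AA = ((sub == 2) & called).sum(axis=0)
        for j in range(ds.n_loci):
            counts = (int(n_AA[j]), int(n_het[j]), int(n_aa[j]))
            if sum(counts) == 0:
                continue
            p = cache.get(counts)
            if p is None:
                p = hwe_exact_pvalue(*counts)
                cache[counts] = p
            if p < alpha:
                n_signif[j] += 1
    keep = np.flatnonzero(n_signif < min_pops)
    removed = [ds.locus_ids[j] for j in np.flatnonzero(n_signif >= min_pops)]
    return ds.subset_loci(keep), removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _r2_matrix(dosage: np.ndarray, called: np.ndarray):
    """All-pairs genotypic r^2 with pairwise-complete observations.

    Returns (r2, n) matrices; r2 is NaN where fewer than 2 co-genotyped
    individuals or zero variance at either locus.
    """
    M = called.astype(float)
    X = np.where(called, dosage, 0.0)
    n = M.T @ M
    sx = X.T @ M  # sx[a, b] = sum of dosage_a over individuals called at both
    sxy = X.T @ X
    sxx = (X**2).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_a = sxx - sx**2 / n
        var_b = var_a.T
        r2 = cov**2 / (var_a * var_b)
    r2[(n < 2) | (var_a <= 1e-12) | (var_b <= 1e-12)] = np.nan
    return r2, n


def pairwise_r2(ds: GenotypeDataset, pop: str, locus_a: str, locus_b: str) -> float:
    """Squared dosage correlation between two loci within one population.

    Computed over individuals genotyped at both loci; undefined (NaN) when
    fewer than two such individuals exist or either locus has zero variance
    among them.
    """
    rows = ds.pop_indices()[pop]
    li = ds.locus_index()
    a, b = li[locus_a], li[locus_b]
    da, db = ds.dosage[rows, a], ds.dosage[rows, b]
    both = ~np.isnan(da) & ~np.isnan(db)
    if both.sum() < 2:
        logger.info("pair (%s, %s) in %s: <2 co-genotyped individuals", locus_a, locus_b, pop)
        return np.nan
    da, db = da[both], db[both]
    va, vb = da.var(), db.var()
    if va <= 1e-12 or vb <= 1e-12:
        logger.info("pair (%s, %s) in %s: zero variance", locus_a, locus_b, pop)
        return np.nan
    cov = ((da - da.mean()) * (db - db.mean())).mean()
    return float(cov**2 / (va * vb))


def ld_prune(
    ds: GenotypeDataset, r2_threshold: float = 0.8, min_pops: int = 3
) -> tuple[GenotypeDataset, list[str]]:
    """Remove one locus from each strongly linked pair.

    A pair offends when its genotypic r^2 exceeds ``r2_threshold`` in at
    least ``min_pops`` populations. Offending pairs are processed in
    deterministic order (descending maximum r^2 across populations, then
    locus IDs); for each pair still intact, the locus genotyped in fewer
    individuals is removed (call-rate tie: the lexicographically later ID).
    """
    labels = ds.pop_labels()
    idx = ds.pop_indices()
    L = ds.n_loci
    count_over = np.zeros((L, L), dtype=int)
    max_r2 = np.full((L, L), -np.inf)
    for p in labels:
        rows = idx[p]
        r2, _ = _r2_matrix(ds.dosage[rows], ds.called[rows])
        over = np.where(np.isnan(r2), False, r2 > r2_threshold)
        count_over += over
        max_r2 = np.fmax(max_r2, np.where(np.isnan(r2), -np.inf, r2))

    ia, ib = np.triu_indices(L, k=1)
    offend = count_over[ia, ib] >= min_pops
    pairs = sorted(
        zip(ia[offend], ib[offend]),
        key=lambda ab: (-max_r2[ab[0], ab[1]], ds.locus_ids[ab[0]], ds.locus_ids[ab[1]]),
    )
    call_n = ds.called.sum(axis=0)
    removed_idx: set[int] = set()
    for a, b in pairs:
        if a in removed_idx or b in removed_idx:
            continue
        if call_n[a] < call_n[b]:
            victim = a
        elif call_n[b] < call_n[a]:
            victim = b
        else:
            victim = a if ds.locus_ids[a] > ds.locus_ids[b] else b
        removed_idx.add(victim)
    keep = [j for j in range(L) if j not in removed_idx]
    removed = [ds.locus_ids[j] for j in sorted(removed_idx)]
    return ds.subset_loci(keep), removed


# ---------------------------------------------------------------------------
# Paralog screen, individuals, duplicates
# ---------------------------------------------------------------------------

def detect_psv(panel: HaploidPanel, het_threshold: float = 0.10) -> list[str]:
    """Flag loci whose haploid heterozygous-call fraction exceeds threshold."""
    het = panel.het_fraction()
    flagged = np.where(np.isnan(het), False, het > het_threshold)
    return [panel.locus_ids[j] for j in np.flatnonzero(flagged)]


def filter_psv(
    ds: GenotypeDataset, panel: HaploidPanel, het_threshold: float = 0.10
) -> tuple[GenotypeDataset, list[str]]:
    flagged = set(detect_psv(panel, het_threshold)) & set(ds.locus_ids)
    removed = sorted(flagged)
    return ds.drop_loci(removed), removed


def filter_individual_missingness(
    ds: GenotypeDataset, max_missing: float = 0.15
) -> tuple[GenotypeDataset, list[str]]:
    """Remove individuals missing more than ``max_missing`` of their genotypes."""
    miss = ds.individual_missing_rate()
    keep = np.flatnonzero(miss <= max_missing)
    removed = [ds.individuals[i] for i in np.flatnonzero(miss > max_missing)]
    if keep.size == 0:
        raise ValueError("individual-missingness filter would remove every individual")
    return ds.subset_individuals(keep), removed


def relatedness_R(ds: GenotypeDataset, ind_i: str, ind_j: str) -> float:
    """Identity-based relatedness: R = 2 * (mean IBS allele sharing) - 1.

    IBS sharing per co-genotyped locus is (2 - |d_i - d_j|)/2, so R reduces
    to ``1 - mean|d_i - d_j|``: 1 for identical genotype vectors, -1 for
    opposite homozygotes everywhere. This is a simple deterministic identity
    statistic, not a maximum-likelihood relatedness estimate; its role here
    is duplicate detection, for which identity is the signal of interest.
    """
    a = ds.dosage[ds.individuals.index(ind_i)]
    b = ds.dosage[ds.individuals.index(ind_j)]
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        raise ValueError(f"individuals {ind_i} and {ind_j} share no genotyped loci")
    return float(1.0 - np.abs(a[both] - b[both]).mean())


def find_duplicates(
    ds: GenotypeDataset, r_threshold: float = 0.9
) -> list[tuple[str, str, float, str]]:
    """Flag all individual pairs with R above threshold.

    Returns (ind_a, ind_b, R, marked_for_removal) tuples; the member with
    the lower call rate is marked (tie: the lexicographically later ID).
    """
    D = ds.dosage
    called = ds.called
    call_n = called.sum(axis=1)
    out = []
    for i in range(ds.n_individuals):
        di = D[i]
        ci = called[i]
        both = ci & called[i + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = np.abs(np.where(both, D[i + 1 :] - di, 0.0)).sum(axis=1)
            n_both = both.sum(axis=1)
            r = 1.0 - diff / n_both
        for k in np.flatnonzero((n_both > 0) & (r > r_threshold)):
            j = i + 1 + k
            if call_n[i] < call_n[j]:
                victim = ds.individuals[i]
            elif call_n[j] < call_n[i]:
                victim = ds.individuals[j]
            else:
                victim = max(ds.individuals[i], ds.individuals[j])
            out.append((ds.individuals[i], ds.individuals[j], float(r[k]), victim))
    return out


def filter_duplicates(
    ds: GenotypeDataset, r_threshold: float = 0.9
) -> tuple[GenotypeDataset, list[str]]:
    victims = sorted({v for _, _, _, v in find_duplicates(ds, r_threshold)})
    return ds.drop_individuals(victims), victims


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

DEFAULT_CASCADE: list[tuple[str, dict]] = [
    ("call_rate", {"min_rate": 0.8}),
    ("tag_position", {"max_pos": 87}),
    ("one_per_tag", {}),
    ("maf", {"threshold": 0.05}),
    ("psv", {"het_threshold": 0.10}),
    ("hwe", {"alpha": 0.05, "min_pops": 3}),
    ("ld", {"r2_threshold": 0.8, "min_pops": 3}),
    ("individual_missingness", {"max_missing": 0.15}),
    ("duplicates", {"r_threshold": 0.9}),
]


def run_cascade(
    ds: GenotypeDataset,
    haploid_panel: HaploidPanel | None = None,
    config: Sequence[tuple[str, dict]] | None = None,
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the filter steps in order and return the audit report.

    ``config`` is an ordered list of (rule, params); the default follows the
    order in which the filters are usually narrated for RAD data: call rate,
    tag position, one SNP per tag, MAF, paralog screen, HWE, LD pruning,
    individual missingness, duplicates. Steps that need absent inputs (the
    paralog screen without a haploid panel; per-tag selection or HWE with a
    single population where theta is undefined) are skipped with a log
    message. Re-running the cascade on its own output removes nothing.
    """
    if config is None:
        config = DEFAULT_CASCADE
    report = FilterReport()
    current = ds
    for rule, params in config:
        before = current
        if rule == "call_rate":
            current, _ = filter_call_rate(current, **params)
        elif rule == "tag_position":
            current, _ = filter_tag_position(current, **params)
        elif rule == "one_per_tag":
            if len(current.pop_labels()) < 2:
                logger.warning("one_per_tag skipped: theta undefined with <2 populations")
                continue
            fst = popstruct.wc_theta(current)
            theta = dict(zip(fst.locus_ids, fst.theta_per_locus))
            current, _ = select_one_snp_per_tag(current, theta)
        elif rule == "maf":
            current, _ = filter_maf(current, **params)
        elif rule == "psv":
            if haploid_panel is None:
                logger.warning("psv step skipped: no haploid panel supplied")
                continue
            current, _ = filter_psv(current, haploid_panel, **params)
        elif rule == "hwe":
            current, _ = filter_hwe(current, **params)
        elif rule == "ld":
            current, _ = ld_prune(current, **params)
        elif rule == "individual_missingness":
            current, _ = filter_individual_missingness(current, **params)
        elif rule == "duplicates":
            current, _ = filter_duplicates(current, **params)
        else:
            raise ValueError(f"unknown filter rule '{rule}'")
        report.add(rule, params, before, current)
    return current, report
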