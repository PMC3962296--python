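"""Population-structure statistics.

Implements the Weir-Cockerham unbiased F_ST estimator (theta) with its
variance components, observed/expected heterozygosities, a permutation test
of pairwise differentiation, hierarchical AMOVA on allele copies, PCA of
individual dosages with a column-permutation significance test, and an
empirical-quantile F_ST outlier flagger.

Theta follows the standard two-allele weighted analysis of variance with
unequal sample sizes: per locus the among-population (a), among-individual
(b), and within-individual (c) components are estimated, and multi-locus
theta is the ratio of sums sum(a) / sum(a+b+c). Negative components and
negative theta are reported as computed; truncation would bias downstream
ratio-of-sums summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from radpopgen.genio import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class FstTable:
    """Per-locus Weir-Cockerham variance components and theta."""

    locus_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    pops: list[str]

    @property
    def theta_per_locus(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)

    @property
    def theta_multilocus(self) -> float:
        a = np.nansum(self.a)
        total = np.nansum(self.a + self.b + self.c)
        if total == 0:
            return np.nan
        return float(a / total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "theta": self.theta_per_locus,
            }
        )


@dataclass
class HetResult:
    """Observed and expected heterozygosity per population."""

    pops: list[str]
    ho_per_locus: np.ndarray  # (n_pops, n_loci), NaN where no data
    he_per_locus: np.ndarray
    ho: np.ndarray  # per-population means over loci
    he: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"population": self.pops, "H_O": self.ho, "H_E": self.he})


@dataclass
class AmovaResult:
    """Nested variance decomposition over allele copies.

    Strata: among groups, among populations within groups, within
    populations. Negative components are retained as computed.
    """

    sigma2_among_groups: float
    sigma2_among_pops: float
    sigma2_within_pops: float
    df_among_groups: int
    df_among_pops: int
    df_within_pops: int

    @property
    def percentages(self) -> tuple[float, float, float]:
        total = self.sigma2_among_groups + self.sigma2_among_pops + self.sigma2_within_pops
        return (
            100.0 * self.sigma2_among_groups / total,
            100.0 * self.sigma2_among_pops / total,
            100.0 * self.sigma2_within_pops / total,
        )

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "source": [
                    "among_groups",
                    "among_populations_within_groups",
                    "within_populations",
                ],
                "df": [self.df_among_groups, self.df_among_pops, self.df_within_pops],
                "variance_component": [
                    self.sigma2_among_groups,
                    self.sigma2_among_pops,
                    self.sigma2_within_pops,
                ],
                "percent_of_total": list(pct),
            }
        )


@dataclass
class PcaResult:
    """Individual PCA with column-permutation eigenvalue significance."""

    scores: np.ndarray  # (n_individuals, n_axes)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportions: np.ndarray  # eigenvalues / sum, sums to 1
    p_values: np.ndarray  # per reported axis


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------

def _pop_locus_counts(
    dosage: np.ndarray, called: np.ndarray, pop_rows: Sequence[np.ndarray]
):
    """Per (population, locus): genotyped count, ref-allele sum, het count."""
    n = np.stack([called[rows].sum(axis=0) for rows in pop_rows]).astype(float)
    d0 = np.where(called, dosage, 0.0)
    x = np.stack([d0[rows].sum(axis=0) for rows in pop_rows])
    het = np.stack(
        [((dosage[rows] == 1) & called[rows]).sum(axis=0) for rows in pop_rows]
    ).astype(float)
    return n, x, het


def _wc_components(n: np.ndarray, x: np.ndarray, het: np.ndarray):
    """Vectorized Weir-Cockerham a, b, c per locus.

    ``n``, ``x``, ``het`` are (n_pops, n_loci): genotyped individuals,
    reference-allele counts, heterozygote counts. Loci with fewer than two
    populations containing data, or with mean sample size <= 1, get NaN
    components.
    """
    present = n > 0
    r = present.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.sum(axis=0) / r
        sum_n2 = (n**2).sum(axis=0)
        nc = (r * nbar - sum_n2 / (r * nbar)) / (r - 1)
        p = np.where(present, x / np.maximum(2 * n, 1), 0.0)
        pbar = x.sum(axis=0) / (2 * r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = het.sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def wc_theta(ds: GenotypeDataset, pops: Sequence[str] | None = None) -> FstTable:
    """Weir-Cockerham theta for the chosen populations (default: all)."""
    if pops is None:
        pops = ds.pop_labels()
    pops = list(pops)
    if len(pops) < 2:
        raise ValueError("wc_theta needs at least 2 populations")
    idx = ds.pop_indices()
    rows = [idx[p] for p in pops]
    n, x, het = _pop_locus_counts(ds.dosage, ds.called, rows)
    a, b, c = _wc_components(n, x, het)
    return FstTable(locus_ids=ds.locus_ids, a=a, b=b, c=c, pops=pops)


def _multilocus_theta_from_counts(n, x, het) -> float:
    a, b, c = _wc_components(n, x, het)
    total = np.nansum(a + b + c)
    if total == 0:
        return np.nan
    return float(np.nansum(a) / total)


def pairwise_fst_matrix(ds: GenotypeDataset) -> pd.DataFrame:
    """Symmetric matrix of multi-locus pairwise theta; NaN diagonal."""
    labels = ds.pop_labels()
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, pi in enumerate(labels):
        for pj in labels[i + 1 :]:
            theta = wc_theta(ds, [pi, pj]).theta_multilocus
            mat.loc[pi, pj] = theta
            mat.loc[pj, pi] = theta
    return mat


def differentiation_test(
    ds: GenotypeDataset,
    pop_i: str,
    pop_j: str,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Permutation test of differentiation between two populations.

    Individuals are shuffled between the two populations, multi-locus theta
    is recomputed for each permutation, and the add-one p-value
    ``(1 + #{theta_perm >= theta_obs}) / (n_perm + 1)`` is returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sub = ds.subset_populations([pop_i, pop_j])
    dosage, called = sub.dosage, sub.called
    pops = np.asarray(sub.populations)
    rows_i = np.flatnonzero(pops == pop_i)
    rows_j = np.flatnonzero(pops == pop_j)
    n_i = rows_i.size

    def theta_for(rows_a, rows_b):
        n, x, het = _pop_locus_counts(dosage, called, [rows_a, rows_b])
        return _multilocus_theta_from_counts(n, x, het)

    obs = theta_for(rows_i, rows_j)
    rng = np.random.default_rng(seed)
    all_rows = np.arange(dosage.shape[0])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_rows)
        t = theta_for(perm[:n_i], perm[n_i:])
        if not np.isnan(t) and t >= obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity(ds: GenotypeDataset) -> HetResult:
    """Observed and expected heterozygosity per population.

    H_O is the heterozygote fraction among genotyped individuals; H_E is
    ``1 - p^2 - q^2`` from the per-population allele frequency. Loci with no
    genotyped individual in a population are skipped for that population.
    """
    labels = ds.pop_labels()
    idx = ds.pop_indices()
    rows = [idx[p] for p in labels]
    n, x, het = _pop_locus_counts(ds.dosage, ds.called, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        p = np.where(n > 0, x / np.maximum(2 * n, 1), np.nan)
        he = 1.0 - p**2 - (1.0 - p) ** 2
        he = np.where(n > 0, he, np.nan)
    return HetResult(
        pops=labels,
        ho_per_locus=ho,
        he_per_locus=he,
        ho=np.nanmean(ho, axis=1),
        he=np.nanmean(he, axis=1),
    )


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------

def amova(ds: GenotypeDataset, hierarchy: Mapping[str, Sequence[str]]) -> AmovaResult:
    """Hierarchical AMOVA over allele copies (groups / populations / within).

    ``hierarchy`` maps group labels to the populations they contain; every
    dataset population must belong to exactly one group and every group must
    be non-empty. Each individual contributes two allele copies; the distance
    between copies is allele mismatch, so per locus the analysis is a nested
    ANOVA on 0/1 allele indicators with unequal cell sizes. Variance
    components are computed locus by locus and summed before forming
    percentages; negative components are retained. The within-individual
    (inbreeding) stratum is not modelled: allele copies within a population
    are exchangeable.
    """
    labels = ds.pop_labels()
    assigned: dict[str, str] = {}
    for g, pops in hierarchy.items():
        if len(pops) == 0:
            raise ValueError(f"group '{g}' contains no populations")
        for p in pops:
            if p in assigned:
                raise ValueError(f"population '{p}' assigned to multiple groups")
            assigned[p] = g
    missing = [p for p in labels if p not in assigned]
    if missing:
        raise ValueError(f"populations not assigned to any group: {missing}")

    groups = list(hierarchy)
    idx = ds.pop_indices()
    # per (pop, locus) allele-copy counts and ref sums
    pop_order = [p for g in groups for p in hierarchy[g]]
    group_of = np.array([groups.index(assigned[p]) for p in pop_order])
    rows = [idx[p] for p in pop_order]
    n, x, _ = _pop_locus_counts(ds.dosage, ds.called, rows)
    m = 2 * n  # allele copies per pop per locus
    s = x

    G = len(groups)
    P = len(pop_order)
    if G < 1:
        raise ValueError("hierarchy must contain at least one group")

    # group-level totals per locus
    Mg = np.stack([m[group_of == g].sum(axis=0) for g in range(G)])
    Sg = np.stack([s[group_of == g].sum(axis=0) for g in range(G)])
    M = m.sum(axis=0)
    S = s.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        ss_within = (s - s**2 / np.where(m > 0, m, np.nan)).sum(axis=0)
        sum_s2m = np.where(m > 0, s**2 / np.where(m > 0, m, 1), 0.0)
        per_group_s2m = np.stack([sum_s2m[group_of == g].sum(axis=0) for g in range(G)])
        with_g = np.where(Mg > 0, Sg**2 / np.where(Mg > 0, Mg, 1), 0.0)
        ss_pops = (per_group_s2m - with_g).sum(axis=0)
        ss_groups = with_g.sum(axis=0) - S**2 / M

        df_c = M - P
        df_b = float(P - G)
        df_a = float(G - 1)

        sum_m2_within_g = np.stack(
            [(m[group_of == g] ** 2).sum(axis=0) for g in range(G)]
        )
        n_prime = (M - (sum_m2_within_g / np.where(Mg > 0, Mg, np.nan)).sum(axis=0)) / df_b
        ms_c = ss_within / df_c
        ms_b = ss_pops / df_b
        sigma_c = ms_c
        sigma_b = (ms_b - ms_c) / n_prime
        if G > 1:
            n_dprime = (
                (sum_m2_within_g / np.where(Mg > 0, Mg, np.nan)).sum(axis=0)
                - (m**2).sum(axis=0) / M
            ) / df_a
            n_tprime = (M - (Mg**2).sum(axis=0) / M) / df_a
            ms_a = ss_groups / df_a
            sigma_a = (ms_a - sigma_c - n_dprime * sigma_b) / n_tprime
        else:
            sigma_a = np.zeros_like(sigma_b)

    ok = np.isfinite(sigma_b) & np.isfinite(sigma_c) & np.isfinite(sigma_a)
    if not ok.any():
        raise ValueError("no locus provides a complete AMOVA decomposition")
    n_copies = int(2 * ds.n_individuals)
    return AmovaResult(
        sigma2_among_groups=float(sigma_a[ok].sum()),
        sigma2_among_pops=float(sigma_b[ok].sum()),
        sigma2_within_pops=float(sigma_c[ok].sum()),
        df_among_groups=G - 1,
        df_among_pops=P - G,
        df_within_pops=n_copies - P,
    )


# ---------------------------------------------------------------------------
# PCA with permutation significance
# ---------------------------------------------------------------------------

def pca(
    ds: GenotypeDataset,
    n_axes: int = 2,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PcaResult:
    """PCA of the individual dosage matrix with a permutation null.

    Loci are centred by mean dosage; missing genotypes are imputed with the
    locus mean (so they are neutral after centring). No per-locus variance
    scaling is applied. The null permutes each locus column independently,
    destroying between-locus correlation while preserving marginal
    frequencies; per-axis p-values compare observed eigenvalues to the
    permuted ones with the add-one estimator.
    """
    if ds.n_individuals < 2:
        raise ValueError("pca needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    X = ds.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_rows, nan_cols = np.where(np.isnan(X))
    X[nan_rows, nan_cols] = col_mean[nan_cols]

    def eigvals(mat: np.ndarray) -> np.ndarray:
        centred = mat - mat.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        return svals**2 / (mat.shape[0] - 1)

    centred = X - X.mean(axis=0)
    U, svals, _ = np.linalg.svd(centred, full_matrices=False)
    lam = svals**2 / (X.shape[0] - 1)
    n_axes = min(n_axes, lam.size)
    scores = U[:, :n_axes] * svals[:n_axes]

    exceed = np.zeros(n_axes, dtype=int)
    for _ in range(n_perm):
        perm = rng.permuted(X, axis=0)  # each locus column shuffled independently
        lam_p = eigvals(perm)
        exceed += lam_p[:n_axes] >= lam[:n_axes]
    p_values = (1 + exceed) / (n_perm + 1)
    total = lam.sum()
    return PcaResult(
        scores=scores,
        eigenvalues=lam,
        proportions=lam / total if total > 0 else lam,
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Empirical-quantile outlier flagging
# ---------------------------------------------------------------------------

def flag_fst_outliers_quantile(fst_table: FstTable, q: float = 0.95) -> list[str]:
    """Flag loci in the upper tail of the empirical per-locus theta distribution.

    This is a deliberate, clearly labelled empirical stand-in for
    coalescent-simulation outlier tests: it flags the top ``floor(n*(1-q))``
    loci by per-locus theta (ties broken by locus ID), so by construction
    about ``1-q`` of loci are flagged. It makes no statement about a neutral
    null model.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    theta = fst_table.theta_per_locus
    usable = np.flatnonzero(~np.isnan(theta))
    if usable.size < 20:
        raise ValueError("need at least 20 loci with defined theta")
    k = int(np.floor(usable.size * (1 - q)))
    if k == 0:
        return []
    order = sorted(usable, key=lambda i: (-theta[i], fst_table.locus_ids[i]))
    return [fst_table.locus_ids[i] for i in order[:k]]
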