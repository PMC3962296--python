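"""Bayesian individual assignment with leave-one-out cross-validation.

Each candidate population's allele frequencies are summarised by the
posterior mean under a uniform Dirichlet prior (the Rannala-Mountain
baseline): with x copies of an allele among n sampled gene copies and k
alleles at the locus, the posterior-mean frequency is (x + 1/k) / (n + 1).
An individual's log-likelihood in a population is the sum over its
non-missing loci of the Hardy-Weinberg genotype probability at those
frequencies (p^2, 2pq, or q^2). For leave-one-out evaluation an
individual's own two allele copies per locus are subtracted from its home
population's counts before its likelihood there is computed, so no
individual ever informs its own baseline.

Assignment is the argmax over populations of the log-likelihood; exact ties
leave the individual unassigned rather than picking arbitrarily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from radpopgen.genio import GenotypeDataset
from radpopgen import popstruct

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


def posterior_freq(x: float, n: float, k: int = 2) -> float:
    """Posterior-mean allele frequency under the uniform Dirichlet prior."""
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    return (x + 1.0 / k) / (n + 1.0)


@dataclass
class AssignmentResult:
    individuals: list[str]
    origin: list[str]
    pops: list[str]
    log_likelihood: np.ndarray  # (n_individuals, n_pops)
    assigned: list[str | None]  # None = unassigned (tie or no data)

    @property
    def correct(self) -> np.ndarray:
        return np.array([a == o for a, o in zip(self.assigned, self.origin)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.log_likelihood, columns=[f"loglik_{p}" for p in self.pops]
        )
        df.insert(0, "individual", self.individuals)
        df.insert(1, "origin", self.origin)
        df.insert(2, "assigned", [a if a is not None else "unassigned" for a in self.assigned])
        df.insert(3, "correct", self.correct)
        return df


def genotype_loglik(dosage_row: np.ndarray, x: np.ndarray, n: np.ndarray) -> float:
    """Log-likelihood of one individual's genotypes given baseline counts.

    ``x`` and ``n`` are per-locus reference-allele and total-allele counts of
    the baseline population. Missing genotypes contribute nothing. Because
    the Dirichlet-smoothed frequencies are strictly inside (0, 1), an allele
    unseen in the baseline still has finite log-probability.
    """
    called = ~np.isnan(dosage_row)
    if not called.any():
        return np.nan
    d = dosage_row[called]
    p = (x[called] + 0.5) / (n[called] + 1.0)
    ll = d * np.log(p) + (2.0 - d) * np.log1p(-p) + (d == 1) * LN2
    return float(ll.sum())


def leave_one_out_assign(ds: GenotypeDataset) -> AssignmentResult:
    """Assign every individual after removing it from its own baseline.

    Deterministic: no randomness enters. Every population needs at least two
    individuals so the leave-one-out baseline is never empty. Individuals
    with zero genotyped loci are reported unassigned.
    """
    pops = ds.pop_labels()
    idx = ds.pop_indices()
    for p in pops:
        if idx[p].size < 2:
            raise ValueError(f"population '{p}' has fewer than 2 individuals")
    dosage, called = ds.dosage, ds.called
    n_ind = ds.n_individuals

    # per-population allele counts per locus
    x_pop = np.stack(
        [np.where(called[idx[p]], dosage[idx[p]], 0.0).sum(axis=0) for p in pops]
    )
    n_pop = np.stack([2.0 * called[idx[p]].sum(axis=0) for p in pops])

    d0 = np.where(called, dosage, 0.0)
    ll = np.empty((n_ind, len(pops)))
    pop_of = {p: k for k, p in enumerate(pops)}
    for k in range(len(pops)):
        p = (x_pop[k] + 0.5) / (n_pop[k] + 1.0)
        lp, lq = np.log(p), np.log1p(-p)
        ll[:, k] = d0 @ lp + (np.where(called, 2.0 - dosage, 0.0)) @ lq + (
            (dosage == 1) & called
        ) @ np.full(ds.n_loci, LN2)
    # replace home-population column with the leave-one-out value
    for i in range(n_ind):
        k = pop_of[ds.populations[i]]
        x_loo = x_pop[k] - d0[i]
        n_loo = n_pop[k] - 2.0 * called[i]
        ll[i, k] = genotype_loglik(dosage[i], x_loo, n_loo)

    assigned: list[str | None] = []
    for i in range(n_ind):
        row = ll[i]
        if np.isnan(row).all():
            assigned.append(None)
            logger.warning("individual %s has no genotyped loci; unassigned", ds.individuals[i])
            continue
        best = np.nanmax(row)
        winners = np.flatnonzero(row == best)
        if winners.size != 1:
            assigned.append(None)
            logger.info("individual %s: log-likelihood tie; unassigned", ds.individuals[i])
        else:
            assigned.append(pops[winners[0]])
    return AssignmentResult(
        individuals=list(ds.individuals),
        origin=list(ds.populations),
        pops=pops,
        log_likelihood=ll,
        assigned=assigned,
    )


def accuracy_table(result: AssignmentResult) -> pd.DataFrame:
    """Percent correctly assigned per origin population."""
    rows = []
    origin = np.asarray(result.origin)
    correct = result.correct
    for p in result.pops:
        mask = origin == p
        n = int(mask.sum())
        n_correct = int(correct[mask].sum())
        rows.append(
            {
                "population": p,
                "n": n,
                "n_correct": n_correct,
                "percent_correct": 100.0 * n_correct / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
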