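"""Synthetic genotype datasets with the structure the analyses assume.

Two generators cover the two signals the pipeline estimates:

* :func:`simulate_island_genotypes` draws hierarchically structured allele
  frequencies from the Balding-Nichols model (population frequencies are
  Beta-distributed around an ancestral frequency with E[F_ST] equal to the
  target), then genotypes binomially. It produces realistic levels of
  differentiation but no drift linkage disequilibrium, so LD-based Ne
  estimates on it are essentially infinite.
* :func:`simulate_wf_genotypes` runs a forward Wright-Fisher population of
  known size with per-linkage-group gamete dropping and Haldane
  recombination, producing the drift LD that the Ne estimator consumes and
  elevated LD between physically close loci.

:func:`inject_artifacts` plants the defect classes the QC cascade removes
(paralog-contaminated loci, 3'-end error SNPs, duplicated individuals) and
returns a truth record so filter sensitivity/specificity can be scored.

These generators are test scaffolding: the study they emulate analysed real
fish, and none of the generator choices below are claims about that data.
Defaults mirror the study conditions (five populations of 47-57 diploids,
hierarchical F_ST around 0.04 overall, a 34-linkage-group map spanning
27.75-160.23 cM, SNPs at tag positions 1-93).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from radpopgen.genio import (
    HAP_ALT,
    HAP_HET,
    HAP_MISSING,
    HAP_REF,
    GenotypeDataset,
    HaploidPanel,
    LocusInfo,
)

logger = logging.getLogger(__name__)

# study-scale defaults: five populations, sample sizes as sampled in the field
_DEFAULT_POPS = ("pop1", "pop2", "pop3", "pop4", "pop5")
_DEFAULT_SAMPLES = (56, 54, 57, 56, 47)
_DEFAULT_GROUPS = {
    "coastal": ["pop1", "pop2", "pop3"],
    "norton": ["pop4"],
    "upper_yukon": ["pop5"],
}
# 34 linkage groups; lengths interpolate the observed range 27.75-160.23 cM
N_LINKAGE_GROUPS = 34
LG_MIN_CM = 27.75
LG_MAX_CM = 160.23


def haldane_c(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from map distance via Haldane's map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw subpopulation frequencies around ancestral ``p`` with E[F_ST]=F."""
    if F == 0.0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


@dataclass
class SimConfig:
    """Configuration of the hierarchical island-model generator.

    ``target_fst`` gives the Balding-Nichols F at each hierarchy level:
    ancestral -> group ("group") and group -> population ("pop"). F values
    must lie in [0, 1); 0 short-circuits to copying the parent frequency.
    """

    n_pops: int = 5
    samples_per_pop: Sequence[int] = _DEFAULT_SAMPLES
    n_loci: int = 10944
    group_assignment: Mapping[str, Sequence[str]] | None = None
    target_fst: Mapping[str, float] = field(
        default_factory=lambda: {"group": 0.05, "pop": 0.005}
    )
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length must equal n_pops")
        if any(s < 2 for s in self.samples_per_pop):
            raise ValueError("each population needs >= 2 samples")
        for level, f in self.target_fst.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"target_fst[{level!r}]={f} outside [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def pop_names(self) -> list[str]:
        if self.group_assignment is not None:
            return [p for pops in self.group_assignment.values() for p in pops]
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    def groups(self) -> Mapping[str, Sequence[str]]:
        if self.group_assignment is not None:
            return self.group_assignment
        if self.n_pops == 5:
            return _DEFAULT_GROUPS
        return {"all": self.pop_names()}


def simulate_island_genotypes(cfg: SimConfig) -> GenotypeDataset:
    """Generate genotypes under the hierarchical Balding-Nichols island model.

    Per locus: ancestral frequency from Uniform(maf_low, maf_high), a group
    frequency drawn around it with F = target_fst["group"], a population
    frequency drawn around the group's with F = target_fst["pop"], genotypes
    Binomial(2, p_pop), and i.i.d. missingness.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = cfg.pop_names()
    if len(pops) != cfg.n_pops:
        raise ValueError("group_assignment population count != n_pops")
    groups = cfg.groups()
    group_of = {p: g for g, ps in groups.items() for p in ps}
    L = cfg.n_loci
    p_anc = rng.uniform(cfg.maf_low, cfg.maf_high, size=L)
    p_group = {g: _balding_nichols(rng, p_anc, cfg.target_fst.get("group", 0.0)) for g in groups}
    f_pop = cfg.target_fst.get("pop", 0.0)

    dosage_blocks = []
    labels: list[str] = []
    individuals: list[str] = []
    for p, n_s in zip(pops, cfg.samples_per_pop):
        p_pop = _balding_nichols(rng, p_group[group_of[p]], f_pop)
        block = rng.binomial(2, p_pop, size=(n_s, L)).astype(float)
        dosage_blocks.append(block)
        labels.extend([p] * n_s)
        individuals.extend(f"{p}_ind{j + 1}" for j in range(n_s))
    dosage = np.vstack(dosage_blocks)
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = np.nan

    tag_pos = rng.integers(1, 88, size=L)
    loci = [
        LocusInfo(locus_id=f"tag{l + 1}_{tag_pos[l]}", tag_id=f"tag{l + 1}",
                  tag_position=int(tag_pos[l]))
        for l in range(L)
    ]
    return GenotypeDataset(
        individuals=individuals, populations=labels, dosage=dosage, loci=loci
    )


def simulate_linkage_map(
    locus_ids: Sequence[str],
    n_lgs: int = N_LINKAGE_GROUPS,
    seed: int = 0,
    fraction_mapped: float = 1.0,
) -> dict[str, tuple[int, float]]:
    """Assign loci random positions on a multi-linkage-group map.

    Linkage-group lengths interpolate linearly between the shortest and
    longest groups of the reference map (27.75 and 160.23 cM).
    """
    rng = np.random.default_rng(seed)
    lengths = np.linspace(LG_MIN_CM, LG_MAX_CM, n_lgs)
    mapping = {}
    for lid in locus_ids:
        if rng.random() > fraction_mapped:
            continue
        lg = int(rng.integers(0, n_lgs))
        mapping[lid] = (lg + 1, float(np.round(rng.uniform(0, lengths[lg]), 3)))
    return mapping


# ---------------------------------------------------------------------------
# Forward Wright-Fisher with recombination
# ---------------------------------------------------------------------------

@dataclass
class WFConfig:
    """Forward Wright-Fisher simulation with a known true Ne.

    ``loci_map`` gives (linkage_group, cM) per locus; ``None`` means every
    locus on its own linkage group (fully unlinked). Recombination between
    adjacent mapped loci follows Haldane's map function of the cM gap;
    loci on different linkage groups assort independently (c = 0.5).
    """

    true_Ne: int = 100
    n_generations: int = 30
    sample_size: int = 50
    n_loci: int = 200
    loci_map: Sequence[tuple[int, float]] | None = None
    p0_low: float = 0.2
    p0_high: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_Ne < 2:
            raise ValueError("true_Ne must be >= 2")
        if self.sample_size > self.true_Ne:
            raise ValueError("sample_size cannot exceed true_Ne")
        if self.loci_map is not None and len(self.loci_map) != self.n_loci:
            raise ValueError("loci_map length must equal n_loci")


def simulate_wf_genotypes(cfg: WFConfig) -> GenotypeDataset:
    """Run the Wright-Fisher forward simulation and sample S individuals.

    Each generation, every one of the Ne offspring picks two parents
    uniformly at random (selfing allowed); each parent contributes one
    recombinant gamete. Initial haplotypes are in linkage equilibrium with
    allele frequencies Uniform(p0_low, p0_high), so all LD in the output is
    generated by drift and physical linkage.
    """
    rng = np.random.default_rng(cfg.seed)
    Ne, L = cfg.true_Ne, cfg.n_loci

    if cfg.loci_map is None:
        lgs = np.arange(L)
        cms = np.zeros(L)
        order = np.arange(L)
    else:
        lgs = np.array([lg for lg, _ in cfg.loci_map])
        cms = np.array([cm for _, cm in cfg.loci_map])
        order = np.lexsort((cms, lgs))
    lgs_o, cms_o = lgs[order], cms[order]
    # recombination fraction between consecutive loci in map order;
    # free recombination across linkage-group boundaries
    c_between = np.empty(L - 1) if L > 1 else np.empty(0)
    if L > 1:
        same_lg = lgs_o[1:] == lgs_o[:-1]
        c_between[:] = 0.5
        c_between[same_lg] = haldane_c(cms_o[1:][same_lg] - cms_o[:-1][same_lg])

    p0 = rng.uniform(cfg.p0_low, cfg.p0_high, size=L)
    # haplotypes stored in map order, axis 0 = 2*Ne haploid genomes
    haps = (rng.random((2 * Ne, L)) < p0[order]).astype(np.int8)

    for _ in range(cfg.n_generations):
        parents = rng.integers(0, Ne, size=2 * Ne)  # one parent per gamete
        switch = rng.random((2 * Ne, L)) < np.concatenate(([0.5], c_between))
        which = np.cumsum(switch, axis=1, dtype=np.int32) & 1
        pat = haps[2 * parents]
        mat = haps[2 * parents + 1]
        haps = np.where(which == 0, pat, mat).astype(np.int8)

    sampled = rng.choice(Ne, size=cfg.sample_size, replace=False)
    rows = np.empty(2 * cfg.sample_size, dtype=int)
    rows[0::2] = 2 * sampled
    rows[1::2] = 2 * sampled + 1
    geno_o = haps[rows[0::2]] + haps[rows[1::2]]
    # back to input locus order
    geno = np.empty_like(geno_o)
    geno[:, order] = geno_o

    loci = []
    for l in range(L):
        if cfg.loci_map is None:
            loci.append(LocusInfo(locus_id=f"wf{l + 1}", tag_id=f"wf{l + 1}",
                                  linkage_group=int(lgs[l]) + 1, map_position_cM=0.0))
        else:
            loci.append(
                LocusInfo(locus_id=f"wf{l + 1}", tag_id=f"wf{l + 1}",
                          linkage_group=int(lgs[l]), map_position_cM=float(cms[l]))
            )
    inds = [f"wf_ind{j + 1}" for j in range(cfg.sample_size)]
    return GenotypeDataset(
        individuals=inds,
        populations=["wf_pop"] * cfg.sample_size,
        dosage=geno.astype(float),
        loci=loci,
    )


# ---------------------------------------------------------------------------
# Artifact injection and haploid panel
# ---------------------------------------------------------------------------

@dataclass
class ArtifactTruth:
    """Record of every injected defect, sufficient to score the filters."""

    psv_loci: dict[str, tuple[float, float]]  # locus_id -> latent allele freqs
    error_loci: list[str]
    duplicate_pairs: list[tuple[str, str]]  # (original, copy)


def inject_artifacts(
    ds: GenotypeDataset,
    psv_fraction: float = 0.02,
    duplicate_pairs: int = 2,
    error_snp_fraction: float = 0.02,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeDataset, ArtifactTruth]:
    """Plant paralog-contaminated loci, 3'-end error SNPs, and duplicates.

    PSV loci are rebuilt by summing the dosages of two independent latent
    loci and collapsing any mixed signal to a heterozygous call (allele
    count 1..3 of 4 reads as heterozygous), which inflates heterozygosity in
    diploids and makes haploids appear heterozygous. Error SNPs are new
    low-frequency loci at tag positions 88-93. Duplicate individuals are
    genotype copies with independent missingness. Extra i.i.d. missingness
    at ``missing_rate`` is applied to the final matrix.
    """
    for frac in (psv_fraction, error_snp_fraction, missing_rate):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = ds.dosage.copy()
    loci = list(ds.loci)
    n_ind, n_loci = dosage.shape

    # paralog-contaminated loci: overwrite existing columns
    n_psv = int(round(psv_fraction * n_loci))
    psv_idx = rng.choice(n_loci, size=n_psv, replace=False) if n_psv else np.array([], int)
    psv_truth: dict[str, tuple[float, float]] = {}
    base_missing = np.isnan(dosage)
    for j in psv_idx:
        p1, p2 = rng.uniform(0.2, 0.8, size=2)
        d1 = rng.binomial(2, p1, size=n_ind)
        d2 = rng.binomial(2, p2, size=n_ind)
        s = d1 + d2
        apparent = np.where(s == 0, 0.0, np.where(s == 4, 2.0, 1.0))
        apparent[base_missing[:, j]] = np.nan
        dosage[:, j] = apparent
        psv_truth[loci[j].locus_id] = (float(p1), float(p2))

    # sequencing-error SNPs at the 3' end of the tag: appended columns
    n_err = int(round(error_snp_fraction * n_loci))
    error_ids = []
    if n_err:
        freqs = rng.uniform(0.002, 0.02, size=n_err)
        err_block = rng.binomial(2, freqs, size=(n_ind, n_err)).astype(float)
        err_pos = rng.integers(88, 94, size=n_err)
        err_loci = []
        for k in range(n_err):
            lid = f"errtag{k + 1}_{err_pos[k]}"
            err_loci.append(
                LocusInfo(locus_id=lid, tag_id=f"errtag{k + 1}", tag_position=int(err_pos[k]))
            )
            error_ids.append(lid)
        dosage = np.hstack([dosage, err_block])
        loci = loci + err_loci

    individuals = list(ds.individuals)
    populations = list(ds.populations)
    dup_truth = []
    if duplicate_pairs:
        chosen = rng.choice(n_ind, size=duplicate_pairs, replace=False)
        dup_rows = []
        for i in chosen:
            copy = dosage[i].copy()
            # the copy is an independent genotyping run of the same fish:
            # give it its own missing genotypes
            dup_miss = rng.random(copy.size) < max(missing_rate, 0.02)
            copy[dup_miss] = np.nan
            dup_rows.append(copy)
            dup_id = f"{individuals[i]}_dup"
            individuals.append(dup_id)
            populations.append(populations[i])
            dup_truth.append((ds.individuals[i], dup_id))
        dosage = np.vstack([dosage] + [r[None, :] for r in dup_rows])

    if missing_rate > 0:
        dosage[np.random.default_rng(seed + 1).random(dosage.shape) < missing_rate] = np.nan

    out = GenotypeDataset(
        individuals=individuals, populations=populations, dosage=dosage, loci=loci
    )
    return out, ArtifactTruth(
        psv_loci=psv_truth, error_loci=error_ids, duplicate_pairs=dup_truth
    )


def simulate_haploid_panel(
    freqs: Mapping[str, float] | Sequence[float],
    psv_truth: ArtifactTruth | None,
    locus_ids: Sequence[str],
    n_individuals: int = 50,
    seed: int = 0,
) -> HaploidPanel:
    """Genotype haploid individuals on the SNP panel.

    A correctly segregating locus can never be heterozygous in a haploid:
    each individual carries a single allele drawn at the locus frequency.
    A paralog-contaminated locus carries one copy of each latent paralog, so
    it reads heterozygous whenever the two latent alleles differ, i.e. with
    probability p1(1-p2) + p2(1-p1).
    """
    if n_individuals < 1:
        raise ValueError("need at least one haploid individual")
    rng = np.random.default_rng(seed)
    if not isinstance(freqs, Mapping):
        freqs = dict(zip(locus_ids, freqs))
    psv = psv_truth.psv_loci if psv_truth is not None else {}
    calls = np.empty((n_individuals, len(locus_ids)), dtype=np.int8)
    for j, lid in enumerate(locus_ids):
        if lid in psv:
            p1, p2 = psv[lid]
            a1 = rng.random(n_individuals) < p1
            a2 = rng.random(n_individuals) < p2
            het = a1 != a2
            calls[:, j] = np.where(het, HAP_HET, np.where(a1, HAP_REF, HAP_ALT))
        else:
            p = float(freqs.get(lid, 0.5))
            calls[:, j] = np.where(rng.random(n_individuals) < p, HAP_REF, HAP_ALT)
    inds = [f"hap{j + 1}" for j in range(n_individuals)]
    return HaploidPanel(individuals=inds, calls=calls, locus_ids=list(locus_ids))


def plant_selected_region(
    ds: GenotypeDataset,
    linkage_group: int,
    center_cM: float,
    half_width_cM: float,
    fst_boost: float,
    pops: Sequence[str],
    seed: int = 0,
) -> GenotypeDataset:
    """Redraw loci inside a map interval with elevated divergence.

    Mapped loci on ``linkage_group`` within ``center_cM +/- half_width_cM``
    have their genotypes in the named populations redrawn from the
    Balding-Nichols model with F = fst_boost around the locus's current
    overall allele frequency; missingness is preserved. With ``fst_boost=0``
    the dataset is returned unchanged.
    """
    lg_pos = [
        l.map_position_cM for l in ds.loci if l.linkage_group == linkage_group
    ]
    if not lg_pos:
        raise ValueError(f"no mapped loci on linkage group {linkage_group}")
    lg_len = max(lg_pos)
    lo, hi = center_cM - half_width_cM, center_cM + half_width_cM
    if lo < 0 or hi > lg_len:
        raise ValueError(
            f"region [{lo}, {hi}] outside linkage group {linkage_group} "
            f"bounds [0, {lg_len}]"
        )
    if fst_boost == 0.0:
        return GenotypeDataset(
            individuals=list(ds.individuals),
            populations=list(ds.populations),
            dosage=ds.dosage.copy(),
            loci=list(ds.loci),
        )
    if not 0.0 < fst_boost < 1.0:
        raise ValueError("fst_boost must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    dosage = ds.dosage.copy()
    target = [
        j
        for j, l in enumerate(ds.loci)
        if l.linkage_group == linkage_group and lo <= l.map_position_cM <= hi
    ]
    pop_rows = ds.pop_indices()
    for j in target:
        col = dosage[:, j]
        called = ~np.isnan(col)
        p_overall = float(col[called].sum() / (2 * called.sum())) if called.any() else 0.5
        p_overall = min(max(p_overall, 0.02), 0.98)
        for p in pops:
            rows = pop_rows[p]
            p_pop = _balding_nichols(rng, np.array([p_overall]), fst_boost)[0]
            new = rng.binomial(2, p_pop, size=rows.size).astype(float)
            keep_missing = np.isnan(col[rows])
            new[keep_missing] = np.nan
            dosage[rows, j] = new
    return GenotypeDataset(
        individuals=list(ds.individuals),
        populations=list(ds.populations),
        dosage=dosage,
        loci=list(ds.loci),
    )
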