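"""Genotype data model and readers/writers for the external text formats.

The central container is :class:`GenotypeDataset`: an individuals x loci
matrix of reference-allele dosages (0, 1, 2, or missing) with per-individual
population labels and per-locus metadata (RAD tag, tag position, optional
linkage-map placement). Genepop is the interchange format for genotypes;
linkage-map assignments and census sizes come in as tab-separated tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

# haploid-panel call codes
HAP_ALT = 0
HAP_REF = 1
HAP_HET = 2
HAP_MISSING = -1


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class LocusInfo:
    """Per-locus metadata.

    ``tag_position`` is the 1-based bp offset of the SNP within its RAD tag
    (1-93 for 100-bp single-end reads after barcode/site trimming).
    ``linkage_group`` and ``map_position_cM`` are either both present (locus
    placed on the linkage map) or both absent.
    """

    locus_id: str
    tag_id: str = ""
    tag_position: int = 1
    linkage_group: int | None = None
    map_position_cM: float | None = None

    def __post_init__(self) -> None:
        if self.tag_position < 1:
            raise ValueError(f"tag_position must be >= 1, got {self.tag_position}")
        if (self.linkage_group is None) != (self.map_position_cM is None):
            raise ValueError(
                f"locus {self.locus_id}: linkage_group and map_position_cM "
                "must be both present or both absent"
            )
        if self.map_position_cM is not None and self.map_position_cM < 0:
            raise ValueError(f"locus {self.locus_id}: negative cM position")

    @property
    def mapped(self) -> bool:
        return self.linkage_group is not None


@dataclass
class GenotypeDataset:
    """Diploid biallelic SNP genotypes for one or more populations.

    ``dosage[i, l]`` counts copies of the reference allele carried by
    individual ``i`` at locus ``l``: 0, 1, or 2, with ``numpy.nan`` for a
    missing genotype.
    """

    individuals: list[str]
    populations: list[str]
    dosage: np.ndarray
    loci: list[LocusInfo]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_ind, n_loc = self.dosage.shape
        if len(self.individuals) != n_ind or len(self.populations) != n_ind:
            raise ValueError("individual/population label length mismatch with dosage rows")
        if len(self.loci) != n_loc:
            raise ValueError("loci metadata length mismatch with dosage columns")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1, or 2")
        if n_ind == 0:
            raise ValueError("dataset must contain at least one individual")

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask, True where a genotype was called."""
        return ~np.isnan(self.dosage)

    def pop_labels(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.pop_labels()}

    def locus_index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.locus_ids)}

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of individuals with a called genotype."""
        return self.called.mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return (~self.called).mean(axis=1)

    # -- subsetting ------------------------------------------------------

    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep, dtype=int)
        return GenotypeDataset(
            individuals=list(self.individuals),
            populations=list(self.populations),
            dosage=self.dosage[:, keep].copy(),
            loci=[self.loci[i] for i in keep],
        )

    def drop_loci(self, locus_ids: Iterable[str]) -> "GenotypeDataset":
        drop = set(locus_ids)
        keep = [i for i, lid in enumerate(self.locus_ids) if lid not in drop]
        return self.subset_loci(keep)

    def subset_individuals(self, keep: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep, dtype=int)
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            dosage=self.dosage[keep, :].copy(),
            loci=list(self.loci),
        )

    def drop_individuals(self, ids: Iterable[str]) -> "GenotypeDataset":
        drop = set(ids)
        keep = [i for i, ind in enumerate(self.individuals) if ind not in drop]
        return self.subset_individuals(keep)

    def subset_populations(self, pops: Sequence[str]) -> "GenotypeDataset":
        keep = [i for i, p in enumerate(self.populations) if p in set(pops)]
        if not keep:
            raise ValueError(f"no individuals in populations {pops}")
        return self.subset_individuals(keep)

    def with_map(self, mapping: Mapping[str, tuple[int, float]]) -> "GenotypeDataset":
        """Return a copy whose loci carry linkage-map assignments.

        Loci absent from ``mapping`` keep no map placement. Map entries for
        loci not in the dataset are ignored.
        """
        loci = []
        for loc in self.loci:
            if loc.locus_id in mapping:
                lg, cm = mapping[loc.locus_id]
                loci.append(replace(loc, linkage_group=int(lg), map_position_cM=float(cm)))
            else:
                loci.append(replace(loc, linkage_group=None, map_position_cM=None))
        return GenotypeDataset(
            individuals=list(self.individuals),
            populations=list(self.populations),
            dosage=self.dosage.copy(),
            loci=loci,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class HaploidPanel:
    """Genotype calls from haploid individuals run on a diploid SNP assay.

    A truly haploid sample can only be homozygous at a correctly segregating
    locus; a heterozygous call indicates co-amplified paralogs (a PSV).
    ``calls[i, l]`` is 1 (reference allele), 0 (alternate), 2 (heterozygous
    call), or -1 (missing).
    """

    individuals: list[str]
    calls: np.ndarray
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.locus_ids)):
            raise ValueError("calls shape mismatch with individual/locus labels")
        valid = (HAP_MISSING, HAP_ALT, HAP_REF, HAP_HET)
        if self.calls.size and not np.isin(self.calls, valid).all():
            raise ValueError("haploid calls must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    def het_fraction(self) -> np.ndarray:
        """Per-locus fraction of heterozygous calls among genotyped haploids."""
        genotyped = self.calls != HAP_MISSING
        n = genotyped.sum(axis=0)
        het = (self.calls == HAP_HET).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / np.maximum(n, 1), np.nan)


@dataclass(frozen=True)
class CensusRecord:
    """Census information for one population.

    ``N`` is the mean yearly escapement (spawners reaching the grounds per
    year); ``G`` is the generation length in years.
    """

    population: str
    N: float
    G: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"census N must be positive, got {self.N}")
        if not self.G > 0:
            raise ValueError(f"generation length G must be positive, got {self.G}")


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

_POP_TOKENS = {"pop"}
_TITLE_POPS_KEY = "pops="


def _is_pop_line(line: str) -> bool:
    return line.strip().lower() in _POP_TOKENS


def _parse_genotype_token(
    token: str, lineno: int
) -> tuple[str, str]:
    """Split a diploid genotype field into its two allele codes."""
    if len(token) == 4:
        return token[:2], token[2:]
    if len(token) == 6:
        return token[:3], token[3:]
    raise GenepopParseError(
        f"line {lineno}: genotype field '{token}' is not a 4- or 6-digit code"
    )


def read_genepop(path, ploidy: str = "diploid") -> GenotypeDataset | HaploidPanel:
    """Read a Genepop file (2- or 3-digit allele codes).

    The reference allele at each locus is the numerically smallest allele
    code observed there, which makes the reader deterministic, independent of
    the 2- vs 3-digit dialect, and an exact inverse of :func:`write_genepop`.
    An all-zero code is a missing genotype; a half-missing genotype (exactly
    one zero allele) is treated as missing with a logged warning.

    With ``ploidy="haploid"`` the same diploid-coded file is reinterpreted as
    calls on haploid individuals: heterozygous genotypes become the
    ``heterozygous_call`` code used by the PSV screen.
    """
    if ploidy not in ("diploid", "haploid"):
        raise ValueError("ploidy must be 'diploid' or 'haploid'")
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopParseError("line 1: empty file, missing Genepop title line")
    title = raw[0]

    # locus names: everything between the title and the first POP line;
    # either one per line or comma-separated on a single line
    locus_names: list[str] = []
    i = 1
    while i < len(raw) and not _is_pop_line(raw[i]):
        chunk = raw[i].strip()
        if chunk:
            locus_names.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(raw):
        raise GenepopParseError(f"line {len(raw)}: no POP line found")
    if not locus_names:
        logger.warning("Genepop file %s declares no loci", path)
    n_loci = len(locus_names)

    individuals: list[str] = []
    pop_of: list[int] = []
    allele_a: list[list[str]] = []
    allele_b: list[list[str]] = []
    pop_first_ind: list[str] = []
    current_pop = -1
    while i < len(raw):
        line = raw[i]
        lineno = i + 1
        i += 1
        if _is_pop_line(line):
            current_pop += 1
            pop_first_ind.append("")
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenepopParseError(
                f"line {lineno}: expected 'name , genotypes' (no comma found)"
            )
        name, _, geno_part = line.partition(",")
        name = name.strip()
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise GenepopParseError(
                f"line {lineno}: individual '{name}' has {len(tokens)} genotype "
                f"fields, expected {n_loci}"
            )
        if not pop_first_ind[current_pop]:
            pop_first_ind[current_pop] = name
        individuals.append(name)
        pop_of.append(current_pop)
        a_row, b_row = [], []
        for tok in tokens:
            a, b = _parse_genotype_token(tok, lineno)
            a_row.append(a)
            b_row.append(b)
        allele_a.append(a_row)
        allele_b.append(b_row)

    n_ind = len(individuals)
    n_pops = current_pop + 1
    pop_names = _pop_names_from_title(title, n_pops) or [
        pop_first_ind[k] or f"pop{k + 1}" for k in range(n_pops)
    ]
    populations = [pop_names[k] for k in pop_of]

    a_arr = np.array(allele_a, dtype=object).reshape(n_ind, n_loci)
    b_arr = np.array(allele_b, dtype=object).reshape(n_ind, n_loci)

    if ploidy == "haploid":
        calls = np.full((n_ind, n_loci), HAP_MISSING, dtype=np.int8)
    else:
        dosage = np.full((n_ind, n_loci), MISSING, dtype=float)

    half_missing = 0
    for l in range(n_loci):
        a_col = np.array([int(x) for x in a_arr[:, l]])
        b_col = np.array([int(x) for x in b_arr[:, l]])
        both_zero = (a_col == 0) & (b_col == 0)
        one_zero = ((a_col == 0) | (b_col == 0)) & ~both_zero
        half_missing += int(one_zero.sum())
        called = ~(both_zero | one_zero)
        codes = np.unique(np.concatenate([a_col[called], b_col[called]]))
        if codes.size > 2:
            raise GenepopParseError(
                f"locus '{locus_names[l]}' carries {codes.size} distinct alleles; "
                "only biallelic loci are supported"
            )
        if codes.size == 0:
            continue
        # monomorphic locus: orient against the conventional reference code 1,
        # so a locus fixed for allele 002 reads as dosage 0, not 2
        ref = codes.min() if codes.size == 2 else 1
        if ploidy == "haploid":
            het = called & (a_col != b_col)
            calls[het, l] = HAP_HET
            hom = called & ~het
            calls[hom & (a_col == ref), l] = HAP_REF
            calls[hom & (a_col != ref), l] = HAP_ALT
        else:
            dosage[called, l] = (a_col[called] == ref).astype(float) + (
                b_col[called] == ref
            ).astype(float)
    if half_missing:
        logger.warning(
            "%d half-missing genotypes (one zero allele) treated as missing", half_missing
        )

    if ploidy == "haploid":
        return HaploidPanel(individuals=individuals, calls=calls, locus_ids=locus_names)
    loci = [LocusInfo(locus_id=name, tag_id=name.rsplit("_", 1)[0] or name) for name in locus_names]
    return GenotypeDataset(
        individuals=individuals, populations=populations, dosage=dosage, loci=loci
    )


def _pop_names_from_title(title: str, n_pops: int) -> list[str] | None:
    """Recover population labels stashed in the title by write_genepop."""
    idx = title.find(_TITLE_POPS_KEY)
    if idx < 0:
        return None
    names = [s.strip() for s in title[idx + len(_TITLE_POPS_KEY):].split(",")]
    if len(names) != n_pops or not all(names):
        logger.warning("title 'pops=' annotation does not match POP block count; ignored")
        return None
    return names


def write_genepop(ds: GenotypeDataset, path, title: str | None = None) -> None:
    """Write a dataset as a 3-digit Genepop file.

    The reference allele is written as code 001 and the alternate as 002;
    missing genotypes as 000000. Population labels are stashed in the title
    line (``pops=...``) so that a round trip through :func:`read_genepop`
    reproduces labels exactly.
    """
    labels = ds.pop_labels()
    if title is None:
        title = "radpopgen export"
    header = f"{title} {_TITLE_POPS_KEY}{','.join(labels)}"
    groups = ds.pop_indices()
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for lid in ds.locus_ids:
            fh.write(lid + "\n")
        for label in labels:
            fh.write("POP\n")
            for i in groups[label]:
                fields = []
                for d in ds.dosage[i]:
                    if math.isnan(d):
                        fields.append("000000")
                    elif d == 2:
                        fields.append("001001")
                    elif d == 1:
                        fields.append("001002")
                    else:
                        fields.append("002002")
                fh.write(f"{ds.individuals[i]} ,  " + " ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Tab-separated side tables
# ---------------------------------------------------------------------------

def read_map_table(path) -> dict[str, tuple[int, float]]:
    """Read the linkage-map table: locus_id, linkage_group, cM (tab-separated).

    Returns a mapping ``locus_id -> (linkage_group, map_position_cM)``. Loci
    absent from the table simply have no map placement downstream. Duplicate
    locus IDs and non-numeric positions are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("map table needs 3 columns: locus_id, linkage_group, cM")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate locus_id rows in map table: {dups[:5]}")
    try:
        lgs = df.iloc[:, 1].astype(int)
        cms = df.iloc[:, 2].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric linkage_group/cM in map table: {exc}") from exc
    if (cms < 0).any():
        raise ValueError("negative cM position in map table")
    return {lid: (int(lg), float(cm)) for lid, lg, cm in zip(ids, lgs, cms)}


def read_census_table(path) -> list[CensusRecord]:
    """Read the census table: population, N (yearly escapement), G (years)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("population", "n", "g"):
        if needed not in cols:
            raise ValueError(f"census table missing column '{needed}'")
    records = []
    for _, row in df.iterrows():
        records.append(
            CensusRecord(
                population=str(row[cols["population"]]),
                N=float(row[cols["n"]]),
                G=float(row[cols["g"]]),
            )
        )
    return records


def match_census(records: Sequence[CensusRecord], ds: GenotypeDataset) -> dict[str, CensusRecord]:
    """Join census records to dataset population labels.

    Census rows for populations absent from the dataset are ignored with a
    warning; dataset populations without census rows are simply absent from
    the result.
    """
    labels = set(ds.pop_labels())
    out = {}
    for rec in records:
        if rec.population in labels:
            out[rec.population] = rec
        else:
            logger.warning("census row for unknown population '%s' ignored", rec.population)
    return out
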