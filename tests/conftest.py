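import numpy as np
import pytest

from radpopgen.genio import GenotypeDataset, LocusInfo
from radpopgen import synthetic_data as synth


def make_dataset(dosage, populations, loci=None, individuals=None):
    dosage = np.asarray(dosage, dtype=float)
    n_ind, n_loc = dosage.shape
    if loci is None:
        loci = [LocusInfo(locus_id=f"l{j}", tag_id=f"t{j}") for j in range(n_loc)]
    if individuals is None:
        individuals = [f"i{k}" for k in range(n_ind)]
    return GenotypeDataset(
        individuals=individuals, populations=list(populations), dosage=dosage, loci=loci
    )


@pytest.fixture(scope="session")
def island_ds():
    """Five moderately diverged populations, 500 loci, a little missingness."""
    cfg = synth.SimConfig(
        n_pops=5,
        samples_per_pop=[30] * 5,
        n_loci=500,
        target_fst={"group": 0.03, "pop": 0.005},
        missing_rate=0.02,
        seed=42,
    )
    return synth.simulate_island_genotypes(cfg)


@pytest.fixture(scope="session")
def two_pop_ds():
    cfg = synth.SimConfig(
        n_pops=2,
        samples_per_pop=[25, 25],
        n_loci=300,
        group_assignment={"g": ["popA", "popB"]},
        target_fst={"group": 0.0, "pop": 0.05},
        missing_rate=0.0,
        seed=7,
    )
    return synth.simulate_island_genotypes(cfg)
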