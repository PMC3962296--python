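"""The SNP-validation cascade and its individual filters."""

import numpy as np
import pytest

from radpopgen import qc_filtering as qc, synthetic_data as synth
from radpopgen.genio import HAP_ALT, HAP_HET, HAP_MISSING, HAP_REF, HaploidPanel, LocusInfo
from conftest import make_dataset
import _oracles


class TestCallRate:
    def test_boundary_and_extremes(self):
        # 100 individuals: loci called in 79, 100, and 0 of them
        d = np.ones((100, 3))
        d[79:, 0] = np.nan
        d[:, 2] = np.nan
        ds = make_dataset(d, ["A"] * 100)
        kept, removed = qc.filter_call_rate(ds, min_rate=0.8)
        assert removed == ["l0", "l2"]
        assert kept.locus_ids == ["l1"]


class TestMaf:
    def _ds_with_pop_freqs(self, freqs_per_pop, n=50, seed=0):
        rng = np.random.default_rng(seed)
        blocks, pops = [], []
        for k, f in enumerate(freqs_per_pop):
            blocks.append(rng.binomial(2, f, size=(n, len(f))).astype(float))
            pops.extend([f"p{k}"] * n)
        return make_dataset(np.vstack(blocks), pops)

    def test_below_threshold_everywhere_removed(self):
        # deterministic construction: exact dosage counts per population
        cols = []
        for maf in ([0.04, 0.03, 0.04, 0.02, 0.01], [0.04, 0.06, 0.01, 0.01, 0.01]):
            col = []
            for f in maf:
                n_alt = int(round(f * 100))  # of 100 allele copies in 50 inds
                col.extend([1.0] * n_alt + [0.0] * (50 - n_alt))
            cols.append(col)
        pops = sum([[f"p{k}"] * 50 for k in range(5)], [])
        ds = make_dataset(np.array(cols).T, pops)
        kept, removed = qc.filter_maf(ds, threshold=0.05)
        assert removed == ["l0"]  # all pops < 0.05
        assert kept.locus_ids == ["l1"]  # one pop at 0.06 rescues it

    def test_monomorphic_removed(self):
        ds = make_dataset(np.full((10, 1), 2.0), ["A"] * 5 + ["B"] * 5)
        _, removed = qc.filter_maf(ds)
        assert removed == ["l0"]


class TestTagPosition:
    @pytest.mark.parametrize("pos,kept", [(88, False), (87, True), (1, True)])
    def test_boundary(self, pos, kept):
        loci = [LocusInfo(locus_id="x", tag_id="t", tag_position=pos)]
        ds = make_dataset([[1.0], [2.0]], ["A", "A"], loci=loci)
        out, removed = qc.filter_tag_position(ds)
        assert (out.n_loci == 1) is kept


class TestOnePerTag:
    def test_highest_fst_kept_and_tie_break(self):
        loci = [
            LocusInfo(locus_id="t1_a", tag_id="t1", tag_position=5),
            LocusInfo(locus_id="t1_b", tag_id="t1", tag_position=10),
            LocusInfo(locus_id="t2_a", tag_id="t2", tag_position=3),
            LocusInfo(locus_id="t3_a", tag_id="t3", tag_position=9),
            LocusInfo(locus_id="t3_b", tag_id="t3", tag_position=2),
        ]
        ds = make_dataset(np.ones((4, 5)), ["A", "A", "B", "B"], loci=loci)
        fst = {"t1_a": 0.01, "t1_b": 0.05, "t2_a": 0.2, "t3_a": 0.1, "t3_b": 0.1}
        kept, removed = qc.select_one_snp_per_tag(ds, fst)
        assert kept.locus_ids == ["t1_b", "t2_a", "t3_b"]  # tie -> lower position
        assert removed == ["t1_a", "t3_a"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        loci = [
            LocusInfo(locus_id=f"t{j // 3}_{j % 3}", tag_id=f"t{j // 3}",
                      tag_position=j % 3 + 1)
            for j in range(12)
        ]
        fst = {l.locus_id: float(rng.choice([0.1, 0.2])) for l in loci}
        ds = make_dataset(np.ones((2, 12)), ["A", "B"], loci=loci)
        kept1, _ = qc.select_one_snp_per_tag(ds, fst)
        perm = rng.permutation(12)
        kept2, _ = qc.select_one_snp_per_tag(ds.subset_loci(perm), fst)
        assert sorted(kept1.locus_ids) == sorted(kept2.locus_ids)


class TestHweExact:
    def test_monomorphic_p_is_one(self):
        assert qc.hwe_exact_pvalue(1, 0, 0) == 1.0

    def test_matches_rational_enumeration(self):
        assert qc.hwe_exact_pvalue(5, 0, 5) == pytest.approx(
            _oracles.hwe_exact_fraction(5, 0, 5), abs=1e-12
        )
        rng = np.random.default_rng(8)
        for _ in range(150):
            counts = tuple(int(x) for x in rng.integers(0, 18, size=3))
            if sum(counts) == 0:
                continue
            assert qc.hwe_exact_pvalue(*counts) == pytest.approx(
                _oracles.hwe_exact_fraction(*counts), abs=1e-12
            )

    def test_enumeration_probabilities_normalized(self):
        hets, logp = qc._hwe_log_probs(10, 10)
        assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-12)

    def test_filter_rule_min_pops(self):
        # strong HW departure (all heterozygotes) in exactly 2 of 5 pops
        def block(het):
            if het:
                return np.ones((20, 1))
            return np.array([[2.0]] * 5 + [[1.0]] * 10 + [[0.0]] * 5)

        pops = sum([[f"p{k}"] * 20 for k in range(5)], [])
        d2 = np.vstack([block(k < 2) for k in range(5)])
        d3 = np.vstack([block(k < 3) for k in range(5)])
        ds = make_dataset(np.hstack([d2, d3]), pops)
        kept, removed = qc.filter_hwe(ds, alpha=0.05, min_pops=3)
        assert removed == ["l1"] and kept.locus_ids == ["l0"]

    def test_type_one_control_on_hwe_data(self):
        cfg = synth.SimConfig(
            n_pops=5, samples_per_pop=[30] * 5, n_loci=1000,
            target_fst={"group": 0.0, "pop": 0.02}, missing_rate=0.0, seed=33,
        )
        ds = synth.simulate_island_genotypes(cfg)
        _, removed = qc.filter_hwe(ds)
        assert len(removed) / ds.n_loci < 0.03


class TestPairwiseR2:
    def test_identical_and_orthogonal(self):
        d = np.array([[0, 0, 0], [1, 1, 2], [2, 2, 0], [1, 1, 2], [0, 0, 0], [2, 2, 0]],
                     dtype=float)
        ds = make_dataset(d, ["A"] * 6)
        assert qc.pairwise_r2(ds, "A", "l0", "l1") == pytest.approx(1.0)

    def test_worked_table_matches_brute_force(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(6, 2)).astype(float)
        d[1, 0] = np.nan
        ds = make_dataset(d, ["A"] * 6)
        got = qc.pairwise_r2(ds, "A", "l0", "l1")
        exp = _oracles.r2_dosage_brute(d[:, 0], d[:, 1])
        assert got == pytest.approx(exp, abs=1e-12)

    def test_zero_variance_undefined(self):
        ds = make_dataset(np.array([[1, 1], [1, 2], [1, 0]], dtype=float), ["A"] * 3)
        assert np.isnan(qc.pairwise_r2(ds, "A", "l0", "l1"))


class TestLdPrune:
    def _three_pop_ds(self, d_block):
        d = np.vstack([d_block] * 3)
        pops = ["A"] * len(d_block) + ["B"] * len(d_block) + ["C"] * len(d_block)
        return make_dataset(np.array(d, dtype=float), pops)

    def test_duplicated_column_pruned_lower_call_rate(self):
        base = [[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]]
        ds = self._three_pop_ds(base)
        d = ds.dosage.copy()
        d[0, 1] = np.nan  # second copy has lower call rate
        ds = make_dataset(d, ds.populations)
        kept, removed = qc.ld_prune(ds)
        assert removed == ["l1"] and kept.locus_ids == ["l0"]

    def test_two_population_hits_insufficient(self):
        base = [[0, 0], [1, 1], [2, 2], [1, 1], [0, 0], [2, 2]]
        d = np.vstack([base, base, base]).astype(float)
        # decouple the pair in population C
        d[12:, 1] = [2, 0, 1, 0, 2, 1]
        ds = make_dataset(d, ["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        kept, removed = qc.ld_prune(ds, min_pops=3)
        assert removed == []


class TestPsvScreen:
    def test_threshold_boundary(self):
        calls = np.full((50, 2), HAP_REF, dtype=np.int8)
        calls[:6, 0] = HAP_HET  # 12% heterozygous
        calls[:5, 1] = HAP_HET  # 10%: not strictly above threshold
        panel = HaploidPanel(individuals=[f"h{i}" for i in range(50)],
                             calls=calls, locus_ids=["a", "b"])
        assert qc.detect_psv(panel) == ["a"]


class TestIndividualFilters:
    def test_missingness_boundary(self):
        d = np.ones((3, 100))
        d[0, :16] = np.nan  # 16% missing -> removed
        d[1, :15] = np.nan  # 15% -> kept
        ds = make_dataset(d, ["A"] * 3)
        kept, removed = qc.filter_individual_missingness(ds)
        assert removed == ["i0"] and kept.individuals == ["i1", "i2"]

    def test_relatedness_extremes(self):
        d = np.array([[2, 2, 2], [2, 2, 2], [0, 0, 0]], dtype=float)
        ds = make_dataset(d, ["A"] * 3)
        assert qc.relatedness_R(ds, "i0", "i1") == 1.0
        assert qc.relatedness_R(ds, "i0", "i2") == -1.0

    def test_mean_relatedness_matches_ibs_expectation(self):
        """Unrelated HWE individuals: E[R] = 1 - E|d_i - d_j| by enumeration."""
        rng = np.random.default_rng(6)
        p = rng.uniform(0.2, 0.8, size=400)
        d = rng.binomial(2, p, size=(40, 400)).astype(float)
        ds = make_dataset(d, ["A"] * 40)
        got = np.mean(
            [qc.relatedness_R(ds, f"i{2 * k}", f"i{2 * k + 1}") for k in range(20)]
        )
        gp = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])  # P(dosage = 0, 1, 2)
        e_absdiff = sum(
            abs(a - b) * gp[a] * gp[b] for a in range(3) for b in range(3)
        ).mean()
        assert got == pytest.approx(1 - e_absdiff, abs=0.02)

    def test_no_false_duplicates_in_clean_data(self, island_ds):
        assert qc.find_duplicates(island_ds) == []


def build_planted_cascade_fixture():
    """One violation of each rule planted into a clean multi-tag panel."""
    rng = np.random.default_rng(99)
    n = 100
    pops = sum([[f"p{k}"] * 20 for k in range(5)], [])
    n_clean = 30  # enough loci that unrelated individuals are never
                  # genotype-identical by chance (R > 0.9 needs identity)
    p = rng.uniform(0.3, 0.7, size=n_clean)
    clean = rng.binomial(2, p, size=(n, n_clean)).astype(float)
    # keep1 gets population-varying frequencies so its first SNP clearly
    # out-ranks the second SNP on the same tag in overall theta
    for k in range(5):
        clean[20 * k : 20 * (k + 1), 1] = rng.binomial(
            2, 0.2 + 0.15 * k, size=20
        )
    loci = [
        LocusInfo(locus_id=f"keep{j}_1", tag_id=f"keep{j}", tag_position=1)
        for j in range(n_clean)
    ]
    cols = [clean]
    # low call rate
    c = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
    c[: int(0.25 * n)] = np.nan
    cols.append(c)
    loci.append(LocusInfo(locus_id="lowcall_1", tag_id="lowcall", tag_position=1))
    # tag tail position
    cols.append(rng.binomial(2, 0.5, size=(n, 1)).astype(float))
    loci.append(LocusInfo(locus_id="tail_90", tag_id="keep0", tag_position=90))
    # second SNP on an existing tag (lower theta: identical freqs everywhere)
    cols.append(rng.binomial(2, 0.5, size=(n, 1)).astype(float))
    loci.append(LocusInfo(locus_id="keep1_2", tag_id="keep1", tag_position=2))
    # low MAF everywhere
    low = np.zeros((n, 1))
    low[0, 0] = 1.0
    cols.append(low)
    loci.append(LocusInfo(locus_id="lowmaf_1", tag_id="lowmaf", tag_position=1))
    # HWE violation in >= 3 pops: all heterozygotes
    cols.append(np.ones((n, 1)))
    loci.append(LocusInfo(locus_id="hwe_1", tag_id="hwe", tag_position=1))
    # LD twin of a clean locus, fewer genotypes
    twin = clean[:, 2:3].copy()
    twin[:2] = np.nan
    cols.append(twin)
    loci.append(LocusInfo(locus_id="ldtwin_1", tag_id="ldtwin", tag_position=1))
    # PSV locus (flagged by the haploid panel below)
    cols.append(np.ones((n, 1)))
    # keep it in HW: het in haploids is what flags it, so give it HW genotypes
    cols[-1] = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
    loci.append(LocusInfo(locus_id="psv_1", tag_id="psv", tag_position=1))
    dosage = np.hstack(cols)
    inds = [f"ind{k}" for k in range(n)]
    ds = make_dataset(dosage, pops, loci=loci, individuals=inds)
    # high-missingness individual
    ds.dosage[7, : int(0.5 * ds.n_loci)] = np.nan
    # duplicated individual (worse call rate copy)
    dup = ds.dosage[3].copy()
    dup[6] = np.nan  # on the low-call-rate column, which is filtered out
                     # before the individual-level steps run
    ds2 = make_dataset(
        np.vstack([ds.dosage, dup[None, :]]),
        pops + [pops[3]],
        loci=loci,
        individuals=inds + ["ind3_dup"],
    )
    calls = np.full((50, ds2.n_loci), HAP_REF, dtype=np.int8)
    psv_col = ds2.locus_ids.index("psv_1")
    calls[:25, psv_col] = HAP_HET
    panel = HaploidPanel(individuals=[f"h{i}" for i in range(50)],
                         calls=calls, locus_ids=ds2.locus_ids)
    return ds2, panel


@pytest.fixture(scope="module")
def fixture_with_planted_violations():
    return build_planted_cascade_fixture()


class TestCascade:

    def test_exactly_planted_defects_removed(self, fixture_with_planted_violations):
        ds, panel = fixture_with_planted_violations
        out, report = qc.run_cascade(ds, panel)
        assert sorted(report.total_removed_loci()) == sorted(
            ["lowcall_1", "tail_90", "keep1_2", "lowmaf_1", "hwe_1", "ldtwin_1", "psv_1"]
        )
        assert sorted(report.total_removed_individuals()) == ["ind3_dup", "ind7"]
        assert sorted(out.locus_ids) == sorted(f"keep{j}_1" for j in range(30))
        # each planted defect is removed by its own rule
        by_rule = {s.rule: s for s in report.steps}
        assert by_rule["call_rate"].removed_loci == ["lowcall_1"]
        assert by_rule["tag_position"].removed_loci == ["tail_90"]
        assert by_rule["one_per_tag"].removed_loci == ["keep1_2"]
        assert by_rule["maf"].removed_loci == ["lowmaf_1"]
        assert by_rule["psv"].removed_loci == ["psv_1"]
        assert by_rule["hwe"].removed_loci == ["hwe_1"]
        assert by_rule["ld"].removed_loci == ["ldtwin_1"]
        assert by_rule["individual_missingness"].removed_individuals == ["ind7"]
        assert by_rule["duplicates"].removed_individuals == ["ind3_dup"]

    def test_audit_identity_and_monotonicity(self, fixture_with_planted_violations):
        ds, panel = fixture_with_planted_violations
        out, report = qc.run_cascade(ds, panel)
        replay = ds
        for step in report.steps:
            assert step.n_loci_after == step.n_loci_before - len(step.removed_loci)
            assert step.n_ind_after == step.n_ind_before - len(step.removed_individuals)
            replay = replay.drop_loci(step.removed_loci).drop_individuals(
                step.removed_individuals
            )
        assert replay.equals(out)

    def test_idempotent(self, fixture_with_planted_violations):
        ds, panel = fixture_with_planted_violations
        out, _ = qc.run_cascade(ds, panel)
        out2, report2 = qc.run_cascade(out, panel)
        assert out2.equals(out)
        assert not report2.total_removed_loci()
        assert not report2.total_removed_individuals()

    def test_empty_config_is_identity(self, island_ds):
        out, report = qc.run_cascade(island_ds, None, config=[])
        assert out.equals(island_ds) and report.steps == []
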