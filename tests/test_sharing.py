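"""Sharing counts, the NormψY statistic, public-clonotype detection."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repshare import sharing
from repshare.clonotyping import Repertoire, subsample
from repshare.simulate import simulate_power_law_pairs, simulate_shared_pair
from repshare.types import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
)


def rep(sample_id, keys, key_mode="cdr3_aa"):
    return Repertoire(sample_id, {k: 10 for k in keys}, key_mode=key_mode)


key_set = st.sets(st.sampled_from([f"K{i:02d}" for i in range(15)]), max_size=15)


class TestSharedCount:
    def test_intersection(self):
        assert sharing.shared_count(rep("a", "ABC"), rep("b", "BCD")) == 2

    def test_self_sharing_equals_x(self):
        r = rep("a", "ABCDE")
        assert sharing.shared_count(r, r) == r.X == 5

    def test_disjoint_is_zero(self):
        assert sharing.shared_count(rep("a", "AB"), rep("b", "CD")) == 0

    def test_key_mode_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="key_mode"):
            sharing.shared_count(rep("a", "AB"),
                                 rep("b", "AB", key_mode="v_plus_cdr3_aa"))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(key_set, key_set)
    def test_symmetric_and_bounded(self, keys_i, keys_j):
        ri, rj = rep("i", keys_i), rep("j", keys_j)
        y = sharing.shared_count(ri, rj)
        assert y == sharing.shared_count(rj, ri)
        assert y <= min(ri.X, rj.X)


class TestNormalizeSharing:
    def test_zero_pseudocount_zero_shared(self):
        assert sharing.normalize_sharing(0, 10, 10, pseudocount=0.0) == 0.0

    def test_pseudocount_formula_small_case(self):
        assert sharing.normalize_sharing(0, 10, 10, 0.01) == pytest.approx(1e-4)

    def test_pseudocount_formula_asymmetric(self):
        assert sharing.normalize_sharing(4, 100, 300, 0.01) == pytest.approx(
            4.01 / 40000)

    def test_zero_x_is_domain_error(self):
        with pytest.raises(DegenerateInputError):
            sharing.normalize_sharing(0, 0, 10)

    def test_recovers_power_law_constant_from_rounded_pairs(self):
        # Y generated as round(a X^2): NormY should give back ~a.  At X=50
        # the rounding error alone is 20%, so the bound is loose there and
        # exact for X where a X^2 is an integer.
        a = 0.001
        for x in (50, 100, 200):
            y = round(a * x * x)
            est = sharing.normalize_sharing(y, x, x, pseudocount=0.0)
            assert est == pytest.approx(a, rel=0.25)
        assert sharing.normalize_sharing(10, 100, 100, 0.0) == pytest.approx(a)


class TestPairwiseSharing:
    def test_eight_populations_give_28_comparisons(self, meta_two_donors):
        reps = [rep(f"P{i}", {f"K{i}{j}" for j in range(5)}) for i in range(8)]
        meta = [meta_two_donors(f"P{i}", "D1") for i in range(8)]
        results = sharing.pairwise_sharing(reps, meta)
        assert len(results) == 28
        assert all(r.relation == "within_individual" for r in results)

    def test_pair_fields_and_relation(self, meta_two_donors):
        reps = [rep("a", "ABC"), rep("b", "BCD")]
        meta = [meta_two_donors("a", "D1"), meta_two_donors("b", "D2")]
        (res,) = sharing.pairwise_sharing(reps, meta, pseudocount=0.01)
        assert (res.Y, res.X_i, res.X_j) == (2, 3, 3)
        assert res.relation == "between_individual"
        assert res.norm_psi_Y == pytest.approx(2.01 / 9)

    def test_empty_repertoire_error_names_sample(self, meta_two_donors):
        reps = [rep("good", "ABC"), Repertoire("empty", {})]
        meta = [meta_two_donors("good", "D1"), meta_two_donors("empty", "D2")]
        with pytest.raises(DegenerateInputError, match="empty"):
            sharing.pairwise_sharing(reps, meta)

    def test_missing_metadata_rejected(self, meta_two_donors):
        with pytest.raises(InputError, match="metadata"):
            sharing.pairwise_sharing([rep("a", "ABC")], [])

    def test_agrees_with_nested_loop_oracle_on_random_repertoires(
            self, meta_two_donors):
        rng = np.random.default_rng(42)
        pool = [f"K{i:03d}" for i in range(60)]
        reps, meta = [], []
        for i in range(20):
            keys = rng.choice(pool, size=rng.integers(3, 30), replace=False)
            reps.append(rep(f"S{i:02d}", set(keys)))
            meta.append(meta_two_donors(f"S{i:02d}", f"D{i % 5}"))
        results = sharing.pairwise_sharing(reps, meta)
        oracle = {}
        for ri, rj in combinations(sorted(reps, key=lambda r: r.sample_id), 2):
            oracle[(ri.sample_id, rj.sample_id)] = sum(
                1 for k in ri.clonotypes if k in rj.clonotypes)
        assert len(results) == 20 * 19 // 2
        for res in results:
            assert res.Y == oracle[(res.sample_i, res.sample_j)]


class TestPowerLawProperties:
    def test_mean_norm_y_recovers_constant(self):
        a = 0.001
        pairs = simulate_power_law_pairs(
            a, [50, 100, 200, 500], noise="poisson", seed=17, n_pairs=4000)
        est = np.mean([sharing.normalize_sharing(y, xi, xj, 0.0)
                       for xi, xj, y in pairs])
        assert est == pytest.approx(a, rel=0.10)

    def test_norm_y_invariant_under_clonotype_subsampling(self):
        # E[Y'] = q^2 Y and E[X'] = q X under independent key thinning, so
        # NormY is (asymptotically) unchanged at any subsampling rate q.
        a, q = 0.002, 0.5
        full, sub = [], []
        for i in range(300):
            x = 400
            y = np.random.default_rng(1000 + i).poisson(a * x * x)
            keys_i, keys_j = simulate_shared_pair(x, x, min(y, x), seed=i)
            ri, rj = rep("i", keys_i), rep("j", keys_j)
            full.append(sharing.normalize_sharing(
                sharing.shared_count(ri, rj), ri.X, rj.X, 0.0))
            si = subsample(ri, q, seed=2 * i)
            sj = subsample(rj, q, seed=2 * i + 1)
            if si.X and sj.X:
                sub.append(sharing.normalize_sharing(
                    sharing.shared_count(si, sj), si.X, sj.X, 0.0))
        ratio = np.mean(sub) / np.mean(full)
        assert ratio == pytest.approx(1.0, abs=0.15)


class TestFindPublic:
    def test_planted_key_across_three_individuals(self, meta_two_donors):
        reps = [rep(f"s{i}", {"KPUB", f"PRIV{i}"}) for i in range(3)]
        meta = [meta_two_donors(f"s{i}", f"D{i}") for i in range(3)]
        report = sharing.find_public(reps, meta)
        assert [p.key for p in report.public] == ["KPUB"]
        assert report.public[0].n_individuals == 3

    def test_same_individual_two_timepoints_is_within_not_public(
            self, meta_two_donors):
        reps = [rep("d0", {"KX"}), rep("d63", {"KX"})]
        meta = [meta_two_donors("d0", "D1", tp=0),
                meta_two_donors("d63", "D1", tp=63)]
        report = sharing.find_public(reps, meta)
        assert report.public == []
        assert [w.key for w in report.within_individual] == ["KX"]
        assert report.within_individual[0].timepoints == frozenset({0, 63})

    def test_timepoint_filter_restricts_detection(self, meta_two_donors):
        reps = [rep("a63", {"KP"}), rep("b63", {"KP"}),
                rep("a0", {"KQ"}), rep("b0", {"KQ"})]
        meta = [meta_two_donors("a63", "D1", tp=63),
                meta_two_donors("b63", "D2", tp=63),
                meta_two_donors("a0", "D1", tp=0),
                meta_two_donors("b0", "D2", tp=0)]
        at63 = sharing.find_public(reps, meta, timepoint_filter={63})
        assert [p.key for p in at63.public] == ["KP"]
        at0 = sharing.find_public(reps, meta, timepoint_filter={0})
        assert [p.key for p in at0.public] == ["KQ"]

    def test_recovers_planted_truth_from_simulation(self, sim_cohort):
        from repshare.clonotyping import collapse
        by = {}
        for r in sim_cohort.records:
            by.setdefault(r.sample_id, []).append(r)
        reps = [collapse(v) for _, v in sorted(by.items())]
        report = sharing.find_public(reps, sim_cohort.meta,
                                     timepoint_filter={63})
        truth = sim_cohort.truth["public_keys"]
        assert {p.key for p in report.public} == set(truth)
        for p in report.public:
            assert sorted(p.individuals) == truth[p.key]["individuals"]
        none_at_0 = sharing.find_public(reps, sim_cohort.meta,
                                        timepoint_filter={0})
        assert none_at_0.public == []


class TestSharingPerDonor:
    def test_symmetric_single_key(self, meta_two_donors):
        reps = [rep("p", {"K1", "A"}), rep("q", {"K1", "B"})]
        meta = [meta_two_donors("p", "P"), meta_two_donors("q", "Q")]
        df = sharing.sharing_per_donor(reps, meta)
        assert dict(zip(df.individual_id, df.shared_count)) == {"P": 1, "Q": 1}

    def test_no_sharing_is_all_zero(self, meta_two_donors):
        reps = [rep("p", {"A"}), rep("q", {"B"})]
        meta = [meta_two_donors("p", "P"), meta_two_donors("q", "Q")]
        assert sharing.sharing_per_donor(reps, meta).shared_count.sum() == 0

    def test_planted_cohort_five_sharers_three_zeros(self, sim_cohort):
        from repshare.clonotyping import collapse
        by = {}
        for r in sim_cohort.records:
            by.setdefault(r.sample_id, []).append(r)
        reps = [collapse(v) for _, v in sorted(by.items())]
        df = sharing.sharing_per_donor(reps, sim_cohort.meta, timepoints={63})
        carriers = set()
        for info in sim_cohort.truth["public_keys"].values():
            carriers.update(info["individuals"])
        sharers = set(df[df.shared_count > 0].individual_id)
        assert sharers == carriers
        assert (df.shared_count == 0).sum() == 8 - len(carriers)


class TestExportSharingGraph:
    def test_pairs_per_key(self, meta_two_donors):
        meta = [meta_two_donors(s, s) for s in "abc"]
        two = sharing.export_sharing_graph(
            [rep("a", {"K"}), rep("b", {"K"})], meta[:2])
        assert len(two) == 1
        three = sharing.export_sharing_graph(
            [rep(s, {"K"}) for s in "abc"], meta)
        assert len(three) == 3
        assert list(three.columns) == ["sample_i", "sample_j", "key", "relation"]

    def test_empty_input_empty_edges(self):
        assert len(sharing.export_sharing_graph([], [])) == 0


class TestCompareSharingGroups:
    def test_identical_groups_are_null(self):
        res = sharing.compare_sharing_groups(
            {"a": [1, 1, 2], "b": [1, 2, 1]}, test="kruskal_wallis")
        assert res.pvalue > 0.9
        res2 = sharing.compare_sharing_groups(
            {"a": [3, 3], "b": [3, 3]}, test="kruskal_wallis")
        assert (res2.statistic, res2.pvalue) == (0.0, 1.0)

    def test_mann_whitney_complete_separation_matches_enumeration(self):
        # Exact oracle: with n=m=3 and complete separation, only 1 of
        # C(6,3)=20 labelings puts all of one group on one side, so the
        # one-sided p is 1/20 and the two-sided p is 2/20 = 0.1.
        res = sharing.compare_sharing_groups(
            {"a": [0, 0, 0], "b": [5, 5, 5]}, test="mann_whitney")
        assert res.pvalue == pytest.approx(2 / math.comb(6, 3))

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 500
        for _ in range(reps):
            a, b = rng.normal(size=(2, 10))
            res = sharing.compare_sharing_groups(
                {"a": list(a), "b": list(b)}, test="unpaired_t")
            hits += res.pvalue < 0.05
        assert 0.02 <= hits / reps <= 0.08

    def test_validation(self):
        with pytest.raises(InputError):
            sharing.compare_sharing_groups({"a": [1.0]})
        with pytest.raises(InputError, match="empty"):
            sharing.compare_sharing_groups({"a": [1.0], "b": []})
        with pytest.raises(InputError):
            sharing.compare_sharing_groups(
                {"a": [1.0], "b": [2.0]}, test="unpaired_t")
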