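"""OTU clustering and alpha-diversity statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nifdiv import diversity, simulate
from nifdiv.diversity import (
    DistanceMatrix,
    DiversityError,
    chao1_index,
    cluster_average_neighbor,
    isozyme_share_percent,
    pairwise_distances,
    rarefaction_expected,
    resample_table,
    shannon_index,
    site_overlap,
    spurious_otu_rate,
)


class TestPairwiseDistances:
    def test_identical_sequences(self):
        dm = pairwise_distances(["a", "b"], ["ACGT", "ACGT"])
        assert dm.d[0, 1] == 0

    def test_counted_mismatches(self):
        s1 = "A" * 458
        s2 = "C" * 5 + "A" * 453
        dm = pairwise_distances(["a", "b"], [s1, s2])
        assert dm.d[0, 1] == pytest.approx(5 / 458)

    def test_gap_positions_excluded(self):
        dm = pairwise_distances(["a", "b"], ["A---", "AAAA"])
        assert dm.d[0, 1] == 0

    def test_all_gap_pair_distance_one(self):
        dm = pairwise_distances(["a", "b"], ["--", "AA"])
        assert dm.d[0, 1] == 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(DiversityError):
            pairwise_distances(["a", "b"], ["ACG", "AC"])


class TestClustering:
    def test_identical_pair_single_otu(self):
        dm = pairwise_distances(["a", "b"], ["ACGT", "ACGT"])
        assign = cluster_average_neighbor(dm, 0.03)
        assert len(set(assign.values())) == 1

    def test_hand_run_average_linkage(self):
        # d(A,B)=0.02 merges first; average d({A,B},C)=0.04 > 0.03 stops
        d = np.array([[0, 0.02, 0.04], [0.02, 0, 0.04], [0.04, 0.04, 0]])
        assign = cluster_average_neighbor(DistanceMatrix(["A", "B", "C"], d), 0.03)
        assert assign["A"] == assign["B"] != assign["C"]

    def test_cutoff_zero_keeps_distinct_sequences_apart(self):
        seqs = ["AAAA", "AAAT", "AAAA", "TTTT"]
        dm = pairwise_distances(list("abcd"), seqs)
        assign = cluster_average_neighbor(dm, 0.0)
        assert len(set(assign.values())) == 3
        assert assign["a"] == assign["c"]

    def test_empty_matrix(self):
        assert cluster_average_neighbor(DistanceMatrix([], np.zeros((0, 0))), 0.1) == {}

    def test_otu_count_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(15)]
        base = seqs[:5]
        # add noisy copies so several cutoffs matter
        for s in base:
            arr = list(s)
            for p in rng.choice(60, size=3, replace=False):
                arr[p] = "ACGT"[rng.integers(4)]
            seqs.append("".join(arr))
        ids = [f"s{i}" for i in range(len(seqs))]
        dm = pairwise_distances(ids, seqs)
        counts = [
            len(set(cluster_average_neighbor(dm, c).values()))
            for c in (0.0, 0.03, 0.05, 0.10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [([50, 50], math.log(2)), ([100], 0.0), ([1, 2, 3], 1.0114)],
    )
    def test_values(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(DiversityError):
            shannon_index([0, 0])

    @given(st.lists(st.integers(1, 200), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_by_log_richness(self, counts):
        h = shannon_index(counts)
        assert -1e-12 <= h <= math.log(len(counts)) + 1e-12


class TestChao1:
    @pytest.mark.parametrize(
        "counts, expected",
        [([2, 2, 3], 3.0), ([1, 1, 1, 1, 2, 2, 5], 9.0), ([10], 1.0)],
    )
    def test_point_estimates(self, counts, expected):
        chao1, se = chao1_index(counts)
        assert chao1 == pytest.approx(expected)

    def test_single_otu_has_zero_se(self):
        assert chao1_index([10]) == (1.0, 0.0)

    def test_no_doubleton_limit_variance_positive(self):
        chao1, se = chao1_index([1, 1, 1, 3])
        assert chao1 > 4 and se > 0

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_estimator_at_least_observed_richness(self, counts):
        chao1, _ = chao1_index(counts)
        n1 = sum(c == 1 for c in counts)
        assert chao1 >= len(counts)
        if n1 <= 1:
            assert chao1 == pytest.approx(len(counts))


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        counts = [5, 3, 2, 1]
        assert rarefaction_expected(counts, [11]) == [pytest.approx(4.0)]

    def test_depth_one(self):
        assert rarefaction_expected([2, 2], [1]) == [pytest.approx(1.0)]

    def test_enumerated_small_case(self):
        # counts [3,1], depth 2: of C(4,2)=6 subsets, 3 contain only the
        # abundant OTU -> E[S] = (3*1 + 3*2)/6 = 1.5
        assert rarefaction_expected([3, 1], [2]) == [pytest.approx(1.5)]

    def test_monotone_in_depth(self):
        counts = [10, 5, 2, 1, 1]
        vals = rarefaction_expected(counts, list(range(1, 20)))
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(DiversityError):
            rarefaction_expected([2, 1], [4])


class TestResampling:
    def make_table(self):
        return pd.DataFrame(
            {"otu1": [80, 8], "otu2": [30, 2], "otu3": [10, 1]},
            index=["EGL_nifD", "SM_vnfD"],
        )

    def test_shallow_pool_dropped(self):
        out, dropped = resample_table(self.make_table(), depth=100, seed=0)
        assert dropped == ["SM_vnfD"]
        assert list(out.index) == ["EGL_nifD"]

    def test_row_sums_equal_depth(self):
        out, _ = resample_table(self.make_table(), depth=100, seed=1)
        assert (out.sum(axis=1) == 100).all()

    def test_exact_depth_row_unchanged(self):
        table = pd.DataFrame({"a": [60], "b": [40]}, index=["pool"])
        out, dropped = resample_table(table, depth=100, seed=3)
        assert not dropped
        assert out.loc["pool"].tolist() == [60, 40]

    def test_deterministic_per_seed(self):
        t = self.make_table()
        a, _ = resample_table(t, 50, seed=9)
        b, _ = resample_table(t, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSiteOverlap:
    def test_disjoint_sites(self):
        regions = site_overlap({"A": {"x"}, "B": {"y"}, "C": {"z"}})
        assert regions["A"] == regions["B"] == regions["C"] == 1
        assert regions["A&B&C"] == 0

    def test_triple_overlap(self):
        regions = site_overlap({"A": {"x"}, "B": {"x"}, "C": {"x"}})
        assert regions["A&B&C"] == 1 and regions["A"] == 0

    def test_matches_brute_force_on_random_assignment(self):
        rng = np.random.default_rng(4)
        otus = [f"otu{i}" for i in range(40)]
        sites = {s: {o for o in otus if rng.random() < 0.5} for s in "ABC"}
        regions = site_overlap(sites)
        total = len(sites["A"] | sites["B"] | sites["C"])
        assert sum(regions.values()) == total
        only_ab = (sites["A"] & sites["B"]) - sites["C"]
        assert regions["A&B"] == len(only_ab)

    def test_wrong_site_count_rejected(self):
        with pytest.raises(DiversityError):
            site_overlap({"A": set()})


class TestPercentShares:
    def test_observed_richness_shares(self):
        shares = isozyme_share_percent({"nifD": 566, "anfD": 34, "vnfD": 108})
        assert shares == {"nifD": 80, "anfD": 5, "vnfD": 15}

    def test_chao1_shares(self):
        shares = isozyme_share_percent({"nifD": 2822, "anfD": 126, "vnfD": 378})
        assert shares == {"nifD": 85, "anfD": 4, "vnfD": 11}

    def test_sub_percent_share_prints_below_one(self):
        shares = isozyme_share_percent({"nifD": 289, "anfD": 31, "vnfD": 2})
        assert shares == {"nifD": 90, "anfD": 10, "vnfD": "<1"}

    def test_all_zero_rejected(self):
        with pytest.raises(DiversityError):
            isozyme_share_percent({"nifD": 0})


class TestSpuriousOTURate:
    def test_error_free_controls_form_one_otu(self, refs, internal_standard):
        reads = simulate.simulate_ccs_reads(
            refs, {"nifD_ref_00": 30}, internal_standard_fraction=1.0, seed=6
        )
        controls = [r for r in reads if r.truth.is_internal_standard]
        res = spurious_otu_rate(controls, internal_standard.dna, cutoff=0.03)
        assert res["otus_observed"] == 1
        assert res["spurious_per_read"] == 0

    def test_heavy_noise_inflates_otus(self, refs, internal_standard):
        reads = simulate.simulate_ccs_reads(
            refs, {"nifD_ref_00": 40}, internal_standard_fraction=1.0,
            error_rates={"substitution": 0.05}, seed=8
        )
        controls = [r for r in reads if r.truth.is_internal_standard]
        res = spurious_otu_rate(controls, internal_standard.dna, cutoff=0.03)
        assert res["spurious_per_read"] > 0

    def test_rate_non_increasing_in_cutoff(self, refs, internal_standard):
        reads = simulate.simulate_ccs_reads(
            refs, {"nifD_ref_00": 40}, internal_standard_fraction=1.0,
            error_rates={"substitution": 0.03}, seed=12
        )
        controls = [r for r in reads if r.truth.is_internal_standard]
        rates = [
            spurious_otu_rate(controls, internal_standard.dna, cutoff=c)[
                "spurious_per_read"
            ]
            for c in (0.01, 0.03, 0.05, 0.10)
        ]
        assert rates == sorted(rates, reverse=True)

    def test_empty_control_set_signaled(self, internal_standard):
        with pytest.raises(DiversityError):
            spurious_otu_rate([], internal_standard.dna)
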