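from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import hippoconn as h
from hippoconn.atlas import SEEDS
from hippoconn.edge_stats import WEAKER
from hippoconn.simulate import GROUP_MINUS, GROUP_PLUS


def _make_fcs(arr):
    roi_ids = np.arange(1, arr.shape[2] + 1)
    return [h.FcMatrix(participant_id=f"s{i}",
                       z=pd.DataFrame(arr[i], index=list(SEEDS),
                                      columns=roi_ids))
            for i in range(len(arr))]


class TestDifferenceScore:
    def test_published_count_arithmetic(self):
        # the group analysis produced 46 right-body weaker edges vs
        # 1 + 11 + 10 on the other seeds: score = 24
        counts = {"left_head": 1, "left_body": 11, "right_head": 10,
                  "right_body": 46}
        assert h.difference_score(counts, "right_body") == 24

    def test_zero_and_symmetric_cases(self):
        zeros = {s: 0 for s in SEEDS}
        assert h.difference_score(zeros, "left_body") == 0
        fours = {s: 4 for s in SEEDS}
        for s in SEEDS:
            assert h.difference_score(fours, s) == -8

    def test_missing_seed_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            h.difference_score({"left_head": 1}, "right_body")


class TestPermTestDifferenceScore:
    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        """4+4 toy: enumerate all C(8,4)=70 group assignments and compare
        the exact permutation p with the Monte-Carlo one."""
        rng = np.random.default_rng(17)
        arr = rng.standard_normal((8, 4, 6)) * 0.3
        arr[4:, 3, :3] -= 1.2  # right_body effect
        fcs = _make_fcs(arr)
        labels = np.array([GROUP_MINUS] * 4 + [GROUP_PLUS] * 4)

        def score_for(assignment):
            lab = np.full(8, GROUP_MINUS)
            lab[list(assignment)] = GROUP_PLUS
            edges = h.edge_group_ttests(fcs, lab)
            counts = h.count_significant(edges, 0.05, WEAKER)
            return h.difference_score(counts, "right_body")

        observed = score_for((4, 5, 6, 7))
        null = [score_for(c) for c in combinations(range(8), 4)]
        exact_p = np.mean([s >= observed for s in null])

        cfg = h.PermutationConfig(n_permutations=10_000, rng_seed=1)
        res = h.perm_test_difference_score(fcs, labels, "binary",
                                           "right_body", cfg)
        assert res.observed_score == observed
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_fixed_seed_reproducible(self, small_cohort):
        _, phen, _, _, _, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=300, rng_seed=42)
        a = h.perm_test_difference_score(fcs, phen["group"], "binary",
                                         "right_body", cfg)
        b = h.perm_test_difference_score(fcs, phen["group"], "binary",
                                         "right_body", cfg)
        assert a.p == b.p
        assert np.array_equal(a.null_scores, b.null_scores)

    def test_p_respects_floor_and_ceiling(self, small_cohort):
        _, phen, _, _, _, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=200, rng_seed=0)
        res = h.perm_test_difference_score(fcs, phen["group"], "binary",
                                           "right_body", cfg)
        assert 1 / 201 <= res.p <= 1.0

    def test_planted_effect_detected(self, small_cohort):
        _, phen, _, _, _, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=1000, rng_seed=2)
        res = h.perm_test_difference_score(fcs, phen["group"], "binary",
                                           "right_body", cfg)
        assert res.observed_counts["right_body"] > 5
        assert res.p < 0.05

    def test_continuous_design_detects_cci_slope(self):
        cfg_c = h.CohortConfig(
            n_minus=12, n_plus=14, n_targets=20,
            partition_spec={"DMN": 12, "VIS": 8}, n_timepoints=300,
            effect_map={("right_body", "DMN"): h.Effect(cci_slope=0.007)},
            rng_seed=23)
        phen, ts, _, atlas = h.simulate_cohort(cfg_c)
        fcs = [h.fc_matrix(t, atlas) for t in ts]
        cfg = h.PermutationConfig(n_permutations=1000, rng_seed=3)
        res = h.perm_test_difference_score(
            fcs, phen["cci12"].astype(float), "continuous", "right_body", cfg)
        assert res.p < 0.05


class TestNetworkContingency:
    def test_planted_dmn_effect_flagged(self, small_cohort):
        _, phen, _, _, atlas, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=1000, rng_seed=4)
        res = h.network_contingency(fcs, phen["group"], "binary",
                                    "right_body", atlas, cfg)
        assert "DMN" in res.significant_networks

    def test_counts_consistent_with_seed_totals(self, small_cohort):
        _, phen, _, _, atlas, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=50, rng_seed=5)
        res = h.network_contingency(fcs, phen["group"], "binary",
                                    "right_body", atlas, cfg)
        edges = h.edge_group_ttests(fcs, phen["group"])
        counts = h.count_significant(edges, 0.05, WEAKER)
        assert res.total_count == counts["right_body"]

    def test_absent_network_gets_count_zero_p_one(self, small_cohort):
        _, phen, _, _, atlas, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=50, rng_seed=6)
        res = h.network_contingency(fcs, phen["group"], "binary",
                                    "right_body", atlas, cfg)
        absent = res.table[res.table["absent"]]
        assert len(absent) == 11  # cohort has only DMN and VIS
        assert (absent["observed_count"] == 0).all()
        assert (absent["p"] == 1.0).all()

    def test_fdr_at_least_raw_p(self, small_cohort):
        _, phen, _, _, atlas, fcs = small_cohort
        cfg = h.PermutationConfig(n_permutations=100, rng_seed=7)
        res = h.network_contingency(fcs, phen["group"], "binary",
                                    "right_body", atlas, cfg)
        assert (res.table["p_fdr"] >= res.table["p"] - 1e-12).all()

    def test_separable_effect_concentrates_on_its_network(self):
        # all significant edges concentrated in one toy network by
        # construction: that network carries the full count and the
        # smallest p; the untouched network stays unremarkable
        rng = np.random.default_rng(30)
        arr = rng.standard_normal((20, 4, 10)) * 0.1
        arr[10:, 3, :5] -= 3.0
        fcs = _make_fcs(arr)
        table = pd.DataFrame({
            "roi_id": np.arange(1, 11), "x": 0.0, "y": 0.0, "z": 0.0,
            "network": ["DMN"] * 5 + ["VIS"] * 5,
        })
        atlas = h.TargetAtlas(table=table)
        labels = [GROUP_MINUS] * 10 + [GROUP_PLUS] * 10
        cfg = h.PermutationConfig(n_permutations=500, rng_seed=8)
        res = h.network_contingency(fcs, labels, "binary", "right_body",
                                    atlas, cfg)
        t = res.table.set_index("network")
        assert t.loc["DMN", "observed_count"] == 5  # saturated
        assert t.loc["DMN", "p"] == t["p"].min() < 0.05
        assert t.loc["VIS", "p"] > t.loc["DMN", "p"]

    def test_p_convention_floor_when_observed_beats_all_nulls(self):
        from hippoconn.permutation import _mc_pvalue
        null = np.arange(500)
        assert _mc_pvalue(null, 1000) == pytest.approx(1 / 501)
        assert _mc_pvalue(null, -1) == 1.0

    def test_permutations_preserve_score_multiset(self):
        # the continuous null must use the same score multiset: with a
        # constant-plus-one-outlier score vector the null distribution of
        # counts is invariant to which participant holds the outlier
        rng = np.random.default_rng(31)
        arr = rng.standard_normal((10, 4, 6))
        fcs = _make_fcs(arr)
        scores = np.array([20.0] * 9 + [40.0])
        cfg = h.PermutationConfig(n_permutations=100, rng_seed=9)
        res = h.perm_test_difference_score(fcs, scores, "continuous",
                                           "right_body", cfg)
        assert 0 < res.p <= 1.0
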