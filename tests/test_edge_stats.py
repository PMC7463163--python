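import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hippoconn as h
from hippoconn.atlas import SEEDS
from hippoconn.edge_stats import NEGATIVE, POSITIVE, WEAKER, STRONGER
from hippoconn.simulate import GROUP_MINUS, GROUP_PLUS


def _fc_from_array(z, roi_ids, pid):
    return h.FcMatrix(participant_id=pid,
                      z=pd.DataFrame(z, index=list(SEEDS), columns=roi_ids))


def _make_fcs(arr):
    """(n, 4, N) array -> list of FcMatrix with roi_ids 1..N."""
    roi_ids = np.arange(1, arr.shape[2] + 1)
    return [_fc_from_array(arr[i], roi_ids, f"s{i}") for i in range(len(arr))]


class TestGroupTtests:
    def test_mirrored_groups_show_no_differences(self):
        rng = np.random.default_rng(0)
        half = rng.standard_normal((6, 4, 8))
        arr = np.concatenate([half, half])  # identical group distributions
        groups = [GROUP_MINUS] * 6 + [GROUP_PLUS] * 6
        res = h.edge_group_ttests(_make_fcs(arr), groups)
        assert (res.table["statistic"].abs() < 1e-12).all()
        assert (res.table["p"] > 0.999).all()

    def test_direction_tracks_sign_of_group_difference(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((12, 4, 6)) * 0.1
        arr[6:, 0, 0] -= 2.0   # left_head/roi_1 weaker in SMD+
        arr[6:, 1, 1] += 2.0   # left_body/roi_2 stronger in SMD+
        groups = [GROUP_MINUS] * 6 + [GROUP_PLUS] * 6
        t = h.edge_group_ttests(_make_fcs(arr), groups).table
        row = t[(t.seed == "left_head") & (t.roi_id == 1)].iloc[0]
        assert row["direction"] == WEAKER and row["p"] < 0.001
        row = t[(t.seed == "left_body") & (t.roi_id == 2)].iloc[0]
        assert row["direction"] == STRONGER and row["p"] < 0.001

    def test_two_tailed_p_is_twice_smaller_one_tailed(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((10, 4, 3))
        groups = [GROUP_MINUS] * 5 + [GROUP_PLUS] * 5
        res = h.edge_group_ttests(_make_fcs(arr), groups).table
        for _, row in res.iterrows():
            one_tailed = stats.t.sf(abs(row["statistic"]), 8)
            assert row["p"] == pytest.approx(2 * one_tailed, rel=1e-10)

    def test_degenerate_edge_flagged_and_excluded(self):
        rng = np.random.default_rng(3)
        arr = rng.standard_normal((8, 4, 3))
        arr[:, 2, 0] = 0.7  # constant across participants
        groups = [GROUP_MINUS] * 4 + [GROUP_PLUS] * 4
        res = h.edge_group_ttests(_make_fcs(arr), groups)
        t = res.table
        row = t[(t.seed == "right_head") & (t.roi_id == 1)].iloc[0]
        assert row["degenerate"]
        counts = h.count_significant(res, alpha=1.0, direction_filter=None)
        assert counts["right_head"] == 2  # degenerate edge never counts


class TestScoreCorrelations:
    def test_edge_equal_to_negated_scores_gives_minus_one(self):
        rng = np.random.default_rng(4)
        n = 10
        scores = rng.uniform(12, 42, n)
        arr = rng.standard_normal((n, 4, 4)) * 0.3
        arr[:, 3, 2] = -scores
        res = h.edge_score_correlations(_make_fcs(arr), scores).table
        row = res[(res.seed == "right_body") & (res.roi_id == 3)].iloc[0]
        assert row["statistic"] == pytest.approx(-1.0)
        assert row["direction"] == NEGATIVE

    def test_null_fpr_within_binomial_bounds(self):
        # per-edge two-tailed test at alpha=0.05 on independent data
        rng = np.random.default_rng(5)
        n, reps = 24, 250
        hits = total = 0
        for _ in range(reps):
            scores = rng.uniform(12, 42, n)
            arr = rng.standard_normal((n, 4, 10))
            t = h.edge_score_correlations(_make_fcs(arr), scores).table
            hits += (t["p"] < 0.05).sum()
            total += len(t)
        fpr = hits / total
        assert 0.04 <= fpr <= 0.06  # 10000 edges, generous binomial band

    def test_planted_cci_slope_concentrates_negative_edges(self):
        cfg = h.CohortConfig(
            n_minus=14, n_plus=16, n_targets=16,
            partition_spec={"DMN": 8, "VIS": 8}, n_timepoints=400,
            effect_map={("right_body", "DMN"): h.Effect(cci_slope=0.006)},
            rng_seed=21)
        phen, ts, _, atlas = h.simulate_cohort(cfg)
        fcs = [h.fc_matrix(t, atlas) for t in ts]
        res = h.edge_score_correlations(fcs, phen["cci12"].astype(float))
        counts = h.count_significant(res, 0.05, NEGATIVE)
        assert counts["right_body"] > max(counts[s] for s in SEEDS
                                          if s != "right_body")


class TestPartialCorrelations:
    def test_closed_form_on_fixed_vectors(self):
        from hippoconn.edge_stats import partial_corr
        x = np.array([1.0, 2.0, 4.0, 3.5, 6.0, 5.0])
        y = np.array([2.0, 1.5, 3.0, 4.0, 5.5, 5.0])
        c = np.array([0.5, 1.0, 2.5, 2.0, 4.0, 3.0])
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xc = np.corrcoef(x, c)[0, 1]
        r_yc = np.corrcoef(y, c)[0, 1]
        expected = (r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc**2) * (1 - r_yc**2))
        assert partial_corr(x, y, c) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 30
        scores = rng.uniform(12, 42, n)
        covar = 0.5 * scores + rng.standard_normal(n) * 5
        arr = rng.standard_normal((n, 4, 3)) + 0.02 * scores[:, None, None]
        res = h.edge_partial_correlations(_make_fcs(arr), scores, covar).table
        df = pd.DataFrame({"x": arr[:, 0, 0], "s": scores, "c": covar})
        ref = pingouin.partial_corr(df, x="x", y="s", covar="c")
        row = res[(res.seed == "left_head") & (res.roi_id == 1)].iloc[0]
        assert row["statistic"] == pytest.approx(ref["r"].iloc[0], abs=1e-9)
        assert row["p"] == pytest.approx(ref["p_val"].iloc[0], abs=1e-9)

    def test_independent_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(7)
        n = 400
        scores = rng.standard_normal(n)
        covar = rng.standard_normal(n)  # independent of everything
        arr = rng.standard_normal((n, 4, 2)) + 0.3 * scores[:, None, None]
        simple = h.edge_score_correlations(_make_fcs(arr), scores).table
        partial = h.edge_partial_correlations(_make_fcs(arr), scores, covar).table
        assert np.allclose(simple["statistic"], partial["statistic"], atol=0.05)

    def test_shared_variance_removed(self):
        # edges driven purely by the covariate: simple r with the scores is
        # strong, but partialling out the covariate leaves only noise
        rng = np.random.default_rng(8)
        n = 200
        covar = rng.standard_normal(n)
        scores = covar + 1e-3 * rng.standard_normal(n)
        arr = np.tile(covar[:, None, None], (1, 4, 2)) \
            + 0.5 * rng.standard_normal((n, 4, 2))
        simple = h.edge_score_correlations(_make_fcs(arr), scores).table
        assert np.abs(simple["statistic"]).min() > 0.8
        partial = h.edge_partial_correlations(_make_fcs(arr), scores, covar).table
        assert np.abs(partial["statistic"]).max() < 0.2

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(9)
        scores = rng.standard_normal(8)
        arr = rng.standard_normal((8, 4, 2))
        with pytest.raises(ValueError, match="collinear"):
            h.edge_partial_correlations(_make_fcs(arr), scores, scores)


class TestCountSignificant:
    def test_no_significant_edges(self):
        rng = np.random.default_rng(10)
        arr = rng.standard_normal((8, 4, 5)) * 1e-3
        groups = [GROUP_MINUS] * 4 + [GROUP_PLUS] * 4
        res = h.edge_group_ttests(_make_fcs(arr), groups)
        counts = h.count_significant(res, alpha=1e-12)
        assert counts == {s: 0 for s in SEEDS}

    def test_exact_counts_on_planted_pvalues(self):
        # build a result set directly with known p-values and directions
        rows = []
        planted = {"left_head": 1, "left_body": 3, "right_head": 0,
                   "right_body": 5}
        for seed in SEEDS:
            for roi in range(1, 9):
                sig = roi <= planted[seed]
                rows.append({"seed": seed, "roi_id": roi,
                             "statistic": -2.0 if sig else 0.1,
                             "p": 0.01 if sig else 0.5,
                             "direction": WEAKER if sig else STRONGER,
                             "degenerate": False})
        res = h.EdgeResultSet("binary", pd.DataFrame(rows), n_participants=20)
        assert h.count_significant(res, 0.05, WEAKER) == planted

    def test_monotone_in_alpha_and_invariant_to_order(self):
        rng = np.random.default_rng(11)
        arr = rng.standard_normal((16, 4, 12))
        arr[8:] -= 0.4
        groups = [GROUP_MINUS] * 8 + [GROUP_PLUS] * 8
        fcs = _make_fcs(arr)
        res = h.edge_group_ttests(fcs, groups)
        c1 = h.count_significant(res, 0.01)
        c5 = h.count_significant(res, 0.05)
        assert all(c1[s] <= c5[s] for s in SEEDS)
        perm = rng.permutation(12)
        fcs_perm = _make_fcs(arr[:, :, perm])  # roi ids relabelled with data
        res_perm = h.edge_group_ttests(fcs_perm, groups)
        assert h.count_significant(res_perm, 0.05) == c5
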