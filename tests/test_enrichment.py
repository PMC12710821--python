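"""Tests for the two-stage permutation enrichment analysis."""

import numpy as np
import pytest

from hemiconn import enrichment as enr
from hemiconn.connectome import hemi_mask_to_matrix



def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle for Benjamini-Hochberg."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestEmpiricalP:
    def test_median_observation_is_not_significant(self):
        null = np.linspace(-1, 1, 1001)
        assert enr.empirical_p_two_sided(0.0, null) == pytest.approx(1.0, abs=0.01)

    def test_extreme_observation_hits_floor(self):
        null = np.random.default_rng(0).normal(size=10_000)
        p = enr.empirical_p_two_sided(99.0, null)
        assert p == pytest.approx(0.0003)
        assert p == enr.p_floor(10_000)

    def test_brute_force_tail_counting(self):
        """Both tails counted by hand on a 900-value null; anything smaller
        than the 3/reps floor is clamped to it."""
        null = np.arange(900, dtype=float)
        observed = 897.5  # ranks 3rd largest: 2 null values above
        n_ge = (null >= observed).sum()  # 2
        n_le = (null <= observed).sum()  # 898
        expected = min(1.0, 2 * min(n_ge, n_le) / 900)
        assert expected == pytest.approx(4 / 900)
        assert enr.empirical_p_two_sided(observed, null) == pytest.approx(expected)
        # one value above: raw 2/900 falls under the floor and is clamped
        assert enr.empirical_p_two_sided(898.5, null) == pytest.approx(3 / 900)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        null = rng.normal(size=(500, 4))
        obs = rng.normal(size=4)
        vec = enr.empirical_p_two_sided(obs, null)
        for j in range(4):
            assert vec[j] == enr.empirical_p_two_sided(obs[j], null[:, j])

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enr.empirical_p_two_sided(0.0, np.array([]))
        with pytest.raises(ValueError, match="100"):
            enr.empirical_p_two_sided(0.0, np.arange(50))


class TestGroupMap:
    @pytest.mark.parametrize("k,expected", [(1, 1), (4, 10), (8, 36)])
    def test_group_count_formula(self, k, expected):
        from hemiconn.connectome import ParcelAtlas

        nets = [(f"N{i}", 3) for i in range(k)]
        atlas = ParcelAtlas.from_networks(nets)
        gid, names = enr.network_group_map(atlas)
        assert len(names) == expected == k * (k + 1) // 2
        assert gid.min() >= 0  # nothing dropped here

    def test_dropped_networks_excluded_from_grouping(self):
        from hemiconn.connectome import ParcelAtlas, merge_and_drop_networks

        atlas = ParcelAtlas.from_networks([("A", 3), ("B", 3), ("C", 2)])
        atlas = merge_and_drop_networks(atlas, merge_rules={}, drop_rules=("C",))
        gid, names = enr.network_group_map(atlas)
        assert len(names) == 3  # A-A, A-B, B-B
        labels = atlas.networks[:8]
        from hemiconn.connectome import feature_pairs

        for f, (i, j) in enumerate(feature_pairs(8, "HC-LH")):
            if "C" in (labels[i], labels[j]):
                assert gid[f] == -1
            else:
                assert gid[f] >= 0


class TestGroupEnrichment:
    def test_empty_mask_gives_unit_pvalues(self):
        gid = np.array([0, 0, 1, 1, 2])
        counts, p = enr.group_enrichment(np.zeros(5, bool), gid, 3, reps=200, seed=0)
        assert counts.tolist() == [0, 0, 0]
        assert np.all(p == 1.0)

    def test_saturated_mask_is_never_enriched(self):
        gid = np.array([0, 0, 1, 1, 2])
        counts, p = enr.group_enrichment(np.ones(5, bool), gid, 3, reps=200, seed=0)
        assert counts.tolist() == [2, 2, 1]
        assert np.all(p == 1.0)

    def test_planted_concentration_detected(self):
        rng = np.random.default_rng(0)
        gid = rng.integers(0, 10, size=400)
        mask = np.zeros(400, bool)
        mask[np.flatnonzero(gid == 3)[:15]] = True  # all hits in group 3
        counts, p = enr.group_enrichment(mask, gid, 10, reps=1000, seed=1)
        assert p[3] < 0.01
        assert np.all(p[np.arange(10) != 3] > 0.05)


class TestFdr:
    def test_all_ones(self):
        assert np.all(enr.fdr_correct(np.ones(36)) == 1.0)

    def test_three_floor_values_among_36(self):
        """Three permutation-floor p-values of .0003 among 36 groups adjust
        to .0036 each (.0003 * 36 / 3)."""
        p = np.ones(36)
        p[:3] = 0.0003
        adj = enr.fdr_correct(p)
        assert np.allclose(adj[:3], 0.0036)

    def test_matches_brute_force_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.005, 0.8])
        assert np.allclose(enr.fdr_correct(p), brute_force_bh(p))
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-4, 1, size=rng.integers(2, 40))
            assert np.allclose(enr.fdr_correct(p), brute_force_bh(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            enr.fdr_correct([0.0, 0.5])


class TestConnectionSignificance:
    def test_planted_feature_hits_floor(self):
        """One feature with a large LH-RH mean shift lands at the p floor."""
        rng = np.random.default_rng(0)
        n_subj, n_feat = 30, 40
        X = rng.normal(size=(2 * n_subj, n_feat))
        y = np.array(["LH", "RH"] * n_subj)
        subj = np.repeat([f"s{i}" for i in range(n_subj)], 2)
        X[y == "LH", 7] += 3.0
        obs, p, mask = enr.connection_significance(X, y, subj, reps=500, alpha=0.01, seed=1)
        assert p[7] == enr.p_floor(500)
        assert mask[7]
        assert obs[7] < 0  # LH>RH loads negative under the orientation

    def test_floor_warning_when_reps_too_small(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        y = np.array(["LH", "RH"] * 10)
        subj = np.repeat([f"s{i}" for i in range(10)], 2)
        with pytest.warns(UserWarning, match="p-floor"):
            enr.connection_significance(X, y, subj, reps=100, alpha=0.01, seed=0)

    def test_sign_summary_conventions(self):
        scalings = np.array([-2.0, -1.0, 0.5, 3.0])
        mask = np.array([True, True, False, True])
        assert enr.sign_summary(scalings, mask) == (2, 1)
        # one-sign case
        assert enr.sign_summary(np.array([-1.0, -2.0]), np.array([True, True])) == (2, 0)


class TestMaskSymmetry:
    def test_mask_maps_to_symmetric_matrix(self):
        rng = np.random.default_rng(5)
        p = 12
        n_feat = p * (p - 1) // 2
        for _ in range(10):
            mask = rng.random(n_feat) < 0.2
            m = hemi_mask_to_matrix(mask, p)
            assert np.array_equal(m, m.T)
            assert not m.diagonal().any()


class TestRecoveryAndCalibration:
    def test_planted_groups_recovered(self, enrichment_recovery):
        """The three planted network groups reach FDR-corrected p < .05 in
        >= 90% of 20 seeds, and no unplanted group out-counts them."""
        hits = 0
        for res in enrichment_recovery:
            if all(v < 0.05 for v in res["planted_fdr"].values()):
                hits += 1
            planted_median = np.median(list(res["planted_counts"].values()))
            assert max(res["other_counts"].values()) <= planted_median
        assert hits >= 18

    def test_planted_direction_is_lh_dominant(self, enrichment_recovery):
        for res in enrichment_recovery:
            assert res["n_lh_greater"] > res["n_rh_greater"]

    def test_floor_and_symmetry_invariants_on_every_run(self, enrichment_recovery):
        for res in enrichment_recovery:
            assert res["min_connection_p"] >= res["floor"]
            assert res["min_group_p"] >= res["floor"]
            m = hemi_mask_to_matrix(res["mask"], res["parcels_per_hemi"])
            assert np.array_equal(m, m.T)

    def test_type_i_calibration_on_null_cohorts(self, null_calibration):
        """Group-level rejections on null cohorts stay at the nominal level.

        The group permutation p-values are discrete (counts are small
        integers), so the exact attainable level below .05 is computed from
        the closed-form hypergeometric shuffle null; the observed rejection
        fraction must (a) not exceed the nominal binomial upper bound and
        (b) match binomial bounds around the attainable level.
        """
        pvals = null_calibration["group_pvals"]
        alpha = null_calibration["alpha_group"]
        n = len(pvals)
        observed = float((pvals < alpha).mean())
        nominal_upper = alpha + 1.96 * np.sqrt(alpha * (1 - alpha) / n)
        assert observed <= nominal_upper
        e = null_calibration["expected_rate"]
        half = 1.96 * np.sqrt(max(e * (1 - e), 1e-12) / n)
        assert e <= alpha  # a valid (conservative) test
        assert abs(observed - e) <= max(half, 2 / n)

    def test_connection_level_type_i_rate(self, null_calibration):
        """Connection-level significant fraction ~ alpha on null cohorts."""
        rates = null_calibration["connection_rates"]
        alpha = null_calibration["alpha_mask"]
        assert abs(rates.mean() - alpha) < alpha  # within [0, 2*alpha]

    def test_attainable_level_is_conservative(self, null_calibration):
        assert null_calibration["expected_rate"] <= null_calibration["alpha_group"]
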