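import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from infoconn.connectivity import (
    compute_icm,
    edge_change,
    edge_contrast_table,
    edge_vector,
    fdr_bh,
    group_edge_contrast,
    permutation_null,
)
from infoconn.errors import InvalidArgumentError
from infoconn.similarity import rsm_stack, within_context_rsm
from infoconn.synthetic import GenerativeModel, generate_pattern_dataset


def toy_rsms(rng, n_rois=3, n_voxels=20):
    """5-ROI-capable toy: 3 runs x 2 trials, one RSM per ROI."""
    trials = pd.DataFrame(
        {
            "trial": np.arange(6),
            "run": [0, 0, 1, 1, 2, 2],
            "context": ["spatial"] * 6,
            "correct": [True] * 6,
            "included": [True] * 6,
        }
    )
    return {
        rid: within_context_rsm(
            rng.standard_normal((6, n_voxels)), trials, roi_id=rid
        )
        for rid in range(1, n_rois + 1)
    }


class TestComputeIcm:
    def test_brute_force_oracle(self, rng):
        """3-ROI toy: ICM entries match nested-loop Pearson over RSM vectors."""
        rsms = toy_rsms(rng)
        icm = compute_icm(rsms)
        from infoconn.similarity import vectorize_rsm

        for a, i in enumerate(icm.roi_ids):
            for b, j in enumerate(icm.roi_ids):
                if a == b:
                    assert np.isnan(icm.z[a, b])
                    continue
                vi, _ = vectorize_rsm(rsms[i])
                vj, _ = vectorize_rsm(rsms[j])
                num = np.sum((vi - vi.mean()) * (vj - vj.mean()))
                den = np.sqrt(np.sum((vi - vi.mean()) ** 2) * np.sum((vj - vj.mean()) ** 2))
                assert icm.z[a, b] == pytest.approx(np.arctanh(num / den), abs=1e-12)

    def test_duplicate_roi_clipped_max(self, rng):
        rsms = toy_rsms(rng, n_rois=2)
        rsms[2] = rsms[1]  # identical patterns -> identical RSM
        icm = compute_icm(rsms)
        assert icm.z[0, 1] > 8.0

    def test_symmetry(self, rng):
        icm = compute_icm(toy_rsms(rng, n_rois=5))
        mask = ~np.isnan(icm.z)
        np.testing.assert_array_equal(icm.z[mask], icm.z.T[mask])

    def test_single_roi_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            compute_icm({1: toy_rsms(rng, 1)[1]})

    def test_independent_noise_rois_null(self, small_design, small_atlas):
        zs = []
        for seed in range(50):
            m = GenerativeModel(n_rois=small_atlas.n_rois, seed=seed)
            ps = generate_pattern_dataset(
                small_design, small_atlas, m, phases=("encoding",)
            )
            icm = compute_icm(rsm_stack(ps, context="spatial"))
            zs.append(edge_vector(icm.z))
        zs = np.concatenate(zs)
        assert abs(zs.mean()) < 3.0 / np.sqrt(zs.size)


class TestEdgeChange:
    def test_identical_icms_zero(self, rng):
        icm = compute_icm(toy_rsms(rng))
        d = edge_change(icm, icm)
        assert np.all(d[~np.isnan(d)] == 0)

    def test_swap_flips_sign(self, rng):
        a = compute_icm(toy_rsms(rng))
        b = compute_icm(toy_rsms(rng))
        d1, d2 = edge_change(a, b), edge_change(b, a)
        mask = ~np.isnan(d1)
        np.testing.assert_allclose(d1[mask], -d2[mask], atol=1e-12)

    def test_hand_built_subtraction(self, rng):
        a = compute_icm(toy_rsms(rng))
        b = compute_icm(toy_rsms(rng))
        d = edge_change(a, b)
        assert d[0, 1] == pytest.approx(b.z[0, 1] - a.z[0, 1], abs=1e-12)

    def test_roi_mismatch_rejected(self, rng):
        a = compute_icm(toy_rsms(rng, n_rois=3))
        b = compute_icm(toy_rsms(rng, n_rois=4))
        with pytest.raises(InvalidArgumentError):
            edge_change(a, b)


class TestGroupEdgeContrast:
    def test_constant_deltas_zero_t(self):
        deltas = np.ones((12, 5))
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        with pytest.warns(UserWarning):
            t = group_edge_contrast(deltas, groups, "a")
        assert np.all(t == 0)

    def test_matches_scipy_welch(self, rng):
        deltas = rng.standard_normal((30, 8))
        groups = np.array(["t"] * 10 + ["o"] * 20)
        t = group_edge_contrast(deltas, groups, "t")
        for e in range(8):
            ref = stats.ttest_ind(
                deltas[:10, e], deltas[10:, e], equal_var=False
            ).statistic
            assert t[e] == pytest.approx(ref, rel=1e-10)

    def test_shifted_edge_attains_max_t(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            deltas = r.standard_normal((72, 6))
            deltas[:24, 3] += 1.0  # +1 sd on edge 3 for the target group
            groups = np.array(["t"] * 24 + ["o"] * 48)
            t = group_edge_contrast(deltas, groups, "t")
            hits += np.argmax(np.abs(t)) == 3
        assert hits >= 95

    def test_empty_group_rejected(self, rng):
        deltas = rng.standard_normal((5, 3))
        with pytest.raises(InvalidArgumentError):
            group_edge_contrast(deltas, np.array(["a"] * 5), "b")


class TestPermutationNull:
    def test_extreme_observed_floor_p(self, rng):
        deltas = rng.standard_normal((24, 4))
        deltas[:8, 2] += 50.0  # unbeatable effect
        groups = np.array(["t"] * 8 + ["o"] * 16)
        _, p = permutation_null(deltas, groups, "t", n_perm=99, seed=0)
        assert p[2] == pytest.approx(1.0 / 100.0)

    def test_deterministic_given_seed(self, rng):
        deltas = rng.standard_normal((18, 6))
        groups = np.array(["t"] * 6 + ["o"] * 12)
        _, p1 = permutation_null(deltas, groups, "t", n_perm=200, seed=5)
        _, p2 = permutation_null(deltas, groups, "t", n_perm=200, seed=5)
        np.testing.assert_array_equal(p1, p2)

    def test_null_p_uniform(self):
        """Exchangeable null: pooled edge p-values are ~U(0,1)."""
        ps = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            deltas = r.standard_normal((30, 200))
            groups = np.array(["t"] * 10 + ["o"] * 20)
            _, p = permutation_null(deltas, groups, "t", n_perm=400, seed=seed)
            ps.append(p)
        ps = np.concatenate(ps)
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05

    def test_converges_to_analytic_t(self, rng):
        deltas = rng.standard_normal((40, 3))
        deltas[:20, 0] += 0.6
        groups = np.array(["t"] * 20 + ["o"] * 20)
        t_obs, p_perm = permutation_null(deltas, groups, "t", n_perm=10_000, seed=3)
        for e in range(3):
            p_ref = stats.ttest_ind(
                deltas[:20, e], deltas[20:, e], equal_var=False
            ).pvalue
            assert abs(p_perm[e] - p_ref) < 0.01

    def test_bad_n_perm_rejected(self, rng):
        deltas = rng.standard_normal((10, 2))
        groups = np.array(["t"] * 5 + ["o"] * 5)
        with pytest.raises(InvalidArgumentError):
            permutation_null(deltas, groups, "t", n_perm=0)


class TestFdrBh:
    def test_hand_worked_example(self):
        # thresholds .0125, .025, .0375, .05 -> reject the 2 smallest
        reject, q = fdr_bh(np.array([0.01, 0.02, 0.04, 0.2]), q=0.05)
        assert reject.tolist() == [True, True, False, False]
        assert q[0] == pytest.approx(0.04)
        assert q[1] == pytest.approx(0.04)
        assert q[2] == pytest.approx(0.04 * 4 / 3)
        assert q[3] == pytest.approx(0.2)

    def test_all_ones_reject_none(self):
        reject, _ = fdr_bh(np.ones(5), q=0.05)
        assert not reject.any()

    def test_single_p_raw_threshold(self):
        reject, q = fdr_bh(np.array([0.04]), q=0.05)
        assert reject[0]
        assert q[0] == pytest.approx(0.04)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(1e-6, 1.0, size=200)
        reject, q = fdr_bh(p, q=0.05)
        ref_reject, ref_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, ref_reject)
        np.testing.assert_allclose(q, ref_q, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fdr_bh(np.array([0.0, 0.5]))
        with pytest.raises(InvalidArgumentError):
            fdr_bh(np.array([0.5, 1.5]))


class TestEdgeContrastTable:
    def test_masked_edges_dropped_listwise(self, rng):
        deltas = rng.standard_normal((12, 4, 4))
        deltas = (deltas + deltas.transpose(0, 2, 1)) / 2
        deltas[3, 0, 1] = deltas[3, 1, 0] = np.nan
        groups = np.array(["t"] * 4 + ["o"] * 8)
        table = edge_contrast_table(
            deltas, groups, (1, 2, 3, 4), "t", n_perm=50, seed=0
        )
        assert len(table) == 5  # 6 edges minus the masked one
        assert not ((table.roi_i == 1) & (table.roi_j == 2)).any()

    def test_direction_labels(self, rng):
        deltas = rng.standard_normal((20, 3, 3)) * 0.1
        deltas[:7, 0, 1] = deltas[:7, 1, 0] = 2.0
        deltas[:7, 0, 2] = deltas[:7, 2, 0] = -2.0
        groups = np.array(["t"] * 7 + ["o"] * 13)
        table = edge_contrast_table(deltas, groups, (1, 2, 3), "t", n_perm=99, seed=1)
        up = table[(table.roi_i == 1) & (table.roi_j == 2)].iloc[0]
        down = table[(table.roi_i == 1) & (table.roi_j == 3)].iloc[0]
        assert up["direction"] == "post>pre"
        assert down["direction"] == "post<pre"
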