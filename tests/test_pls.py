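"""Two-group behavioral PLS: cross-block build, SVD structure, inference."""

import numpy as np
import pytest

from blockcpm import (
    SimulationConfig, balanced_pls, bootstrap_saliences, build_crossblock,
    fit_pls, lv_behavior_correlations, permutation_test, pls_svd,
    simulate_study, stage_rng, subject_average_edges,
)


class TestCrossblock:
    def test_behavior_equal_to_one_edge(self, rng):
        y = rng.normal(size=40)
        x = rng.normal(size=(40, 10))
        x[:, 4] = y
        R = build_crossblock(x, y, ["g"] * 40)
        assert R.shape == (1, 10)
        assert R[0, 4] == pytest.approx(1.0, abs=1e-10)
        assert np.abs(np.delete(R[0], 4)).max() < 0.5

    def test_identical_groups_give_identical_rows(self, rng):
        x = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        R = build_crossblock(np.vstack([x, x]), np.concatenate([y, y]),
                             ["a"] * 30 + ["b"] * 30)
        assert np.allclose(R[0], R[1], atol=1e-12)

    def test_common_vs_differential_sign_structure(self):
        """Generator's common edges load same-sign in both rows; the
        differential edges load with opposite signs."""
        cfg = SimulationConfig(
            p=30, n_per_group=2000, n_sites=4,
            mask_sizes={"sa_pos": 30, "sa_neg": 20, "wm_pos": 30, "wm_neg": 20},
            overlap_spec={}, n_common=40, n_differential=40)
        ds = simulate_study(cfg, seed=21, keep_connectomes=False)
        edges = subject_average_edges(ds.subjects, ds.behavior, ds.ground_truth,
                                      cfg, seed=stage_rng(21, 3))
        import pandas as pd
        subj = pd.DataFrame([vars(s) for s in ds.subjects])
        acc0 = (ds.behavior[ds.behavior["condition"] == "zero_back"]
                .groupby("subject_id")["accuracy"].mean())
        y = acc0.loc[subj["subject_id"]].to_numpy()
        R = build_crossblock(edges, y, subj["group"].to_numpy())
        gt = ds.ground_truth
        common = R[:, gt.common_edges]
        assert (np.sign(common[0]) == np.sign(common[1])).mean() > 0.95
        diff = R[:, gt.differential_edges]
        assert (np.sign(diff[0]) == -np.sign(diff[1])).mean() > 0.95

    def test_constant_behavior_within_group_rejected(self, rng):
        x = rng.normal(size=(20, 5))
        y = np.concatenate([np.ones(10), rng.normal(size=10)])
        with pytest.raises(ValueError, match="constant"):
            build_crossblock(x, y, ["a"] * 10 + ["b"] * 10)


class TestSVD:
    def test_rank_one_gives_full_first_fraction(self, rng):
        row = rng.normal(size=50)
        R = np.vstack([row, 2 * row])
        U, s, V, frac = pls_svd(R)
        assert frac[0] == pytest.approx(1.0, abs=1e-12)
        assert frac[1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_equal_rows_split_evenly(self):
        R = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        _, _, _, frac = pls_svd(R)
        assert np.allclose(frac, [0.5, 0.5])

    def test_orthonormality_and_reconstruction(self, rng):
        R = rng.normal(size=(2, 100))
        U, s, V, frac = pls_svd(R)
        assert np.allclose(U.T @ U, np.eye(2), atol=1e-10)
        assert np.allclose(V.T @ V, np.eye(2), atol=1e-10)
        assert np.linalg.norm(R - V @ np.diag(s) @ U.T) <= 1e-8 * np.linalg.norm(R)
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(s) <= 0)

    def test_sigma_frac_scale_invariant(self, rng):
        R = rng.normal(size=(2, 30))
        _, _, _, f1 = pls_svd(R)
        _, _, _, f2 = pls_svd(-17.3 * R)
        assert np.allclose(f1, np.sort(f2)[::-1]) or np.allclose(f1, f2)

    def test_sign_convention_is_deterministic(self, rng):
        R = rng.normal(size=(2, 40))
        U1, _, V1, _ = pls_svd(R)
        U2, _, V2, _ = pls_svd(R.copy())
        assert np.array_equal(U1, U2) and np.array_equal(V1, V2)
        for l in range(2):
            assert U1[np.argmax(np.abs(U1[:, l])), l] > 0


class TestPermutation:
    def test_seed_determinism(self, rng):
        x = rng.normal(size=(40, 20))
        y = rng.normal(size=40)
        g = ["a"] * 20 + ["b"] * 20
        p1 = permutation_test(x, y, g, n_perm=100, seed=9)
        p2 = permutation_test(x, y, g, n_perm=100, seed=9)
        assert np.array_equal(p1, p2)

    def test_strong_common_effect_reaches_floor(self):
        """Planted common brain-behavior signal: LV1 p at the 1/(n+1) floor."""
        floor_hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 250
            y = r.normal(size=2 * n)
            x = r.normal(size=(2 * n, 60))
            x[:, :20] += 0.5 * y[:, None]    # common effect, both groups
            g = ["a"] * n + ["b"] * n
            p = permutation_test(x, y, g, n_perm=100, seed=seed)
            floor_hits += p[0] == pytest.approx(1 / 101)
        assert floor_hits >= 9


class TestBootstrap:
    def test_planted_common_edges_recovered(self):
        """At a strong planted effect and large n, at least 80% of the
        common edges clear |Z_BR| >= 3 on LV1, with few false positives
        among the truly-null edges."""
        import pandas as pd
        cfg = SimulationConfig(
            p=60, n_per_group=1000, n_sites=4,
            mask_sizes={"sa_pos": 60, "sa_neg": 40, "wm_pos": 60, "wm_neg": 40},
            overlap_spec={}, n_common=60, n_differential=60)
        ds = simulate_study(cfg, seed=31, keep_connectomes=False)
        edges = subject_average_edges(ds.subjects, ds.behavior, ds.ground_truth,
                                      cfg, seed=stage_rng(31, 3))
        subj = pd.DataFrame([vars(s) for s in ds.subjects])
        acc0 = (ds.behavior[ds.behavior["condition"] == "zero_back"]
                .groupby("subject_id")["accuracy"].mean())
        y = acc0.loc[subj["subject_id"]].to_numpy()
        _, z_br, sig = bootstrap_saliences(edges, y, subj["group"].to_numpy(),
                                           n_boot=200, seed=5)
        gt = ds.ground_truth
        assert np.isin(gt.common_edges, sig[0]).mean() >= 0.8
        planted = set(gt.common_edges) | set(gt.differential_edges)
        for c in ("sa", "wm"):
            planted |= set(gt.planted_edge_indices(c))
        null = np.setdiff1d(np.arange(edges.shape[1]), sorted(planted))
        assert np.isin(null, sig[0]).mean() <= 0.005

    def test_zero_salience_gives_zero_ratio(self, rng):
        # an all-zero edge column has zero salience in every resample
        x = rng.normal(size=(60, 10))
        x[:, 7] = 0.0
        y = rng.normal(size=60)
        _, z_br, _ = bootstrap_saliences(x, y, ["a"] * 30 + ["b"] * 30,
                                         n_boot=100, seed=2)
        assert z_br[7, 0] == 0.0 and z_br[7, 1] == 0.0

    def test_ratio_stability_under_more_resamples(self, small_edges):
        d = small_edges
        _, z1, _ = bootstrap_saliences(d["edges"], d["behavior"], d["groups"],
                                       n_boot=200, seed=3)
        _, z2, _ = bootstrap_saliences(d["edges"], d["behavior"], d["groups"],
                                       n_boot=400, seed=3)
        gt = d["dataset"].ground_truth
        strong = gt.common_edges
        rel = np.abs(z1[strong, 0] - z2[strong, 0]) / np.abs(z2[strong, 0])
        assert np.median(rel) < 0.10


class TestBalanced:
    def test_equal_groups_match_single_run(self, rng):
        x1 = rng.normal(size=(40, 15))
        x2 = rng.normal(size=(40, 15))
        y1, y2 = rng.normal(size=40), rng.normal(size=40)
        avg = balanced_pls(x1, y1, x2, y2, n_rep=5, seed=0)
        single = fit_pls(np.vstack([x1, x2]), np.concatenate([y1, y2]),
                         ["large"] * 40 + ["small"] * 40)
        assert np.allclose(avg.sigma_frac, single.sigma_frac, atol=1e-12)
        assert np.allclose(np.abs(avg.U), np.abs(single.U), atol=1e-10)

    def test_match_n_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            balanced_pls(rng.normal(size=(10, 5)), rng.normal(size=10),
                         rng.normal(size=(8, 5)), rng.normal(size=8),
                         match_n=20, seed=0)

    def test_unbalanced_design_tracks_equal_n_truth(self):
        """1545-vs-754-style imbalance: averaged σ fractions stay within
        0.02 of the balanced ground-truth run (scaled sizes)."""
        r = np.random.default_rng(3)
        n_large, n_small, e = 400, 180, 80
        y_l, y_s = r.normal(size=n_large), r.normal(size=n_small)
        x_l = r.normal(size=(n_large, e))
        x_s = r.normal(size=(n_small, e))
        x_l[:, :25] += 0.4 * y_l[:, None]
        x_s[:, :25] += 0.4 * y_s[:, None]
        x_l[:, 25:45] += 0.3 * y_l[:, None]
        x_s[:, 25:45] -= 0.3 * y_s[:, None]
        avg = balanced_pls(x_l, y_l, x_s, y_s, n_rep=50, seed=4)
        truth = fit_pls(np.vstack([x_l[:n_small], x_s]),
                        np.concatenate([y_l[:n_small], y_s]),
                        ["large"] * n_small + ["small"] * n_small)
        assert np.abs(avg.sigma_frac - truth.sigma_frac).max() < 0.02


class TestLVBehavior:
    def test_noiseless_rank_one_gives_perfect_correlation(self, rng):
        y = rng.normal(size=60)
        x = np.outer(y, rng.normal(size=12))
        g = ["a"] * 30 + ["b"] * 30
        res = fit_pls(x, y, g)
        out = lv_behavior_correlations(res, x, y, g, n_boot=100, seed=0)
        for gname in ("a", "b"):
            assert abs(out[gname]["r"]) == pytest.approx(1.0, abs=1e-8)
            lo, hi = out[gname]["ci"]
            assert lo <= out[gname]["r"] + 1e-9 and out[gname]["r"] <= hi + 1e-9

    def test_common_lv_same_sign_differential_lv_opposite(self, small_edges):
        d = small_edges
        res = fit_pls(d["edges"], d["behavior"], d["groups"])
        out1 = lv_behavior_correlations(res, d["edges"], d["behavior"], d["groups"],
                                        n_boot=100, seed=1, lv=0)
        out2 = lv_behavior_correlations(res, d["edges"], d["behavior"], d["groups"],
                                        n_boot=100, seed=1, lv=1)
        rs1 = [out1[g]["r"] for g in out1]
        rs2 = [out2[g]["r"] for g in out2]
        assert np.sign(rs1[0]) == np.sign(rs1[1])
        assert np.sign(rs2[0]) == -np.sign(rs2[1])


def test_common_signal_monotonically_dominates_lv1():
    """Raising the common-effect size with the differential effect fixed
    makes LV1's covariance fraction non-decreasing."""
    fracs = []
    for beta_c in (0.02, 0.033, 0.05):
        cfg = SimulationConfig(
            p=30, n_per_group=400, n_sites=4,
            mask_sizes={"sa_pos": 20, "sa_neg": 15, "wm_pos": 20, "wm_neg": 15},
            overlap_spec={}, n_common=40, n_differential=40,
            beta_common=beta_c, beta_diff=0.025)
        ds = simulate_study(cfg, seed=5, keep_connectomes=False)
        edges = subject_average_edges(ds.subjects, ds.behavior, ds.ground_truth,
                                      cfg, seed=stage_rng(5, 3))
        import pandas as pd
        subj = pd.DataFrame([vars(s) for s in ds.subjects])
        acc0 = (ds.behavior[ds.behavior["condition"] == "zero_back"]
                .groupby("subject_id")["accuracy"].mean())
        res = fit_pls(edges, acc0.loc[subj["subject_id"]].to_numpy(),
                      subj["group"].to_numpy())
        fracs.append(res.sigma_frac[0])
    assert fracs[0] <= fracs[1] <= fracs[2]
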