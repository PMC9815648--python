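"""Ground-truth construction, subject/behavior/connectome generation,
dataset materialization and seed determinism."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from blockcpm import (
    SimulationConfig, generate_dataset, make_ground_truth, simulate_behavior,
    simulate_connectomes, simulate_study, simulate_subjects, stage_rng,
    subject_average_edges, vectorize,
)
from blockcpm.connectome import n_edges
from blockcpm.synth import nearest_correlation, subjects_frame


class TestGroundTruth:
    def test_exact_sizes_and_forced_overlaps(self):
        gt = make_ground_truth(
            268, {"sa_pos": 757, "sa_neg": 630, "wm_pos": 1674, "wm_neg": 1203},
            {("sa_pos", "wm_pos"): 37, ("sa_neg", "wm_neg"): 33}, seed=1)
        assert {k: m.n_edges for k, m in gt.masks.items()} == \
            {"sa_pos": 757, "sa_neg": 630, "wm_pos": 1674, "wm_neg": 1203}
        assert len(gt.masks["sa_pos"].edge_set("pos")
                   & gt.masks["wm_pos"].edge_set("pos")) == 37
        assert len(gt.masks["sa_neg"].edge_set("neg")
                   & gt.masks["wm_neg"].edge_set("neg")) == 33
        # pairs without a requested overlap are disjoint
        assert not (gt.masks["sa_pos"].edge_set("any")
                    & gt.masks["wm_neg"].edge_set("any"))

    def test_saturated_mask_is_complete_graph(self):
        gt = make_ground_truth(10, {"m": 45}, {}, seed=0)
        assert gt.masks["m"].n_edges == n_edges(10) == 45

    def test_seed_determinism(self):
        a = make_ground_truth(268, seed=1)
        b = make_ground_truth(268, seed=1)
        for name in a.masks:
            assert np.array_equal(a.masks[name].w, b.masks[name].w)

    def test_infeasible_requests_rejected(self):
        with pytest.raises(ValueError, match="available"):
            make_ground_truth(10, {"m": 46}, {})
        with pytest.raises(ValueError, match="exceeds"):
            make_ground_truth(20, {"a": 10, "b": 10}, {("a", "b"): 11})

    def test_masks_are_valid_network_masks(self):
        gt = make_ground_truth(30, {"a": 50, "b": 40}, {("a", "b"): 5}, seed=3)
        for m in gt.masks.values():
            assert np.array_equal(m.w, m.w.T)
            assert np.all(np.diag(m.w) == 0)


class TestSubjects:
    def test_ability_correlation_converges(self):
        subs = simulate_subjects(10000, ability_corr=0.62, seed=1)
        df = subjects_frame(subs)
        youth = df[df.group == "youth"]
        r = np.corrcoef(youth.a_sa, youth.a_wm)[0, 1]
        assert r == pytest.approx(0.62, abs=0.02)

    def test_independent_abilities_when_uncorrelated(self):
        subs = simulate_subjects(5000, ability_corr=0.0, seed=2)
        df = subjects_frame(subs)
        r = np.corrcoef(df[df.group == "youth"].a_sa, df[df.group == "youth"].a_wm)[0, 1]
        assert abs(r) < 0.05

    def test_zero_offsets_equalize_group_means(self):
        subs = simulate_subjects(4000, group_offsets=(0.0, 0.0), seed=3)
        df = subjects_frame(subs)
        gap = df[df.group == "adult"].a_sa.mean() - df[df.group == "youth"].a_sa.mean()
        assert abs(gap) < 0.08

    def test_round_robin_site_balance(self):
        df = subjects_frame(simulate_subjects(90, n_sites=18, seed=4))
        counts = df[df.group == "youth"].site_id.value_counts()
        assert counts.max() - counts.min() <= 1
        assert len(counts) == 18

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            simulate_subjects(10, ability_corr=1.0)


class TestBehavior:
    cfg = SimulationConfig(p=20, n_per_group=200, n_sites=2,
                           mask_sizes={"sa_pos": 10, "sa_neg": 5,
                                       "wm_pos": 10, "wm_neg": 5},
                           overlap_spec={}, n_common=0, n_differential=0)

    def test_noiseless_accuracy_is_deterministic_offsets(self):
        import dataclasses
        cfg = dataclasses.replace(
            self.cfg, lambda_ability=0.0, lambda_cross=0.0, lambda_state=0.0,
            accuracy_noise_sd=0.0, motion_effect=0.0)
        subs = simulate_subjects(5, n_sites=2, seed=0)
        beh = simulate_behavior(subs, cfg, seed=1)
        run1_neutral = beh[(beh.run_id == "run_1") & (beh.stimulus == "neutral_face")]
        assert run1_neutral.accuracy.nunique() == 1
        assert run1_neutral.accuracy.iloc[0] == pytest.approx(cfg.base_accuracy)

    def test_condition_specific_ability_loading(self):
        """With zero cross-loading, a_SA predicts 0-back accuracy better
        than it predicts 2-back accuracy."""
        subs = simulate_subjects(2000, ability_corr=0.0, seed=5)
        beh = simulate_behavior(subs, self.cfg, seed=6)
        df = subjects_frame(subs).set_index("subject_id")
        acc = beh.groupby(["subject_id", "condition"]).accuracy.mean().unstack()
        a_sa = df.loc[acc.index, "a_sa"]
        r0 = np.corrcoef(a_sa, acc["zero_back"])[0, 1]
        r2 = np.corrcoef(a_sa, acc["two_back"])[0, 1]
        assert r0 > r2 + 0.2

    def test_place_blocks_hardest(self):
        subs = simulate_subjects(500, seed=7)
        beh = simulate_behavior(subs, self.cfg, seed=8)
        means = beh.groupby("stimulus").accuracy.mean()
        assert means["place"] < means["neutral_face"]

    def test_accuracy_clipped_to_unit_interval(self):
        subs = simulate_subjects(200, seed=9)
        beh = simulate_behavior(subs, self.cfg, seed=10)
        assert beh.accuracy.between(0, 1).all()


class TestConnectomes:
    small = SimulationConfig(p=20, n_per_group=10, n_sites=2,
                             mask_sizes={"sa_pos": 15, "sa_neg": 10,
                                         "wm_pos": 15, "wm_neg": 10},
                             overlap_spec={}, n_common=5, n_differential=5)

    def test_no_effects_no_noise_gives_shared_matrix(self):
        import dataclasses
        cfg = dataclasses.replace(
            self.small, beta_mask=0.0, beta_common=0.0, beta_diff=0.0,
            state_gain=0.0, edge_noise_sd=0.0, adult_strength_offset=0.0)
        ds = simulate_study(cfg, seed=12)
        mats = [vectorize(em.z) for ems in ds.connectomes.values() for em in ems]
        assert all(np.allclose(m, mats[0], atol=1e-12) for m in mats)

    def test_noiseless_strength_tracks_ability_exactly(self):
        """With edge noise and state noise off, mask strength is a perfect
        linear function of ability: correlation exactly 1."""
        import dataclasses
        from blockcpm import network_strength
        cfg = dataclasses.replace(self.small, edge_noise_sd=0.0, state_gain=0.0,
                                  n_per_group=30)
        ds = simulate_study(cfg, seed=13)
        mask = ds.ground_truth.combined_mask("sa")
        df = subjects_frame(ds.subjects)
        youth = df[df.group == "youth"]
        strengths = [network_strength(ds.connectomes[sid][0], mask)
                     for sid in youth.subject_id]
        r = np.corrcoef(strengths, youth.a_sa)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_planted_effect_recovered_across_subjects(self):
        cfg = SimulationConfig(
            p=30, n_per_group=1000, n_sites=2,
            mask_sizes={"sa_pos": 30, "sa_neg": 20, "wm_pos": 20, "wm_neg": 15},
            overlap_spec={}, n_common=0, n_differential=0)
        ds = simulate_study(cfg, seed=14, keep_connectomes=False)
        edges = subject_average_edges(ds.subjects, ds.behavior, ds.ground_truth,
                                      cfg, seed=stage_rng(14, 3))
        df = subjects_frame(ds.subjects)
        w = ds.ground_truth.mask_vector("sa_pos")
        strength = edges @ w
        assert np.corrcoef(strength, df.a_sa)[0, 1] > 0.5

    def test_differential_edges_flip_sign_by_group(self):
        """corr(edge, behavior) has opposite signs in the two groups for
        the planted differential edges (large-sample check)."""
        cfg = SimulationConfig(
            p=20, n_per_group=2500, n_sites=2,
            mask_sizes={"sa_pos": 10, "sa_neg": 5, "wm_pos": 10, "wm_neg": 5},
            overlap_spec={}, n_common=0, n_differential=30)
        ds = simulate_study(cfg, seed=15, keep_connectomes=False)
        edges = subject_average_edges(ds.subjects, ds.behavior, ds.ground_truth,
                                      cfg, seed=stage_rng(15, 3))
        df = subjects_frame(ds.subjects)
        acc0 = (ds.behavior[ds.behavior.condition == "zero_back"]
                .groupby("subject_id").accuracy.mean())
        y = acc0.loc[df.subject_id].to_numpy()
        gt = ds.ground_truth
        signs = {}
        for group in ("youth", "adult"):
            sel = (df.group == group).to_numpy()
            x = edges[sel][:, gt.differential_edges]
            xc = x - x.mean(0)
            yc = y[sel] - y[sel].mean()
            signs[group] = np.sign((xc * yc[:, None]).sum(0))
        assert (signs["youth"] == -signs["adult"]).mean() > 0.95

    def test_timeseries_fc_converges_to_target(self):
        """As the block grows long, estimated FC approaches the target
        correlation matrix (max |Δr| < 0.05 at 10⁴ TRs)."""
        import dataclasses
        from blockcpm import BlockRecord, block_fc
        cfg = dataclasses.replace(self.small, mode="timeseries", n_per_group=1,
                                  n_runs=1, blocks_per_run=1, block_len_trs=10000,
                                  edge_noise_sd=0.0, state_gain=0.0)
        ds = simulate_study(cfg, seed=16)
        sid = ds.subjects[0].subject_id
        row = ds.behavior.iloc[0]
        from blockcpm.synth import baseline_mu, _subject_base_vector
        from blockcpm.connectome import unvectorize
        mu_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=16, spawn_key=(3,)))
        mu = baseline_mu(cfg.p, cfg, mu_rng)
        target = nearest_correlation(
            np.tanh(unvectorize(_subject_base_vector(ds.subjects[0],
                                                     ds.ground_truth, cfg, mu),
                                cfg.p)) + np.eye(cfg.p))
        blk = BlockRecord(run_id="run_1", block_index=0, condition=row.condition,
                          stimulus=row.stimulus, onset_tr=int(row.onset_tr),
                          offset_tr=int(row.offset_tr), fd_mean=0.1, fd_max=0.5)
        em = block_fc(ds.connectomes[sid]["run_1"], blk)
        est_r = np.tanh(em.z)
        np.fill_diagonal(est_r, 1.0)
        assert np.abs(est_r - target).max() < 0.05


class TestNearestCorrelation:
    def test_psd_and_unit_diagonal(self, rng):
        raw = rng.normal(size=(15, 15))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 1.0)
        out = nearest_correlation(raw)
        assert np.linalg.eigvalsh(out).min() >= -1e-10
        assert np.allclose(np.diag(out), 1.0)

    def test_valid_matrix_unchanged(self, rng):
        a = rng.normal(size=(30, 8))
        c = np.corrcoef(a, rowvar=False)
        assert np.allclose(nearest_correlation(c), c, atol=1e-12)


class TestGenerateDataset:
    def test_reproducible_checksums_and_layout(self, tmp_path):
        cfg = SimulationConfig(
            p=15, n_per_group=3, n_sites=2,
            mask_sizes={"sa_pos": 8, "sa_neg": 5, "wm_pos": 8, "wm_neg": 5},
            overlap_spec={}, n_common=3, n_differential=3, n_regions=3)
        m1 = generate_dataset(cfg, seed=42, out_dir=tmp_path / "a")
        m2 = generate_dataset(cfg, seed=42, out_dir=tmp_path / "b")
        assert m1["files"] == m2["files"]
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest["seed"] == 42
        assert (tmp_path / "a" / "subjects.tsv").exists()
        assert (tmp_path / "a" / "masks" / "sa_pos.tsv").exists()

    def test_timeseries_mode_block_shapes(self, tmp_path):
        cfg = SimulationConfig(
            p=12, n_per_group=2, n_sites=2, mode="timeseries",
            mask_sizes={"sa_pos": 6, "sa_neg": 4, "wm_pos": 6, "wm_neg": 4},
            overlap_spec={}, n_common=2, n_differential=2, n_regions=3)
        generate_dataset(cfg, seed=1, out_dir=tmp_path / "ts")
        beh = pd.read_csv(tmp_path / "ts" / "behavior.tsv", sep="\t")
        ts_files = sorted((tmp_path / "ts" / "timeseries").glob("*.tsv"))
        assert ts_files
        ts = pd.read_csv(ts_files[0], sep="\t")
        assert ts.shape[1] == 12
        # every block window fits inside its run and spans 30 or 31 TRs
        lengths = beh.offset_tr - beh.onset_tr
        assert set(lengths.unique()) == {30, 31}

    def test_nonempty_target_rejected(self, tmp_path):
        d = tmp_path / "busy"
        d.mkdir()
        (d / "junk.txt").write_text("x")
        cfg = SimulationConfig(p=10, n_per_group=1, n_sites=1,
                               mask_sizes={"m": 5}, overlap_spec={},
                               n_common=0, n_differential=0)
        with pytest.raises(FileExistsError):
            generate_dataset(cfg, seed=0, out_dir=d)


def test_stage_seed_isolation():
    """Regenerating one stage from the global seed reproduces it exactly."""
    a = stage_rng(7, 1).standard_normal(5)
    b = stage_rng(7, 1).standard_normal(5)
    c = stage_rng(7, 2).standard_normal(5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
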