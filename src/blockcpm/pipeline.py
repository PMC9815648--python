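"""End-to-end orchestration: simulate → strength → cpm → overlap → lesion
→ pls → report, driven by one validated config, with per-stage seeds, an
exclusion cascade log, and a checksummed results bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome as cn
from . import cpm as cpm_mod
from . import lesion as lesion_mod
from . import netstats
from . import pls as pls_mod
from .synth import SimulationConfig, simulate_study, stage_rng

logger = logging.getLogger("blockcpm")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration (exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3)."""


_DEFAULT_STAGES = {"strength": True, "cpm": True, "overlap": True,
                   "lesion": True, "pls": True}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; unknown keys are rejected."""

    out_dir: str = "results"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(default_factory=lambda: dict(_DEFAULT_STAGES))
    fd_profile: str = "strict"          # or "liberal"
    lag_trs: int = 0
    cpm_alpha: float = 0.01
    cpm_group: str = "youth"            # group the LOSO model is trained on
    lesion_n_boot: int = 200
    pls_n_perm: int = 100
    pls_n_boot: int = 100

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        unknown = set(self.stages) - set(_DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
        if self.fd_profile not in ("strict", "liberal"):
            raise ConfigError(f"fd_profile must be strict or liberal, got {self.fd_profile!r}")
        self.stages = {**_DEFAULT_STAGES, **self.stages}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


def _fd_thresholds(profile: str) -> tuple[float, float]:
    return cn.FD_STRICT if profile == "strict" else cn.FD_LIBERAL


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest.

    Stage failures raise :class:`StageError` tagged with the stage name;
    everything written so far stays on disk and is flagged in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "stages": {}, "files": {}}
    results: dict = {}
    stage = "simulate"
    try:
        ds = simulate_study(config.simulation, seed=config.seed)
        subj_df = pd.DataFrame([vars(s) for s in ds.subjects]).set_index("subject_id")
        subj_df.reset_index().to_csv(out / "subjects.tsv", sep="\t", index=False,
                                     float_format="%.6f")
        ds.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False,
                           float_format="%.6f")
        manifest["stages"]["simulate"] = {"status": "ok", "n_subjects": len(ds.subjects)}

        # block FC (timeseries mode) or planted matrices (direct mode),
        # then the motion-exclusion cascade
        stage = "strength"
        fd_mean_max, fd_max_max = _fd_thresholds(config.fd_profile)
        pairs_by_subject: dict[str, list] = {}
        excl = cn.ExclusionLog()
        n_blocks_total = n_blocks_kept = 0
        for s in ds.subjects:
            if config.simulation.mode == "direct_edges":
                pairs = ds.block_pairs(s.subject_id)
            else:
                pairs = []
                runs = ds.connectomes[s.subject_id]
                rows = ds.behavior[ds.behavior["subject_id"] == s.subject_id]
                for row in rows.itertuples():
                    blk = cn.BlockRecord(
                        run_id=row.run_id, block_index=int(row.block_index),
                        condition=row.condition, stimulus=row.stimulus,
                        onset_tr=int(row.onset_tr), offset_tr=int(row.offset_tr),
                        fd_mean=float(row.fd_mean), fd_max=float(row.fd_max))
                    pairs.append((blk, cn.block_fc(runs[row.run_id], blk,
                                                   lag_trs=config.lag_trs)))
            blocks = [b for b, _ in pairs]
            kept, log = cn.motion_filter(blocks, fd_mean_max, fd_max_max)
            excl.lines.extend(f"{s.subject_id}\t{line}" for line in log.lines)
            kept_idx = {(b.run_id, b.block_index) for b in kept}
            pairs_by_subject[s.subject_id] = [
                (b, em) for b, em in pairs if (b.run_id, b.block_index) in kept_idx]
            n_blocks_total += len(pairs)
            n_blocks_kept += len(kept)
        excl.write(out / "exclusions.log")
        manifest["stages"]["motion_filter"] = {
            "status": "ok", "blocks_total": n_blocks_total,
            "blocks_retained": n_blocks_kept, "profile": config.fd_profile}

        strengths = {}
        if config.stages["strength"]:
            tables = []
            for construct in ("sa", "wm"):
                mask = ds.ground_truth.combined_mask(construct)
                for cond in cn.CONDITIONS:
                    scores, table = cn.condition_strengths(pairs_by_subject, mask, cond)
                    strengths[(construct, cond)] = scores
                    tables.append(table)
            pd.concat(tables).to_csv(out / "strengths.tsv", sep="\t", index=False,
                                     float_format="%.8f")
            manifest["stages"]["strength"] = {"status": "ok"}

        # subject-level aggregates shared by cpm / lesion / pls
        acc0 = (ds.behavior[ds.behavior["condition"] == "zero_back"]
                .groupby("subject_id")["accuracy"].mean())
        task_avg = {sid: np.mean([em.vector() for _, em in pairs], axis=0)
                    for sid, pairs in pairs_by_subject.items() if pairs}
        subj_ids = sorted(task_avg)
        edges_all = np.vstack([task_avg[sid] for sid in subj_ids])
        groups = subj_df.loc[subj_ids, "group"].to_numpy()
        sites = subj_df.loc[subj_ids, "site_id"].to_numpy()
        behav = acc0.loc[subj_ids].to_numpy()

        if config.stages["cpm"]:
            stage = "cpm"
            train = groups == config.cpm_group
            model = cpm_mod.train_loso(edges_all[train], behav[train],
                                       sites[train], alpha=config.cpm_alpha,
                                       p=config.simulation.p)
            consensus = model.consensus
            cn.write_mask(consensus, out / "cpm_consensus_mask.tsv")
            # held-out scoring: each subject scored by their own site's model
            held_strengths = np.array([
                cn.network_strength(cn.unvectorize(edges_all[k], config.simulation.p),
                                    model.site_models[sites[k]])
                for k in np.flatnonzero(train)])
            report = cpm_mod.evaluate_prediction(held_strengths, behav[train],
                                                 sites[train])
            results["cpm"] = {"prediction": report.as_dict(),
                              "consensus_edges": consensus.n_edges,
                              "alpha": config.cpm_alpha}
            manifest["stages"]["cpm"] = {"status": "ok"}

        if config.stages["overlap"]:
            stage = "overlap"
            gt = ds.ground_truth
            results["overlap"] = {
                f"{a}_vs_{b}": netstats.network_overlap(
                    gt.masks[a], gt.masks[b],
                    ("pos" if a.endswith("pos") else "neg",
                     "pos" if b.endswith("pos") else "neg")).as_dict()
                for a, b in (("sa_pos", "wm_pos"), ("sa_neg", "wm_neg"),
                             ("sa_pos", "wm_neg"), ("sa_neg", "wm_pos"))}
            manifest["stages"]["overlap"] = {"status": "ok"}

        if config.stages["lesion"]:
            stage = "lesion"
            sa_mask = ds.ground_truth.combined_mask("sa")
            rng = stage_rng(config.seed, 10)
            lesion_results = {}
            strengths_full = np.array([
                cn.network_strength(cn.unvectorize(edges_all[k], config.simulation.p),
                                    sa_mask) for k in range(len(subj_ids))])
            for region in sorted(ds.region_labels.unique()):
                lm = lesion_mod.lesion_mask(sa_mask, region, ds.region_labels)
                strengths_les = np.array([
                    cn.network_strength(cn.unvectorize(edges_all[k], config.simulation.p),
                                        lm) for k in range(len(subj_ids))])
                ga = groups == "youth"
                res = lesion_mod.compare_lesion_groups(
                    (strengths_full[ga], strengths_les[ga], behav[ga]),
                    (strengths_full[~ga], strengths_les[~ga], behav[~ga]),
                    region=region, n_boot=config.lesion_n_boot,
                    seed=rng, group_names=("youth", "adult"))
                lesion_results[region] = res.as_dict()
            results["lesion"] = lesion_results
            manifest["stages"]["lesion"] = {"status": "ok"}

        if config.stages["pls"]:
            stage = "pls"
            res = pls_mod.fit_pls(edges_all, behav, groups)
            res.perm_p = pls_mod.permutation_test(
                edges_all, behav, groups, n_perm=config.pls_n_perm,
                seed=stage_rng(config.seed, 11))
            _, z_br, sig = pls_mod.bootstrap_saliences(
                edges_all, behav, groups, n_boot=config.pls_n_boot,
                seed=stage_rng(config.seed, 12))
            lv_corr = pls_mod.lv_behavior_correlations(
                res, edges_all, behav, groups, n_boot=config.pls_n_boot,
                seed=stage_rng(config.seed, 13))
            results["pls"] = {
                "sigma_frac": res.sigma_frac.tolist(),
                "perm_p": res.perm_p.tolist(),
                "n_sig_edges": {str(l): len(v) for l, v in sig.items()},
                "lv1_behavior_corr": {g: d for g, d in lv_corr.items()},
            }
            pd.DataFrame(z_br, columns=[f"lv{l + 1}" for l in range(z_br.shape[1])]) \
                .to_csv(out / "pls_bootstrap_ratios.tsv", sep="\t", index=False,
                        float_format="%.6f")
            manifest["stages"]["pls"] = {"status": "ok"}

        for name, toggled in config.stages.items():
            if not toggled:
                manifest["stages"][name] = {"status": "skipped"}

        stage = "report"
        (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True,
                                                     default=float))
        for f in sorted(out.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    passed: bool
    messages: list[str]

    def __str__(self) -> str:
        head = "PASS" if self.passed else "FAIL"
        return "\n".join([head] + self.messages)


def validate_inputs(dataset_dir) -> ValidationReport:
    """Check a materialized dataset directory for structural consistency.

    Verifies required files, vocabulary of conditions/stimuli, block
    windows inside their runs, FD presence, and parcel-index ranges in
    masks.  Always returns a report rather than raising.
    """
    root = Path(dataset_dir)
    msgs: list[str] = []

    def fail(msg: str) -> None:
        msgs.append(f"FAIL: {msg}")

    for req in ("subjects.tsv", "behavior.tsv"):
        if not (root / req).exists():
            fail(f"missing {req}")
    if msgs:
        return ValidationReport(False, msgs)

    behavior = pd.read_csv(root / "behavior.tsv", sep="\t")
    bad_cond = set(behavior["condition"].unique()) - set(cn.CONDITIONS)
    if bad_cond:
        fail(f"unknown condition labels {sorted(bad_cond)}")
    bad_stim = set(behavior["stimulus"].unique()) - set(cn.STIMULI)
    if bad_stim:
        fail(f"unknown stimulus labels {sorted(bad_stim)}")
    for col in ("fd_mean", "fd_max"):
        if col not in behavior.columns:
            fail(f"behavior table lacks {col}")
        elif behavior[col].isna().any():
            rows = behavior.index[behavior[col].isna()].tolist()[:5]
            fail(f"missing {col} at rows {rows}")
    if (behavior["onset_tr"] >= behavior["offset_tr"]).any():
        rows = behavior.index[behavior["onset_tr"] >= behavior["offset_tr"]].tolist()[:5]
        fail(f"non-positive block windows at rows {rows}")

    p = None
    cfg_path = root / "config.yaml"
    if cfg_path.exists():
        p = SimulationConfig.from_yaml(cfg_path).p
    ts_dir = root / "timeseries"
    if ts_dir.exists():
        for f in sorted(ts_dir.glob("*.tsv")):
            ts = pd.read_csv(f, sep="\t")
            if p is None:
                p = ts.shape[1]
            elif ts.shape[1] != p:
                fail(f"{f.name}: {ts.shape[1]} parcels, expected {p}")
            sid, run = f.stem.rsplit("_run_", 1)
            rows = behavior[(behavior["subject_id"] == sid)
                            & (behavior["run_id"] == f"run_{run}")]
            if len(rows) and rows["offset_tr"].max() > len(ts):
                fail(f"{f.name}: block offset {rows['offset_tr'].max()} beyond "
                     f"run length {len(ts)}")
    masks_dir = root / "masks"
    if masks_dir.exists() and p is not None:
        for f in sorted(masks_dir.glob("*.tsv")):
            mdf = pd.read_csv(f, sep="\t")
            if {"i", "j"}.issubset(mdf.columns) and len(mdf):
                top = int(max(mdf["i"].max(), mdf["j"].max()))
                if top >= p:
                    fail(f"{f.name}: parcel index {top} out of range for p={p}")
    if not msgs:
        msgs.append("all checks passed")
    return ValidationReport(not any(m.startswith("FAIL") for m in msgs), msgs)
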