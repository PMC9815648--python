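"""Synthetic two-group, multi-site, block-design connectome study.

Emulates the structure of a developmental n-back dataset — two age groups
acquired at many sites, 16 task blocks per subject (8 low-load "0-back", 8
high-load "2-back"; 30/31 TRs at TR = 0.8 s), latent sustained-attention
(SA) and working-memory (WM) abilities correlated at 0.62, planted
positive/negative predictive edge sets of the published sizes (757/630 SA,
1,674/1,203 WM out of 35,778 edges at P = 268), group-common and
group-differential brain-behavior edge sets, stimulus-type and run effects
on accuracy, and per-block motion confounds — with fully known ground
truth, so every downstream stage has a recoverable planted signal.

Generative model (direct-edge mode)
-----------------------------------
Subject abilities (a_SA, a_WM) are bivariate standard normal with the
configured correlation; adults receive configurable mean offsets.  The
Fisher-z value of edge e for subject s in block b is::

    z_e(s,b) = mu_e
             + sum_m  beta_m * w_m[e] * (a_m(s) + delta * state(s,b) * 1[cond(b) matches m])
             + beta_common * c[e] * a_SA(s)
             + beta_diff   * d[e] * g(s) * a_SA(s)
             + group strength offset
             + eps,   eps ~ N(0, edge_noise_sd^2)

where w_m is the signed mask vector (+1 high-, −1 low-behavior edges),
c and d are ±1 sign vectors over the common/differential edge sets,
g(s) = +1 for youth and −1 for adults, and state(s,b) is the shared
block-level latent that also feeds accuracy (this is what makes strength
track accuracy block-to-block).  Block accuracy is linear-then-clipped::

    acc(s,b) = base + lambda_cond * a_cond(s) + stim + run + motion
             + lambda_state * state(s,b) + noise,  clipped to [0, 1].

Time-series mode converts the target z matrix to r = tanh(z), projects it
to the nearest unit-diagonal PSD correlation matrix (eigenvalue clipping),
and draws T TRs of zero-mean multivariate normal data per block, so the
estimated FC carries realistic T-limited noise.

All the effect-size defaults are artifact choices (the emulated study is
empirical and publishes no generative model); they are documented in the
package's methods note.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
import yaml

from .connectome import (
    BlockRecord, EdgeMatrix, NetworkMask, ParcelTimeSeries,
    n_edges, triu_index, unvectorize,
    write_block_table, write_edge_matrix, write_mask, write_timeseries,
)

STAGE_GROUND_TRUTH, STAGE_SUBJECTS, STAGE_BEHAVIOR, STAGE_CONNECTOMES = 0, 1, 2, 3


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Per-stage generator: SeedSequence(seed, spawn_key=(stage,)).

    The fixed stage counters (0 ground truth, 1 subjects, 2 behavior,
    3 connectomes) let any stage be regenerated independently of the
    others from the one global seed.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_MASK_SIZES = {"sa_pos": 757, "sa_neg": 630, "wm_pos": 1674, "wm_neg": 1203}
DEFAULT_OVERLAPS = {("sa_pos", "wm_pos"): 37, ("sa_neg", "wm_neg"): 33}

#: standardized stimulus-type effects (latent scale); place blocks hardest
DEFAULT_STIM_EFFECTS = {"neutral_face": 0.0, "negative_face": -0.08,
                        "positive_face": -0.05, "place": -0.22}


@dataclass
class SimulationConfig:
    """Full generator configuration; defaults are the emulated study's shape."""

    p: int = 268
    n_per_group: int = 754
    n_sites: int = 18
    site_assignment: str = "round_robin"        # or "multinomial"
    ability_corr: float = 0.62
    # adult mean offsets: (ability SD units, z-units added to mask edges)
    adult_ability_offset: float = 0.5
    adult_strength_offset: float = 0.05
    mask_sizes: dict = field(default_factory=lambda: dict(DEFAULT_MASK_SIZES))
    overlap_spec: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAPS))
    n_common: int = 100
    n_differential: int = 100
    n_regions: int = 20
    focal_region: str | None = None             # restrict SA masks to one region
    # effect sizes (z-units of edge strength per SD of ability)
    beta_mask: float = 0.033
    beta_common: float = 0.033
    beta_diff: float = 0.025
    state_sd: float = 1.0
    state_gain: float = 0.15                    # delta: state → mask edges
    edge_noise_sd: float = 0.3
    mu_sd: float = 0.25                         # spread of baseline edge means
    mu_mean: float = 0.25
    # behavior model
    base_accuracy: float = 0.87
    lambda_ability: float = 0.06
    lambda_cross: float = 0.0                   # 0-back loading on a_WM etc.
    lambda_state: float = 0.02
    stim_effects: dict = field(default_factory=lambda: dict(DEFAULT_STIM_EFFECTS))
    stim_scale: float = 0.1                     # latent → accuracy units
    run_effect: float = -0.01                   # run 2 relative to run 1
    motion_effect: float = -0.05                # per mm of block FD above 0.1
    accuracy_noise_sd: float = 0.1
    # geometry
    n_runs: int = 2
    blocks_per_run: int = 8
    block_len_trs: int = 30                     # alternates with +1
    tr: float = 0.8
    mode: str = "direct_edges"                  # or "timeseries"
    # motion generation
    fd_median: float = 0.10
    fd_subject_log_sd: float = 0.35
    fd_block_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("direct_edges", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not abs(self.ability_corr) < 1:
            raise ValueError("|ability_corr| must be < 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        self.overlap_spec = {tuple(k.split("&")) if isinstance(k, str) else tuple(k): v
                             for k, v in self.overlap_spec.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["overlap_spec"] = {"&".join(k): v for k, v in self.overlap_spec.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @classmethod
    def scaled(cls, p: int, **overrides) -> "SimulationConfig":
        """Desk-scale config: mask sizes and overlaps shrink with the edge count.

        Planted set sizes scale by n_edges(p)/n_edges(268) (minimum 5 edges
        per mask); effect sizes and the behavioral model are untouched, so
        per-edge effect strengths match the full-size default.
        """
        ratio = n_edges(p) / n_edges(268)
        sizes = {k: max(5, int(round(v * ratio))) for k, v in DEFAULT_MASK_SIZES.items()}
        overlaps = {k: int(round(v * ratio)) for k, v in DEFAULT_OVERLAPS.items()}
        base = dict(p=p, mask_sizes=sizes, overlap_spec=overlaps)
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted masks, common/differential edge sets, and effect sizes."""

    masks: dict[str, NetworkMask]
    common_edges: np.ndarray          # indices into the edge vector
    common_signs: np.ndarray
    differential_edges: np.ndarray
    differential_signs: np.ndarray
    effect_sizes: dict[str, float]
    p: int
    params: dict = field(default_factory=dict)

    def mask_vector(self, name: str) -> np.ndarray:
        i, j = triu_index(self.p)
        return self.masks[name].w[i, j].astype(float)

    def combined_mask(self, construct: str) -> NetworkMask:
        """Signed union, e.g. 'sa' → sa_pos (+1) plus sa_neg (−1)."""
        w = self.masks[f"{construct}_pos"].w + self.masks[f"{construct}_neg"].w
        return NetworkMask(w=np.clip(w, -1, 1), name=construct)

    def planted_edge_indices(self, construct: str) -> np.ndarray:
        i, j = triu_index(self.p)
        w = self.combined_mask(construct).w[i, j]
        return np.flatnonzero(w != 0)


def make_ground_truth(
    p: int,
    mask_sizes: dict[str, int] | None = None,
    overlap_spec: dict[tuple[str, str], int] | None = None,
    seed: int | np.random.Generator = 0,
    n_common: int = 0,
    n_differential: int = 0,
    effect_sizes: dict[str, float] | None = None,
    edge_pools: dict[str, np.ndarray] | None = None,
) -> GroundTruth:
    """Sample planted edge-set masks with exact sizes and pairwise overlaps.

    Masks are disjoint except where ``overlap_spec`` requests an exact
    shared count for a pair; common/differential edge sets are drawn from
    the leftover pool.  ``edge_pools`` optionally restricts a mask's edges
    to a subset of edge indices (used to concentrate a mask in one
    anatomical region).  Sign convention: ``*_pos`` masks carry +1,
    ``*_neg`` masks −1, everything else +1.
    """
    rng = np.random.default_rng(seed)
    sizes = dict(mask_sizes if mask_sizes is not None else DEFAULT_MASK_SIZES)
    overlaps = dict(overlap_spec or {})
    e_total = n_edges(p)

    for name, size in sizes.items():
        pool_size = len(edge_pools[name]) if edge_pools and name in edge_pools else e_total
        if size > pool_size:
            raise ValueError(f"mask {name!r} wants {size} edges but only "
                             f"{pool_size} are available for it")
    for (a, b), x in overlaps.items():
        if a not in sizes or b not in sizes:
            raise ValueError(f"overlap references unknown mask(s) {a!r}/{b!r}")
        if x > min(sizes[a], sizes[b]):
            raise ValueError(f"overlap {a}&{b}={x} exceeds min(|{a}|, |{b}|)")

    used = np.zeros(e_total, dtype=bool)
    chosen: dict[str, set[int]] = {name: set() for name in sizes}

    def draw(n: int, allowed: np.ndarray | None) -> np.ndarray:
        pool = np.flatnonzero(~used)
        if allowed is not None:
            pool = np.intersect1d(pool, allowed, assume_unique=False)
        if len(pool) < n:
            raise ValueError(f"edge pool exhausted: need {n}, have {len(pool)}")
        pick = rng.choice(pool, size=n, replace=False)
        used[pick] = True
        return pick

    # shared edges first, then the disjoint remainders
    for (a, b), x in overlaps.items():
        allowed = None
        if edge_pools:
            for m in (a, b):
                if m in edge_pools:
                    allowed = edge_pools[m] if allowed is None else \
                        np.intersect1d(allowed, edge_pools[m])
        shared = draw(x, allowed)
        chosen[a].update(shared.tolist())
        chosen[b].update(shared.tolist())
    for name, size in sizes.items():
        need = size - len(chosen[name])
        allowed = edge_pools.get(name) if edge_pools else None
        chosen[name].update(draw(need, allowed).tolist())

    i_idx, j_idx = triu_index(p)
    masks = {}
    for name, edges in chosen.items():
        sign = -1 if name.endswith("_neg") else 1
        vec = np.zeros(e_total)
        vec[sorted(edges)] = sign
        masks[name] = NetworkMask(w=unvectorize(vec, p).astype(np.int8), name=name)
        if len(edges) != sizes[name]:
            raise AssertionError("mask size bookkeeping failed")

    common = draw(n_common, None) if n_common else np.empty(0, dtype=int)
    differential = draw(n_differential, None) if n_differential else np.empty(0, dtype=int)
    return GroundTruth(
        masks=masks,
        common_edges=np.sort(common),
        common_signs=rng.choice([-1.0, 1.0], size=len(common)),
        differential_edges=np.sort(differential),
        differential_signs=rng.choice([-1.0, 1.0], size=len(differential)),
        effect_sizes=dict(effect_sizes or {}),
        p=p,
        params={"mask_sizes": sizes,
                "overlap_spec": {"&".join(k): v for k, v in overlaps.items()}},
    )


def make_region_labels(p: int, n_regions: int) -> pd.Series:
    """Round-robin parcel → region assignment ('region_00' ... )."""
    names = [f"region_{k:02d}" for k in range(n_regions)]
    return pd.Series([names[i % n_regions] for i in range(p)],
                     index=range(p), name="region")


# ---------------------------------------------------------------------------
# subjects and behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    group: str                 # 'youth' or 'adult'
    site_id: str
    a_sa: float
    a_wm: float
    mean_fd: float
    weight: float


def simulate_subjects(
    n_per_group: int,
    n_sites: int = 18,
    ability_corr: float = 0.62,
    group_offsets: tuple[float, float] = (0.5, 0.05),
    seed: int | np.random.Generator = 0,
    site_assignment: str = "round_robin",
    fd_median: float = 0.10,
    fd_log_sd: float = 0.35,
) -> list[SimulatedSubject]:
    """Draw two equal groups of subjects with correlated latent abilities.

    ``group_offsets = (ability, strength)``: adults get the ability offset
    added to both latent abilities (they perform better); the strength
    offset is applied later by the connectome stage.  Sites are assigned
    round-robin (equal counts) or multinomially.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    cov = np.array([[1.0, ability_corr], [ability_corr, 1.0]])
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError(f"ability correlation {ability_corr} gives a "
                         "non-positive-definite covariance")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov)
    subjects = []
    for group in ("youth", "adult"):
        abilities = rng.standard_normal((n_per_group, 2)) @ chol.T
        if group == "adult":
            abilities = abilities + group_offsets[0]
        if site_assignment == "round_robin":
            sites = [f"site_{k % n_sites:02d}" for k in range(n_per_group)]
        elif site_assignment == "multinomial":
            sites = [f"site_{k:02d}" for k in rng.integers(0, n_sites, size=n_per_group)]
        else:
            raise ValueError(f"unknown site_assignment {site_assignment!r}")
        fd = fd_median * np.exp(rng.normal(0.0, fd_log_sd, size=n_per_group))
        weight = rng.gamma(shape=20.0, scale=0.05, size=n_per_group)  # mean 1
        for k in range(n_per_group):
            subjects.append(SimulatedSubject(
                subject_id=f"{group}_{k:04d}", group=group, site_id=sites[k],
                a_sa=float(abilities[k, 0]), a_wm=float(abilities[k, 1]),
                mean_fd=float(fd[k]), weight=float(weight[k])))
    return subjects


def subjects_frame(subjects: list[SimulatedSubject]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in subjects])


def _block_design(cfg: SimulationConfig) -> list[dict]:
    """Fixed within-run block layout: conditions alternate, stimuli cycle.

    Block lengths alternate 30/31 TRs; onsets leave an 8-TR inter-block
    gap after a 10-TR lead-in.
    """
    stimuli = list(DEFAULT_STIM_EFFECTS)
    blocks = []
    for run in range(cfg.n_runs):
        onset = 10
        for b in range(cfg.blocks_per_run):
            length = cfg.block_len_trs + (b % 2)
            blocks.append({
                "run_id": f"run_{run + 1}",
                "block_index": b,
                "condition": "zero_back" if (b + run) % 2 == 0 else "two_back",
                "stimulus": stimuli[(b // 2 + run) % len(stimuli)],
                "onset_tr": onset,
                "offset_tr": onset + length,
            })
            onset += length + 8
    return blocks


def simulate_behavior(
    subjects: list[SimulatedSubject],
    cfg: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-block accuracy table with the latent block state used by connectomes.

    Columns: subject_id, run_id, block_index, condition, stimulus,
    onset_tr, offset_tr, fd_mean, fd_max, state, accuracy.  0-back blocks
    load on a_SA and 2-back on a_WM (plus the configurable cross-loading);
    accuracy is linear in its effects and clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    design = _block_design(cfg)
    for blk in design:
        if blk["stimulus"] not in cfg.stim_effects:
            raise ValueError(f"unknown stimulus label {blk['stimulus']!r}")
    rows = []
    for s in subjects:
        for blk in design:
            state = rng.normal(0.0, cfg.state_sd)
            fd_mean = s.mean_fd * np.exp(rng.normal(0.0, cfg.fd_block_log_sd))
            fd_max = fd_mean * (4.0 + rng.exponential(3.0))
            ability = s.a_sa if blk["condition"] == "zero_back" else s.a_wm
            cross = s.a_wm if blk["condition"] == "zero_back" else s.a_sa
            acc = (cfg.base_accuracy
                   + cfg.lambda_ability * ability
                   + cfg.lambda_cross * cross
                   + cfg.stim_scale * cfg.stim_effects[blk["stimulus"]]
                   + (cfg.run_effect if blk["run_id"] != "run_1" else 0.0)
                   + cfg.motion_effect * (fd_mean - 0.1)
                   + cfg.lambda_state * state
                   + rng.normal(0.0, cfg.accuracy_noise_sd))
            rows.append({**blk, "subject_id": s.subject_id, "state": state,
                         "fd_mean": fd_mean, "fd_max": fd_max,
                         "accuracy": float(np.clip(acc, 0.0, 1.0))})
    cols = ["subject_id", "run_id", "block_index", "condition", "stimulus",
            "onset_tr", "offset_tr", "fd_mean", "fd_max", "state", "accuracy"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# connectomes
# ---------------------------------------------------------------------------

def _subject_base_vector(s: SimulatedSubject, gt: GroundTruth,
                         cfg: SimulationConfig, mu: np.ndarray) -> np.ndarray:
    """Block-invariant part of a subject's edge vector."""
    z = mu.copy()
    for name in gt.masks:
        a = s.a_sa if name.startswith("sa") else s.a_wm
        z += cfg.beta_mask * gt.mask_vector(name) * a
        if s.group == "adult":
            z += cfg.adult_strength_offset * gt.mask_vector(name)
    g = 1.0 if s.group == "youth" else -1.0
    if len(gt.common_edges):
        z[gt.common_edges] += cfg.beta_common * gt.common_signs * s.a_sa
    if len(gt.differential_edges):
        z[gt.differential_edges] += cfg.beta_diff * gt.differential_signs * g * s.a_sa
    return z


def _state_vector(gt: GroundTruth, cfg: SimulationConfig, condition: str) -> np.ndarray:
    """Edge loading of the block state: the condition's masks co-fluctuate."""
    prefix = "sa" if condition == "zero_back" else "wm"
    vec = np.zeros(n_edges(gt.p))
    for name in (f"{prefix}_pos", f"{prefix}_neg"):
        if name in gt.masks:
            vec += cfg.beta_mask * cfg.state_gain * gt.mask_vector(name)
    return vec


def baseline_mu(p: int, cfg: SimulationConfig, seed: int | np.random.Generator) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(cfg.mu_mean, cfg.mu_sd, size=n_edges(p))


def nearest_correlation(r: np.ndarray, tol: float = -1e-10) -> np.ndarray:
    """Nearest-PSD projection: clip eigenvalues at 0, rescale to unit diagonal."""
    r = (r + r.T) / 2
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= tol and np.allclose(np.diag(r), 1.0):
        return r
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2
    if np.linalg.eigvalsh(out).min() < -1e-8:
        raise ValueError("PSD projection failed to converge; target matrix "
                         "is too far from a correlation matrix")
    return out


def simulate_block_edge_vectors(
    subject: SimulatedSubject,
    behavior: pd.DataFrame,
    gt: GroundTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mu: np.ndarray,
) -> np.ndarray:
    """Direct-mode block × E edge vectors for one subject (rows follow the
    subject's behavior-table rows)."""
    base = _subject_base_vector(subject, gt, cfg, mu)
    blocks = behavior[behavior["subject_id"] == subject.subject_id]
    out = np.empty((len(blocks), len(base)))
    for k, row in enumerate(blocks.itertuples()):
        z = base + _state_vector(gt, cfg, row.condition) * row.state
        if cfg.edge_noise_sd > 0:
            z = z + rng.normal(0.0, cfg.edge_noise_sd, size=len(base))
        out[k] = z
    return out


def simulate_connectomes(
    subjects: list[SimulatedSubject],
    behavior: pd.DataFrame,
    gt: GroundTruth,
    cfg: SimulationConfig | None = None,
    mode: Literal["direct_edges", "timeseries"] | None = None,
    seed: int | np.random.Generator = 0,
) -> Iterator[tuple[SimulatedSubject, object]]:
    """Yield per-subject connectome data.

    direct_edges mode yields ``(subject, list[EdgeMatrix])`` (one matrix
    per block, ordered as in the behavior table); timeseries mode yields
    ``(subject, dict[run_id, ParcelTimeSeries])`` with blocks embedded at
    their onsets and the implied block correlation structure sampled from
    the nearest-PSD projection of tanh(z).
    """
    cfg = cfg or SimulationConfig()
    mode = mode or cfg.mode
    if gt.p != cfg.p:
        raise ValueError(f"ground truth p={gt.p} does not match config p={cfg.p}")
    rng = np.random.default_rng(seed)
    mu = baseline_mu(cfg.p, cfg, rng)
    for s in subjects:
        vecs = simulate_block_edge_vectors(s, behavior, gt, cfg, rng, mu)
        blocks = behavior[behavior["subject_id"] == s.subject_id].reset_index(drop=True)
        if mode == "direct_edges":
            ems = [EdgeMatrix(z=unvectorize(vecs[k], cfg.p), subject_id=s.subject_id,
                              run_id=blocks.loc[k, "run_id"],
                              block_index=int(blocks.loc[k, "block_index"]))
                   for k in range(len(blocks))]
            yield s, ems
        else:
            yield s, _timeseries_from_blocks(s, blocks, vecs, cfg, rng)


def _timeseries_from_blocks(s: SimulatedSubject, blocks: pd.DataFrame,
                            vecs: np.ndarray, cfg: SimulationConfig,
                            rng: np.random.Generator) -> dict[str, ParcelTimeSeries]:
    out = {}
    for run_id, run_blocks in blocks.groupby("run_id", sort=True):
        t_run = int(run_blocks["offset_tr"].max()) + 5
        data = rng.normal(0.0, 1.0, size=(t_run, cfg.p))  # rest TRs: white noise
        for k, row in run_blocks.iterrows():
            target = nearest_correlation(np.tanh(unvectorize(vecs[k], cfg.p))
                                         + np.eye(cfg.p))
            vals, vecs_e = np.linalg.eigh(target)
            factor = vecs_e * np.sqrt(np.clip(vals, 0.0, None))
            t_blk = int(row.offset_tr - row.onset_tr)
            data[int(row.onset_tr):int(row.offset_tr)] = \
                rng.standard_normal((t_blk, cfg.p)) @ factor.T
        out[run_id] = ParcelTimeSeries(values=data, tr=cfg.tr,
                                       subject_id=s.subject_id, run_id=run_id)
    return out


def subject_average_edges(
    subjects: list[SimulatedSubject],
    behavior: pd.DataFrame,
    gt: GroundTruth,
    cfg: SimulationConfig,
    seed: int | np.random.Generator = 0,
    condition: str | None = None,
) -> np.ndarray:
    """Subjects × E matrix of task-average edge vectors (direct mode).

    Memory-lean path for the across-subject analyses: block edge vectors
    are averaged on the fly instead of materializing every edge matrix.
    ``condition`` restricts the average to one block condition.
    """
    rng = np.random.default_rng(seed)
    mu = baseline_mu(cfg.p, cfg, rng)
    out = np.empty((len(subjects), n_edges(cfg.p)))
    for k, s in enumerate(subjects):
        vecs = simulate_block_edge_vectors(s, behavior, gt, cfg, rng, mu)
        if condition is not None:
            mask = (behavior[behavior["subject_id"] == s.subject_id]
                    ["condition"] == condition).to_numpy()
            vecs = vecs[mask]
        out[k] = vecs.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    subjects: list[SimulatedSubject]
    behavior: pd.DataFrame
    connectomes: dict              # subject_id → list[EdgeMatrix] or {run: ts}
    ground_truth: GroundTruth
    region_labels: pd.Series
    config: SimulationConfig
    seed: int

    def block_pairs(self, subject_id: str) -> list[tuple[BlockRecord, EdgeMatrix]]:
        """(BlockRecord, EdgeMatrix) pairs for the connectome module."""
        ems = self.connectomes[subject_id]
        rows = self.behavior[self.behavior["subject_id"] == subject_id]
        pairs = []
        for em, row in zip(ems, rows.itertuples()):
            pairs.append((BlockRecord(
                run_id=row.run_id, block_index=int(row.block_index),
                condition=row.condition, stimulus=row.stimulus,
                onset_tr=int(row.onset_tr), offset_tr=int(row.offset_tr),
                fd_mean=float(row.fd_mean), fd_max=float(row.fd_max)), em))
        return pairs


def simulate_study(cfg: SimulationConfig | None = None, seed: int = 0,
                   keep_connectomes: bool = True) -> SimulatedDataset:
    """Run every generator stage under the documented per-stage seeds."""
    cfg = cfg or SimulationConfig()
    edge_pools = None
    region_labels = make_region_labels(cfg.p, cfg.n_regions)
    if cfg.focal_region is not None:
        members = set(region_labels.index[region_labels == cfg.focal_region])
        if not members:
            raise ValueError(f"focal region {cfg.focal_region!r} has no parcels")
        i, j = triu_index(cfg.p)
        touching = np.flatnonzero(np.isin(i, list(members)) | np.isin(j, list(members)))
        edge_pools = {"sa_pos": touching, "sa_neg": touching}
    gt = make_ground_truth(
        cfg.p, cfg.mask_sizes, cfg.overlap_spec,
        seed=stage_rng(seed, STAGE_GROUND_TRUTH),
        n_common=cfg.n_common, n_differential=cfg.n_differential,
        effect_sizes={"beta_mask": cfg.beta_mask, "beta_common": cfg.beta_common,
                      "beta_diff": cfg.beta_diff},
        edge_pools=edge_pools)
    gt.params["config"] = cfg.to_dict()
    subjects = simulate_subjects(
        cfg.n_per_group, cfg.n_sites, cfg.ability_corr,
        group_offsets=(cfg.adult_ability_offset, cfg.adult_strength_offset),
        seed=stage_rng(seed, STAGE_SUBJECTS), site_assignment=cfg.site_assignment,
        fd_median=cfg.fd_median, fd_log_sd=cfg.fd_subject_log_sd)
    behavior = simulate_behavior(subjects, cfg, seed=stage_rng(seed, STAGE_BEHAVIOR))
    connectomes = {}
    if keep_connectomes:
        for s, data in simulate_connectomes(subjects, behavior, gt, cfg,
                                            seed=stage_rng(seed, STAGE_CONNECTOMES)):
            connectomes[s.subject_id] = data
    return SimulatedDataset(subjects=subjects, behavior=behavior,
                            connectomes=connectomes, ground_truth=gt,
                            region_labels=region_labels, config=cfg, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_dataset(cfg: SimulationConfig, seed: int, out_dir) -> dict:
    """Materialize a full simulated study on disk; returns the manifest.

    Layout: subjects.tsv, behavior.tsv, blocks/<subject>.tsv,
    edges/<subject>_b<k>.tsv (direct mode) or timeseries/<subject>_<run>.tsv,
    masks/<name>.tsv, region_labels.tsv, ground_truth.json, config.yaml,
    manifest.json.  A failed run removes the partial output directory.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        ds = simulate_study(cfg, seed=seed, keep_connectomes=True)
        files: list[Path] = []

        def save(relpath: str, writer) -> None:
            path = out / relpath
            path.parent.mkdir(parents=True, exist_ok=True)
            writer(path)
            files.append(path)

        save("subjects.tsv", lambda p: subjects_frame(ds.subjects).to_csv(
            p, sep="\t", index=False, float_format="%.6f"))
        save("behavior.tsv", lambda p: ds.behavior.to_csv(
            p, sep="\t", index=False, float_format="%.6f"))
        save("region_labels.tsv", lambda p: ds.region_labels.rename_axis("parcel_id")
             .reset_index().to_csv(p, sep="\t", index=False))
        for name, mask in ds.ground_truth.masks.items():
            save(f"masks/{name}.tsv", lambda p, m=mask: write_mask(m, p))
        for s in ds.subjects:
            pairs = ds.block_pairs(s.subject_id) if cfg.mode == "direct_edges" else None
            blocks = ds.behavior[ds.behavior["subject_id"] == s.subject_id]
            save(f"blocks/{s.subject_id}.tsv", lambda p, b=blocks: b[
                ["run_id", "block_index", "condition", "stimulus",
                 "onset_tr", "offset_tr", "fd_mean", "fd_max"]].to_csv(
                p, sep="\t", index=False, float_format="%.6f"))
            if cfg.mode == "direct_edges":
                for blk, em in pairs:
                    save(f"edges/{s.subject_id}_b{blk.run_id}_{blk.block_index}.tsv",
                         lambda p, e=em: write_edge_matrix(e, p))
            else:
                for run_id, ts in ds.connectomes[s.subject_id].items():
                    save(f"timeseries/{s.subject_id}_{run_id}.tsv",
                         lambda p, t=ts: write_timeseries(t, p))
        gt = ds.ground_truth
        save("ground_truth.json", lambda p: p.write_text(json.dumps({
            "common_edges": gt.common_edges.tolist(),
            "common_signs": gt.common_signs.tolist(),
            "differential_edges": gt.differential_edges.tolist(),
            "differential_signs": gt.differential_signs.tolist(),
            "effect_sizes": gt.effect_sizes, "p": gt.p, "params": gt.params,
        }, indent=1, sort_keys=True)))
        save("config.yaml", lambda p: cfg.to_yaml(p))
        manifest = {
            "seed": seed,
            "config": cfg.to_dict(),
            "n_subjects": len(ds.subjects),
            "files": {str(f.relative_to(out)): _sha256(f) for f in sorted(files)},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        return manifest
    except BaseException:
        shutil.rmtree(out, ignore_errors=True)
        raise
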