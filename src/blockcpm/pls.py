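"""Two-group behavioral partial least squares (PLS) on connectome edges.

Behavioral PLS asks which weighted pattern of functional connections
maximally covaries with behavior across two groups at once.  The
cross-block matrix R stacks, one row per group, the within-group Pearson
correlation of every edge with behavior (edges and behavior z-scored
within group — the correlation-PLS convention).  Its SVD, R' = U S V',
yields exactly two latent variables for two groups × one behavior: in the
planted-signal regime LV1 captures the brain-behavior pattern common to
both groups and LV2 the pattern whose behavioral relevance differs by
group.

Inference:
* LV significance — permutation of the subject rows of the edge matrix
  against the (behavior, group) labels; add-one p per LV on the singular
  values.
* Edge reliability — subject bootstrap within group; each resample's
  scaled saliences are Procrustes-rotated onto the original solution and
  the bootstrap ratio Z_BR = salience / bootstrap SE is thresholded at
  |Z_BR| ≥ 3.
* Unequal group sizes — repeated balanced subsampling of the larger group,
  with sign-aligned averaging of the resulting solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("blockcpm")


# ---------------------------------------------------------------------------
# cross-block construction
# ---------------------------------------------------------------------------

def _group_order(groups) -> list:
    return list(pd.unique(pd.Series(groups)))


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns map to 0 so they carry no signal."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (x - mu) / sd_safe
    out[:, sd == 0] = 0.0
    return out


def build_crossblock(edges: np.ndarray, behavior: np.ndarray, groups) -> np.ndarray:
    """G×E matrix of within-group edge-behavior correlations.

    Row g holds, for every edge, the Pearson correlation with behavior
    computed over subjects of group g alone.  Requires ≥ 2 subjects and
    non-constant behavior per group.
    """
    x = np.asarray(edges, dtype=float)
    y = np.asarray(behavior, dtype=float)
    glabels = pd.Series(groups).reset_index(drop=True)
    order = _group_order(glabels)
    rows = []
    for g in order:
        sel = (glabels == g).to_numpy()
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        yg = y[sel]
        if yg.std() == 0:
            raise ValueError(f"behavior is constant within group {g!r}")
        xz = _zscore_cols(x[sel])
        yz = (yg - yg.mean()) / yg.std()
        rows.append(xz.T @ yz / sel.sum())
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# SVD and the result container
# ---------------------------------------------------------------------------

def pls_svd(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of the cross-block matrix with a deterministic sign convention.

    Returns (U, s, V, sigma_frac): U is E×L edge saliences, V is G×L
    design saliences, s the non-increasing singular values, and
    sigma_frac_i = s_i² / Σ s_j² the cross-block covariance fraction of
    each LV.  Each LV is oriented so its largest-magnitude edge salience
    is positive.
    """
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise ValueError("cross-block matrix contains non-finite values")
    U_t, s, Vt = np.linalg.svd(R.T, full_matrices=False)
    U, V = U_t, Vt.T
    for l in range(U.shape[1]):
        lead = np.argmax(np.abs(U[:, l]))
        if U[lead, l] < 0:
            U[:, l] *= -1
            V[:, l] *= -1
    total = float((s**2).sum())
    sigma_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return U, s, V, sigma_frac


@dataclass
class PLSResult:
    """Fitted two-group behavioral PLS with permutation and bootstrap inference."""

    U: np.ndarray                     # E×L edge saliences
    V: np.ndarray                     # G×L design saliences
    s: np.ndarray                     # singular values
    sigma_frac: np.ndarray            # s_i²/Σs² per LV
    groups: list                      # row order of the cross-block matrix
    perm_p: np.ndarray | None = None
    boot_se: np.ndarray | None = None
    boot_ratio: np.ndarray | None = None
    sig_edges: dict[int, np.ndarray] = field(default_factory=dict)
    lv_behavior_corr: dict | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None

    @property
    def n_lv(self) -> int:
        return len(self.s)

    def scaled_saliences(self) -> np.ndarray:
        return self.U * self.s[None, :]


def fit_pls(edges: np.ndarray, behavior: np.ndarray, groups) -> PLSResult:
    """Cross-block construction + SVD, no resampling inference."""
    R = build_crossblock(edges, behavior, groups)
    U, s, V, frac = pls_svd(R)
    return PLSResult(U=U, V=V, s=s, sigma_frac=frac, groups=_group_order(groups))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(edges: np.ndarray, behavior: np.ndarray, groups,
                     n_perm: int = 500, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add-one permutation p per LV on the singular values.

    Each permutation shuffles the subject rows of the edge matrix against
    the fixed (behavior, group) labels — group sizes are preserved — then
    rebuilds the cross-block matrix and re-runs the SVD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    x = np.asarray(edges, dtype=float)
    _, s_obs, _, _ = pls_svd(build_crossblock(x, behavior, groups))
    exceed = np.zeros_like(s_obs)
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[0])
        _, s_p, _, _ = pls_svd(build_crossblock(x[perm], behavior, groups))
        exceed += s_p >= s_obs
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# bootstrap reliability
# ---------------------------------------------------------------------------

def _procrustes_rotation(V_ref: np.ndarray, V_boot: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ||V_boot Q − V_ref|| (align boot LVs to original)."""
    A, _, Bt = np.linalg.svd(V_boot.T @ V_ref)
    return A @ Bt


def bootstrap_saliences(
    edges: np.ndarray, behavior: np.ndarray, groups,
    n_boot: int = 500, seed: int | np.random.Generator = 0,
    z_threshold: float = 3.0, align: str = "procrustes",
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Bootstrap SE, bootstrap ratios, and the reliable-edge sets per LV.

    Subjects are resampled with replacement within group.  Each bootstrap
    solution's scaled saliences (U·S) are aligned to the original — by
    Procrustes rotation of the design saliences (default) or by per-LV
    sign flips (``align='sign'``) — before pooling.  Z_BR is the original
    scaled salience over its bootstrap SD, with the 0/0 case defined as 0;
    edges with |Z_BR| ≥ ``z_threshold`` form the reliable sets.  Resamples
    that leave behavior constant within a group are redrawn (count logged).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    x = np.asarray(edges, dtype=float)
    y = np.asarray(behavior, dtype=float)
    glabels = pd.Series(groups).reset_index(drop=True)
    order = _group_order(glabels)
    group_idx = {g: np.flatnonzero((glabels == g).to_numpy()) for g in order}

    R0 = build_crossblock(x, y, glabels)
    U0, s0, V0, _ = pls_svd(R0)
    Us0 = U0 * s0[None, :]

    boots = np.empty((n_boot,) + Us0.shape)
    redraws = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = np.concatenate([rng.choice(gi, size=len(gi), replace=True)
                                  for gi in group_idx.values()])
            try:
                Rb = build_crossblock(x[idx], y[idx], glabels.iloc[idx].reset_index(drop=True))
                break
            except ValueError:
                redraws += 1
        else:
            raise RuntimeError("bootstrap kept drawing degenerate resamples")
        Ub, sb, Vb, _ = pls_svd(Rb)
        if align == "procrustes":
            Q = _procrustes_rotation(V0, Vb)
            boots[b] = (Ub * sb[None, :]) @ Q
        elif align == "sign":
            flips = np.sign(np.sum(Ub * U0, axis=0))
            flips[flips == 0] = 1.0
            boots[b] = (Ub * sb[None, :]) * flips[None, :]
        else:
            raise ValueError(f"unknown alignment {align!r}")
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)

    se = boots.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_br = np.where(se > 0, Us0 / np.where(se == 0, 1.0, se), 0.0)
    z_br[(se == 0) & (Us0 == 0)] = 0.0
    sig = {l: np.flatnonzero(np.abs(z_br[:, l]) >= z_threshold)
           for l in range(Us0.shape[1])}
    return se, z_br, sig


# ---------------------------------------------------------------------------
# balanced resampling for unequal group sizes
# ---------------------------------------------------------------------------

def balanced_pls(
    edges_large: np.ndarray, behavior_large: np.ndarray,
    edges_small: np.ndarray, behavior_small: np.ndarray,
    group_names: tuple = ("large", "small"),
    n_rep: int = 200, match_n: int | None = None,
    seed: int | np.random.Generator = 0,
) -> PLSResult:
    """Average PLS over balanced subsamples of the larger group.

    Each replicate draws ``match_n`` subjects of the larger group without
    replacement (default: the smaller group's size), runs the full
    two-group PLS, Procrustes-aligns the solution to the first replicate,
    and averages saliences and σ fractions across replicates.
    """
    xl = np.asarray(edges_large, dtype=float)
    xs = np.asarray(edges_small, dtype=float)
    yl = np.asarray(behavior_large, dtype=float)
    ys = np.asarray(behavior_small, dtype=float)
    if match_n is None:
        match_n = len(xs)
    if match_n > len(xl):
        raise ValueError(f"match_n={match_n} exceeds the larger group's size {len(xl)}")
    rng = np.random.default_rng(seed)
    glabels = [group_names[0]] * match_n + [group_names[1]] * len(xs)

    U_sum = V_sum = s_sum = frac_sum = None
    U_ref = V_ref = None
    for _ in range(n_rep):
        pick = rng.choice(len(xl), size=match_n, replace=False)
        x = np.vstack([xl[pick], xs])
        y = np.concatenate([yl[pick], ys])
        U, s, V, frac = pls_svd(build_crossblock(x, y, glabels))
        if U_ref is None:
            U_ref, V_ref = U, V
        else:
            Q = _procrustes_rotation(V_ref, V)
            U, V = U @ Q, V @ Q
        if U_sum is None:
            U_sum, V_sum = U.copy(), V.copy()
            s_sum, frac_sum = s.copy(), frac.copy()
        else:
            U_sum += U
            V_sum += V
            s_sum += s
            frac_sum += frac
    return PLSResult(U=U_sum / n_rep, V=V_sum / n_rep, s=s_sum / n_rep,
                     sigma_frac=frac_sum / n_rep, groups=list(group_names))


# ---------------------------------------------------------------------------
# LV scores and behavior correlations
# ---------------------------------------------------------------------------

def lv_behavior_correlations(
    result: PLSResult, edges: np.ndarray, behavior: np.ndarray, groups,
    n_boot: int = 500, seed: int | np.random.Generator = 0, lv: int = 0,
) -> dict:
    """Within-group correlation of LV brain scores with behavior, with CI.

    Brain scores project each subject's (within-group z-scored) edge vector
    onto the LV's edge saliences.  The 95% CI is a percentile bootstrap
    over subjects within the group.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(edges, dtype=float)
    y = np.asarray(behavior, dtype=float)
    glabels = pd.Series(groups).reset_index(drop=True)
    out = {}
    for g in _group_order(glabels):
        sel = (glabels == g).to_numpy()
        scores = _zscore_cols(x[sel]) @ result.U[:, lv]
        yg = y[sel]
        r = float(stats.pearsonr(scores, yg)[0])
        boot_r = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(yg), size=len(yg))
            if np.std(scores[idx]) == 0 or np.std(yg[idx]) == 0:
                boot_r[b] = r
            else:
                boot_r[b] = stats.pearsonr(scores[idx], yg[idx])[0]
        lo, hi = np.percentile(boot_r, [2.5, 97.5])
        out[g] = {"r": r, "ci": (float(lo), float(hi)), "n": int(sel.sum())}
    return out
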