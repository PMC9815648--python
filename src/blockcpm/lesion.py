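"""Computational lesioning of predictive networks by macroscale region.

Deleting from a network every edge that touches an anatomical region and
measuring the drop in predictive R² asks which parts of the anatomy the
model's predictive power depends on.  Group differences in that drop
(ΔR² = R²_full − R²_lesioned) are tested with a within-group subject
bootstrap of the ΔR² difference.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectome import NetworkMask


def lesion_mask(mask: NetworkMask, region, region_labels: pd.Series | dict) -> NetworkMask:
    """Remove every mask edge with at least one endpoint in ``region``."""
    labels = pd.Series(region_labels)
    members = labels.index[labels == region].to_numpy()
    if len(members) == 0:
        raise ValueError(f"region {region!r} not found in region labels")
    w = mask.w.copy()
    w[members, :] = 0
    w[:, members] = 0
    return NetworkMask(w=w, name=f"{mask.name}_lesion_{region}")


def _ols_r2(y: np.ndarray, design: np.ndarray) -> float:
    x = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design matrix in lesion regression")
    return float(sm.OLS(y, x).fit().rsquared)


def lesion_delta_r2(strength_full: np.ndarray, strength_lesioned: np.ndarray,
                    behavior: np.ndarray,
                    covariates: np.ndarray | None = None) -> tuple[float, float, float]:
    """R² of behavior on full vs lesioned network strength, and their difference.

    Ordinary least squares of behavior on [strength (+ covariates)]; the
    default model is univariate.  Returns (R²_full, R²_lesioned, ΔR²).
    """
    y = np.asarray(behavior, dtype=float)
    sf_ = np.asarray(strength_full, dtype=float)
    sl = np.asarray(strength_lesioned, dtype=float)
    if not (len(y) == len(sf_) == len(sl)):
        raise ValueError("misaligned inputs")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    ncov = 0 if covariates is None else covariates.shape[1]
    if len(y) <= ncov + 2:
        raise ValueError("too few subjects for the lesion regression")

    def design(s):
        return s[:, None] if covariates is None else np.column_stack([s, covariates])

    def r2(s):
        # a constant strength (e.g. a fully lesioned mask) explains nothing
        if s.std() == 0:
            return 0.0 if covariates is None else _ols_r2(y, covariates)
        return _ols_r2(y, design(s))

    r2_full = r2(sf_)
    r2_les = r2(sl)
    return r2_full, r2_les, r2_full - r2_les


@dataclass(frozen=True)
class LesionResult:
    """Group comparison of predictive-power loss after lesioning one region."""

    region: str
    group_results: dict  # group → {"r2_full", "r2_lesioned", "delta_r2"}
    diff: float          # ΔR²(groupA) − ΔR²(groupB)
    p: float             # two-sided bootstrap p (add-one)
    n_boot: int

    def as_dict(self) -> dict:
        return {"region": self.region, "group_results": self.group_results,
                "diff": self.diff, "p": self.p, "n_boot": self.n_boot}


def compare_lesion_groups(
    group_a: tuple[np.ndarray, np.ndarray, np.ndarray],
    group_b: tuple[np.ndarray, np.ndarray, np.ndarray],
    region: str = "",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    group_names: tuple[str, str] = ("groupA", "groupB"),
) -> LesionResult:
    """Bootstrap test of whether lesioning hurts one group's prediction more.

    Each group is a (strength_full, strength_lesioned, behavior) triple.
    Subjects are resampled with replacement within their group (sizes
    fixed), ΔR² recomputed per group, and their difference collected; the
    two-sided p is twice the add-one fraction of bootstrap differences
    falling on the far side of zero from the observed difference.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is low for a stable bootstrap p", stacklevel=2)
    rng = np.random.default_rng(seed)
    groups = {group_names[0]: tuple(np.asarray(v, float) for v in group_a),
              group_names[1]: tuple(np.asarray(v, float) for v in group_b)}
    observed = {}
    for name, (sf_, sl, y) in groups.items():
        r2f, r2l, d = lesion_delta_r2(sf_, sl, y)
        observed[name] = {"r2_full": r2f, "r2_lesioned": r2l, "delta_r2": d}
    obs_diff = observed[group_names[0]]["delta_r2"] - observed[group_names[1]]["delta_r2"]

    boot_diffs = np.empty(n_boot)
    for b in range(n_boot):
        deltas = []
        for name, (sf_, sl, y) in groups.items():
            idx = rng.integers(0, len(y), size=len(y))
            try:
                _, _, d = lesion_delta_r2(sf_[idx], sl[idx], y[idx])
            except ValueError:  # degenerate resample: constant strengths
                d = observed[name]["delta_r2"]
            deltas.append(d)
        boot_diffs[b] = deltas[0] - deltas[1]

    sign = np.sign(obs_diff) if obs_diff != 0 else 1.0
    p_one = (1 + np.sum(boot_diffs * sign <= 0)) / (n_boot + 1)
    return LesionResult(region=region, group_results=observed, diff=float(obs_diff),
                        p=float(min(1.0, 2.0 * p_one)), n_boot=n_boot)
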