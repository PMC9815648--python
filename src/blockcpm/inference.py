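"""Auxiliary statistics: dependent-correlation tests, coefficient
comparisons, weighted correlation, within-subject block tracking, and the
recognition-memory discrimination index d′.

The two dependent-correlation tests follow Steiger's (1980) formulations:
Williams' t for two correlations sharing one variable (is X1 or X2 the
better correlate of Y?) and Steiger's Z for two correlations measured on
the same subjects but involving different variable pairs sharing one
variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("blockcpm")


@dataclass(frozen=True)
class DependentCorrTest:
    statistic: float
    p: float
    df: float | None          # None for the asymptotic Z test
    kind: str
    inputs: dict

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "p": self.p, "df": self.df,
                "kind": self.kind, "inputs": self.inputs}


def _check_r(*rs: float) -> None:
    for r in rs:
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"correlation {r} must satisfy |r| < 1")


def williams_t(r13: float, r23: float, r12: float, n: int) -> DependentCorrTest:
    """Williams' t for two dependent correlations sharing variable 3.

    Tests r13 = r23 where variables 1 and 2 are themselves correlated at
    r12 and all three are measured on the same n subjects.  Uses Williams'
    (1959) t2 statistic as codified by Steiger (1980)::

        t = (r13 − r23) · sqrt[ (n−1)(1+r12) /
              ( 2·((n−1)/(n−3))·|R| + r̄²(1−r12)³ ) ]

    with |R| = 1 − r12² − r13² − r23² + 2·r12·r13·r23 the determinant of
    the correlation matrix and r̄ = (r13 + r23)/2; df = n − 3, two-sided p.
    """
    _check_r(r13, r23, r12)
    if n <= 3:
        raise ValueError("Williams' t requires n > 3")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det <= 0:
        raise ValueError(f"inconsistent correlation triple (|R| = {det:.4g} <= 0)")
    rbar = (r13 + r23) / 2
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r12) ** 3
    t = (r13 - r23) * np.sqrt((n - 1) * (1 + r12) / denom)
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return DependentCorrTest(statistic=float(t), p=float(p), df=float(n - 3),
                             kind="williams_t",
                             inputs={"r13": r13, "r23": r23, "r12": r12, "n": n})


def steiger_z(r_xy1: float, r_xy2: float, r_y1y2: float, n: int) -> DependentCorrTest:
    """Steiger's Z for two dependent correlations sharing variable X.

    Tests corr(X, Y1) = corr(X, Y2) on the same n subjects, where Y1 and
    Y2 correlate at r_y1y2.  Fisher-z transforms both correlations and
    uses Steiger's pooled-estimate covariance::

        r̄ = (r_xy1 + r_xy2)/2
        cov = [ r_y1y2(1 − 2r̄²) − ½r̄²(1 − 2r̄² − r_y1y2²) ] / (1 − r̄²)²
        Z   = (z1 − z2)·sqrt( (n − 3) / (2 − 2·cov) )

    Two-sided p from the standard normal.
    """
    _check_r(r_xy1, r_xy2, r_y1y2)
    if n <= 3:
        raise ValueError("Steiger's Z requires n > 3")
    det = 1 - r_y1y2**2 - r_xy1**2 - r_xy2**2 + 2 * r_y1y2 * r_xy1 * r_xy2
    if det <= 0:
        raise ValueError(f"inconsistent correlation triple (|R| = {det:.4g} <= 0)")
    z1, z2 = np.arctanh(r_xy1), np.arctanh(r_xy2)
    rbar = (r_xy1 + r_xy2) / 2
    cov = (r_y1y2 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_y1y2**2)) \
        / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * cov))
    p = 2 * stats.norm.sf(abs(z))
    return DependentCorrTest(statistic=float(z), p=float(p), df=None,
                             kind="steiger_z",
                             inputs={"r_xy1": r_xy1, "r_xy2": r_xy2,
                                     "r_y1y2": r_y1y2, "n": n})


def beta_z(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Z test for the difference of two independent regression coefficients."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _standardized_beta(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None) -> float:
    """Standardized OLS coefficient of y on x, partialling covariates."""
    ys = (y - y.mean()) / y.std()
    xs = (x - x.mean()) / x.std()
    design = np.column_stack([np.ones(len(y)), xs]) if covariates is None else \
        np.column_stack([np.ones(len(y)), xs, covariates])
    beta, *_ = np.linalg.lstsq(design, ys, rcond=None)
    return float(beta[1])


def bootstrap_beta_diff(
    outcome: np.ndarray, predictor_a: np.ndarray, predictor_b: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 1000, seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bootstrap p for the difference of two standardized OLS coefficients.

    Fits outcome ~ predictor separately for each predictor (plus optional
    shared covariates), resamples subjects with replacement, and returns
    (observed βA − βB, add-one two-sided p).  Degenerate resamples
    (a constant predictor) are redrawn and logged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(predictor_a, dtype=float)
    b = np.asarray(predictor_b, dtype=float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov is not None and cov.shape[0] != len(y):
        cov = cov.T

    def diff(idx):
        c = None if cov is None else cov[idx]
        return _standardized_beta(y[idx], a[idx], c) - _standardized_beta(y[idx], b[idx], c)

    full = np.arange(len(y))
    obs = diff(full)
    boot = np.empty(n_boot)
    redraws = 0
    for k in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, len(y), size=len(y))
            if y[idx].std() > 0 and a[idx].std() > 0 and b[idx].std() > 0:
                break
            redraws += 1
        boot[k] = diff(idx)
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    sign = np.sign(obs) if obs != 0 else 1.0
    p_one = (1 + np.sum(boot * sign <= 0)) / (n_boot + 1)
    return float(obs), float(min(1.0, 2 * p_one))


def weighted_correlation(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Pearson correlation under per-subject sampling weights.

    Weighted moments: m_w(x) = Σwᵢxᵢ/Σwᵢ, cov_w = Σwᵢ(xᵢ−m_w(x))(yᵢ−m_w(y))/Σwᵢ,
    r = cov_w/√(var_w(x)·var_w(y)).  With integer weights this equals the
    unweighted correlation on the correspondingly replicated dataset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("misaligned inputs")
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be finite and non-negative")
    ws = w.sum()
    if ws == 0:
        raise ValueError("weights sum to zero")
    mx, my = (w * x).sum() / ws, (w * y).sum() / ws
    vx = (w * (x - mx) ** 2).sum() / ws
    vy = (w * (y - my) ** 2).sum() / ws
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance")
    cov = (w * (x - mx) * (y - my)).sum() / ws
    return float(cov / np.sqrt(vx * vy))


def within_subject_tracking(
    strengths: dict[str, np.ndarray] | "pd.DataFrame",
    accuracies: dict[str, np.ndarray] | None = None,
    min_blocks: int = 4,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Does block-to-block network strength track block-to-block accuracy?

    Accepts either two dicts mapping subject_id → per-block vectors, or a
    long DataFrame with columns (subject_id, strength, accuracy).  Each
    included subject contributes the Pearson r over their own blocks
    (subjects with fewer than ``min_blocks`` paired blocks, or a constant
    series, are skipped); the summary is the mean per-subject r with a 95%
    percentile bootstrap CI resampling subjects.
    """
    import pandas as pd
    if accuracies is None:
        df = strengths
        pairs = {sid: (g["strength"].to_numpy(float), g["accuracy"].to_numpy(float))
                 for sid, g in df.groupby("subject_id")}
    else:
        pairs = {sid: (np.asarray(strengths[sid], float), np.asarray(accuracies[sid], float))
                 for sid in strengths}
    per_subject = {}
    for sid, (s, a) in pairs.items():
        if len(s) != len(a):
            raise ValueError(f"subject {sid}: strength/accuracy block counts differ")
        if len(s) < min_blocks or s.std() == 0 or a.std() == 0:
            continue
        per_subject[sid] = float(stats.pearsonr(s, a)[0])
    if not per_subject:
        raise ValueError(f"no subject has >= {min_blocks} usable paired blocks")
    rs = np.array(list(per_subject.values()))
    rng = np.random.default_rng(seed)
    boot = np.array([rs[rng.integers(0, len(rs), size=len(rs))].mean()
                     for _ in range(n_boot)])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"per_subject_r": per_subject, "mean_r": float(rs.mean()),
            "ci": (float(lo), float(hi)), "n_subjects": len(rs)}


def dprime(hits: int, n_old: int, false_alarms: int, n_new: int,
           correction: str = "loglinear") -> float:
    """Recognition-memory discrimination index d′ = Φ⁻¹(HR) − Φ⁻¹(FAR).

    The log-linear correction (add 0.5 to each count, 1 to each total)
    keeps both rates strictly inside (0, 1), so perfect performance yields
    a large but finite d′.  ``correction='none'`` uses the raw rates and
    may return ±inf.
    """
    if not (0 <= hits <= n_old and 0 <= false_alarms <= n_new):
        raise ValueError("counts out of range")
    if correction == "loglinear":
        hr = (hits + 0.5) / (n_old + 1)
        far = (false_alarms + 0.5) / (n_new + 1)
    elif correction == "none":
        hr = hits / n_old
        far = false_alarms / n_new
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))
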