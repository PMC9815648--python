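"""Connectome-based predictive modeling (CPM) with leave-one-site-out CV.

A CPM "model" is nothing more than a pair of edge sets: the edges whose
Fisher-z connectivity correlates positively (or negatively) with a behavior
across training subjects at a two-tailed p below ``alpha``.  New subjects
are scored by the signed strength sum in those sets — no regression weights
are fit or applied out of fold.  Multi-site data are cross-validated by
holding out one acquisition site at a time; the per-site masks are averaged
as signed indicators and binarized at 0.5 (inclusive) into a consensus
network.

Baselines: canonical-network mean strength and random size-matched edge
sets drawn from outside a reference network, with add-one empirical p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import NetworkMask, n_edges, triu_index, unvectorize

logger = logging.getLogger("blockcpm")


def edge_behavior_correlation(edge_vectors: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """Pearson r of every edge column against the behavior vector.

    ``edge_vectors`` is subjects × E.  Constant columns get r = 0 (they can
    never be selected); constant behavior is an error.
    """
    x = np.asarray(edge_vectors, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("edge matrix and behavior disagree on subject count")
    yc = y - y.mean()
    ysd = yc.std()
    if ysd == 0:
        raise ValueError("behavior is constant; edge selection undefined")
    xc = x - x.mean(axis=0)
    xsd = xc.std(axis=0)
    dead = xsd == 0
    xsd_safe = np.where(dead, 1.0, xsd)
    r = (xc * yc[:, None]).mean(axis=0) / (xsd_safe * ysd)
    r[dead] = 0.0
    if dead.any():
        logger.info("skipped %d constant edge(s) during selection", int(dead.sum()))
    return np.clip(r, -1.0, 1.0)


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r via the t transform with n − 2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def select_edges(edge_vectors: np.ndarray, behavior: np.ndarray,
                 alpha: float = 0.01, p: int | None = None,
                 name: str = "cpm") -> NetworkMask:
    """CPM edge selection: keep edges with two-tailed Pearson p < alpha.

    ``edge_vectors`` holds each subject's task-average connectome as a
    vectorized upper triangle (subjects × E).  Selected edges carry the
    sign of their correlation.  Selection p-values are deliberately not
    multiplicity-corrected — the edge sets, not individual edges, are the
    inferential unit.
    """
    x = np.asarray(edge_vectors, dtype=float)
    nsub, e = x.shape
    if nsub < 10:
        raise ValueError(f"need at least 10 subjects for edge selection, got {nsub}")
    if p is None:
        p = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(p) != e:
        raise ValueError(f"{e} edge columns do not match p={p} parcels")
    r = edge_behavior_correlation(x, behavior)
    pvals = correlation_p(r, nsub)
    w = np.where(pvals < alpha, np.sign(r), 0.0)
    return NetworkMask(w=unvectorize(w, p).astype(np.int8), name=name)


@dataclass
class CPMModel:
    """Per-site CPM masks from leave-one-site-out training, plus consensus."""

    site_models: dict[str, NetworkMask]
    train_sizes: dict[str, int]
    alpha: float = 0.01
    binarize_threshold: float = 0.5
    _consensus: NetworkMask | None = field(default=None, repr=False)

    @property
    def consensus(self) -> NetworkMask:
        if self._consensus is None:
            self._consensus = consensus_mask(self)
        return self._consensus


def train_loso(edge_vectors: np.ndarray, behavior: np.ndarray,
               site_labels: np.ndarray, alpha: float = 0.01,
               p: int | None = None) -> CPMModel:
    """Leave-one-site-out CPM: one edge-selection model per held-out site.

    Each site's model is trained on every subject NOT at that site, so a
    held-out subject's prediction never sees their own site's data.
    """
    sites = pd.Series(site_labels).astype(str)
    uniq = sites.unique()
    if len(uniq) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")
    counts = sites.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"every site needs >= 2 subjects; too small: {small.index.tolist()}")
    behavior = np.asarray(behavior, dtype=float)
    models, sizes = {}, {}
    for site in uniq:
        train = (sites != site).to_numpy()
        models[site] = select_edges(edge_vectors[train], behavior[train],
                                    alpha=alpha, p=p, name=f"loso_holdout_{site}")
        sizes[site] = int(train.sum())
    return CPMModel(site_models=models, train_sizes=sizes, alpha=alpha)


def consensus_mask(model: CPMModel, name: str = "consensus") -> NetworkMask:
    """Average the signed site indicators and binarize at the threshold.

    An edge survives if the mean of its signed indicator over site models
    has absolute value ≥ the threshold (inclusive, so an exact even split
    of votes at 0.5 is kept); edges whose votes conflict in sign are
    attenuated toward 0 and typically dropped.
    """
    masks = list(model.site_models.values())
    if not masks:
        raise ValueError("no site models to aggregate")
    mean_w = np.mean([m.w.astype(float) for m in masks], axis=0)
    w = np.where(np.abs(mean_w) >= model.binarize_threshold, np.sign(mean_w), 0.0)
    return NetworkMask(w=w.astype(np.int8), name=name)


@dataclass(frozen=True)
class PredictionReport:
    """Pooled and per-site accuracy of strength-based behavior prediction."""

    r: float
    r_p: float
    rho: float
    rho_p: float
    n: int
    per_site: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        d = {"r": self.r, "r_p": self.r_p, "rho": self.rho, "rho_p": self.rho_p, "n": self.n}
        if self.per_site is not None:
            d["per_site"] = self.per_site.to_dict("records")
        return d


def evaluate_prediction(strengths: np.ndarray, behavior: np.ndarray,
                        site_labels: np.ndarray | None = None) -> PredictionReport:
    """Pearson r and Spearman ρ between predicted strengths and behavior.

    Spearman uses average ranks for ties.  With site labels, a per-site
    breakdown accompanies the pooled estimate.
    """
    s = np.asarray(strengths, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if len(s) != len(y):
        raise ValueError("strengths and behavior lengths differ")
    if len(s) < 3:
        raise ValueError("need at least 3 subjects to evaluate")
    if s.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    r, r_p = stats.pearsonr(s, y)
    rho, rho_p = stats.spearmanr(s, y)
    per_site = None
    if site_labels is not None:
        rows = []
        for site, grp in pd.DataFrame({"s": s, "y": y, "site": site_labels}).groupby("site"):
            if len(grp) >= 3 and grp["s"].std() > 0 and grp["y"].std() > 0:
                sr, sp = stats.pearsonr(grp["s"], grp["y"])
            else:
                sr, sp = np.nan, np.nan
            rows.append({"site": site, "n": len(grp), "r": sr, "p": sp})
        per_site = pd.DataFrame(rows)
    return PredictionReport(r=float(r), r_p=float(r_p), rho=float(rho),
                            rho_p=float(rho_p), n=len(s), per_site=per_site)


def canonical_network_strength(em, partition: pd.Series | dict, network_id) -> float:
    """Mean Fisher-z over unique edges with BOTH endpoints in one canonical network."""
    z = em.z if hasattr(em, "z") else np.asarray(em, dtype=float)
    labels = pd.Series(partition)
    members = np.asarray(sorted(labels.index[labels == network_id]))
    if len(members) < 2:
        raise ValueError(f"network {network_id!r} has fewer than 2 parcels")
    sub = z[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def random_matched_networks(reference: NetworkMask, n_random: int = 200,
                            seed: int | np.random.Generator = 0) -> list[NetworkMask]:
    """Size-matched random edge sets drawn from OUTSIDE the reference network.

    Each random mask has exactly the reference's positive and negative edge
    counts, drawn without replacement from edges not in the reference (any
    sign).  Used as a null family for "is this network special" tests.
    """
    rng = np.random.default_rng(seed)
    p = reference.n_parcels
    i, j = triu_index(p)
    ref_vec = reference.w[i, j]
    pool = np.flatnonzero(ref_vec == 0)
    need = reference.n_edges
    if len(pool) < need:
        raise ValueError(f"only {len(pool)} edges outside the reference; need {need}")
    out = []
    for k in range(n_random):
        pick = rng.choice(pool, size=need, replace=False)
        vec = np.zeros(len(ref_vec))
        vec[pick[:reference.n_pos]] = 1
        vec[pick[reference.n_pos:]] = -1
        out.append(NetworkMask(w=unvectorize(vec, p).astype(np.int8),
                               name=f"{reference.name}_random{k}"))
    return out


def empirical_p(observed: float, null_effects: np.ndarray) -> float:
    """Add-one empirical p: (1 + #{null ≥ observed}) / (n_null + 1).

    The add-one convention keeps p strictly positive, so an observed effect
    exceeding all 200 null draws reports 1/201 — below the 1/200 resolution
    of the null family, never zero.
    """
    null_effects = np.asarray(null_effects, dtype=float)
    return float((1 + (null_effects >= observed).sum()) / (len(null_effects) + 1))
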