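"""Hypergeometric overlap tests between edge sets and region-level anatomy.

Whether two predictive networks share more edges than chance is assessed
against the hypergeometric distribution: drawing ``N`` edges without
replacement from the ``M`` possible edges of the connectome, of which ``K``
belong to the other network, how surprising is an intersection of ``x``?
The headline p-value is the literal upper tail ``1 − F(x) = P(X > x)``;
the inclusive tail ``P(X ≥ x)`` is also reported because the two conventions
differ at the third decimal for the typical counts involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import NetworkMask, n_edges


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two edge sets of sizes K and N out of M, intersecting in x."""

    x: int
    K: int
    N: int
    M: int
    pct_combined: float   # 100·x / (K + N − x), percent of the union
    expected: float       # chance expectation K·N/M
    p_gt: float           # P(X > x), the 1 − F convention
    p_ge: float           # P(X ≥ x)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("x", "K", "N", "M", "pct_combined", "expected", "p_gt", "p_ge")}


def hypergeom_p(x: int, K: int, N: int, M: int, convention: str = "greater") -> float:
    """Tail probability of a hypergeometric overlap.

    Parameters
    ----------
    x : observed intersection size
    K : size of the first edge set
    N : size of the second edge set (number of draws)
    M : total number of edges in the pool
    convention : 'greater' returns P(X > x) = 1 − F(x); 'greater_equal'
        returns P(X ≥ x).

    Evaluated through the survival function of ``scipy.stats.hypergeom``,
    which works in log space and is stable for M ≈ 35,778.
    """
    x, K, N, M = int(x), int(K), int(N), int(M)
    if not (0 <= K <= M and 0 <= N <= M):
        raise ValueError(f"require 0 <= K, N <= M; got K={K}, N={N}, M={M}")
    if not (0 <= x <= min(K, N)):
        raise ValueError(f"require 0 <= x <= min(K, N); got x={x}, K={K}, N={N}")
    if x < max(0, N + K - M):
        raise ValueError(f"x={x} below the minimum feasible overlap {N + K - M}")
    dist = stats.hypergeom(M, K, N)
    if convention == "greater":
        return float(dist.sf(x))
    if convention == "greater_equal":
        return float(dist.sf(x - 1))
    raise ValueError(f"unknown convention {convention!r}")


def network_overlap(mask_a: NetworkMask, mask_b: NetworkMask,
                    sign_pair: tuple[str, str] = ("pos", "pos")) -> OverlapResult:
    """Hypergeometric overlap between the chosen sign-components of two masks."""
    if mask_a.n_parcels != mask_b.n_parcels:
        raise ValueError(f"masks disagree on parcel count: "
                         f"{mask_a.n_parcels} vs {mask_b.n_parcels}")
    p = mask_a.n_parcels
    ea = mask_a.edge_set(sign_pair[0])
    eb = mask_b.edge_set(sign_pair[1])
    x, K, N, M = len(ea & eb), len(ea), len(eb), n_edges(p)
    union = K + N - x
    return OverlapResult(
        x=x, K=K, N=N, M=M,
        pct_combined=100.0 * x / union if union else 0.0,
        expected=K * N / M if M else 0.0,
        p_gt=hypergeom_p(x, K, N, M, "greater"),
        p_ge=hypergeom_p(x, K, N, M, "greater_equal"),
    )


@dataclass
class RegionComposition:
    """Mask edges tallied by unordered macroscale region pair."""

    regions: list[str]
    counts: np.ndarray  # R×R symmetric, diagonal = within-region edges
    pct: np.ndarray     # counts normalized so the unique-cell total is 100

    @property
    def total_edges(self) -> int:
        iu = np.triu_indices(len(self.regions))
        return int(self.counts[iu].sum())


def region_composition(mask: NetworkMask, region_labels: pd.Series | dict) -> RegionComposition:
    """Percentage of a mask's edges falling in each region pair.

    ``region_labels`` maps parcel index → region name and must cover every
    parcel the mask touches.  Each undirected edge increments its unordered
    region-pair cell exactly once; percentages are over the mask's total
    edge count, so the unique cells sum to 100.
    """
    labels = pd.Series(region_labels)
    regions = sorted(labels.unique().tolist())
    idx = {r: k for k, r in enumerate(regions)}
    counts = np.zeros((len(regions), len(regions)), dtype=int)
    for i, j in mask.edge_set("any"):
        for parcel in (i, j):
            if parcel not in labels.index:
                raise ValueError(f"parcel {parcel} has no region label")
        a, b = sorted((idx[labels[i]], idx[labels[j]]))
        counts[a, b] += 1
    counts = counts + np.triu(counts, k=1).T  # mirror for a symmetric view
    total = mask.n_edges
    iu = np.triu_indices(len(regions))
    pct = np.zeros_like(counts, dtype=float)
    if total:
        pct = counts / total * 100.0
        # the mirrored lower triangle double-represents off-diagonal cells;
        # the unique-cell (upper-triangle incl. diagonal) percentages sum to 100
    return RegionComposition(regions=regions, counts=counts, pct=pct)


def composition_diff(a: RegionComposition, b: RegionComposition) -> np.ndarray:
    """Cell-wise percentage difference a − b (e.g. WM minus SA composition)."""
    if a.regions != b.regions:
        raise ValueError("compositions use different region sets")
    return a.pct - b.pct
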