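"""Block-wise functional connectivity and network-strength scoring.

This module holds the package's core domain objects — parcel time series,
block records, Fisher-z edge matrices, and trinary network masks — and the
operations that turn a parcellated BOLD run into scalar network-strength
scores: motion-based exclusion, optional confound regression + band-pass
denoising, block-wise Pearson/Fisher-z connectivity, signed strength
summation against a mask, within-matrix standardization, and per-condition
aggregation across blocks.

Conventions
-----------
* TR indexing is 0-based; block windows are half-open ``[onset, offset)``.
* Correlations are clipped to ``|r| <= 1 - 1e-6`` before ``atanh`` so a
  degenerate block cannot produce an infinite edge.
* Network strength sums each undirected edge once (upper triangle), with
  the mask's sign: positive-mask sum minus negative-mask sum.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("blockcpm")

CONDITIONS = ("zero_back", "two_back")
STIMULI = ("neutral_face", "negative_face", "positive_face", "place")

#: clip bound applied to Pearson r before the Fisher transform
R_CLIP = 1.0 - 1e-6

#: strict framewise-displacement exclusion profile (mm): (fd_mean, fd_max)
FD_STRICT = (0.2, 2.0)
#: liberal profile retaining roughly twice as many runs
FD_LIBERAL = (0.5, 5.0)

BLOCK_TABLE_COLUMNS = [
    "run_id", "block_index", "condition", "stimulus",
    "onset_tr", "offset_tr", "fd_mean", "fd_max",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def n_edges(p: int) -> int:
    """Number of unique undirected edges among ``p`` parcels: p(p-1)/2."""
    return p * (p - 1) // 2


def triu_index(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i < j) index pair used for all edge vectorization."""
    return np.triu_indices(p, k=1)


def vectorize(mat: np.ndarray) -> np.ndarray:
    """Flatten a symmetric P×P matrix to its length-E upper-triangle vector."""
    i, j = triu_index(mat.shape[0])
    return np.asarray(mat)[i, j]


def unvectorize(vec: np.ndarray, p: int) -> np.ndarray:
    """Inverse of :func:`vectorize`; returns a symmetric matrix, zero diagonal."""
    out = np.zeros((p, p), dtype=float)
    i, j = triu_index(p)
    out[i, j] = vec
    out[j, i] = vec
    return out


@dataclass
class ParcelTimeSeries:
    """A T×P matrix of parcel-averaged BOLD values for one subject × run."""

    values: np.ndarray
    tr: float
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("time series must be T×P with T >= 2")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BlockRecord:
    """Metadata for one task block within a run.

    ``onset_tr``/``offset_tr`` are 0-based TR indices with a half-open
    window; ``fd_mean``/``fd_max`` summarize framewise displacement (mm)
    over the block (or its parent run, when per-block motion is absent).
    """

    run_id: str
    block_index: int
    condition: str
    stimulus: str
    onset_tr: int
    offset_tr: int
    fd_mean: float
    fd_max: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}; expected one of {STIMULI}")
        if not (0 <= self.onset_tr < self.offset_tr):
            raise ValueError(f"invalid block window [{self.onset_tr}, {self.offset_tr})")


@dataclass
class EdgeMatrix:
    """P×P symmetric Fisher-z connectivity for one subject × block."""

    z: np.ndarray
    subject_id: str = ""
    run_id: str = ""
    block_index: int = -1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        p = self.z.shape[0]
        if self.z.shape != (p, p):
            raise ValueError("edge matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("edge matrix must be symmetric")
        if not np.isfinite(self.z).all():
            raise ValueError("edge matrix contains non-finite values")
        np.fill_diagonal(self.z, 0.0)

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]

    def vector(self) -> np.ndarray:
        return vectorize(self.z)


@dataclass
class NetworkMask:
    """Trinary symmetric mask: +1 / −1 marks predictive edges, 0 elsewhere.

    The unit of CPM models, overlap tests and lesioning.  ``w[i, j] = +1``
    means edge (i, j) predicts better behavior, −1 worse.
    """

    w: np.ndarray
    name: str = "mask"

    def __post_init__(self) -> None:
        w = np.asarray(self.w)
        if not np.array_equal(w, w.T):
            raise ValueError("mask must be symmetric")
        if not np.isin(w, (-1, 0, 1)).all():
            raise ValueError("mask entries must be in {-1, 0, +1}")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("mask diagonal must be zero")
        self.w = w.astype(np.int8)

    @property
    def n_parcels(self) -> int:
        return self.w.shape[0]

    @property
    def n_pos(self) -> int:
        return int((vectorize(self.w) == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((vectorize(self.w) == -1).sum())

    @property
    def n_edges(self) -> int:
        return self.n_pos + self.n_neg

    def edge_set(self, sign: str = "any") -> frozenset[tuple[int, int]]:
        """Edges as (i, j) pairs with i < j; ``sign`` in {'pos','neg','any'}."""
        i, j = triu_index(self.n_parcels)
        v = self.w[i, j]
        if sign == "pos":
            keep = v == 1
        elif sign == "neg":
            keep = v == -1
        elif sign == "any":
            keep = v != 0
        else:
            raise ValueError(f"unknown sign {sign!r}")
        return frozenset(zip(i[keep].tolist(), j[keep].tolist()))

    @classmethod
    def from_edges(
        cls,
        p: int,
        pos: Iterable[tuple[int, int]] = (),
        neg: Iterable[tuple[int, int]] = (),
        name: str = "mask",
    ) -> "NetworkMask":
        w = np.zeros((p, p), dtype=np.int8)
        for edges, val in ((pos, 1), (neg, -1)):
            for i, j in edges:
                if not (0 <= i < p and 0 <= j < p and i != j):
                    raise ValueError(f"edge ({i}, {j}) out of range for {p} parcels")
                if w[i, j] != 0 and w[i, j] != val:
                    raise ValueError(f"edge ({i}, {j}) assigned conflicting signs")
                w[i, j] = w[j, i] = val
        return cls(w=w, name=name)

    def __neg__(self) -> "NetworkMask":
        return NetworkMask(w=-self.w, name=self.name)


# ---------------------------------------------------------------------------
# tabular I/O (TSV everywhere; long-format masks are i, j, w with i < j)
# ---------------------------------------------------------------------------

def read_timeseries(path, tr: float = 0.8, subject_id: str = "", run_id: str = "") -> ParcelTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ParcelTimeSeries(values=df.to_numpy(float), tr=tr, subject_id=subject_id, run_id=run_id)


def write_timeseries(ts: ParcelTimeSeries, path) -> None:
    cols = [f"parcel_{k}" for k in range(ts.n_parcels)]
    pd.DataFrame(ts.values, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_block_table(path) -> list[BlockRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOCK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"block table missing columns: {missing}")
    return [
        BlockRecord(
            run_id=str(r.run_id), block_index=int(r.block_index),
            condition=str(r.condition), stimulus=str(r.stimulus),
            onset_tr=int(r.onset_tr), offset_tr=int(r.offset_tr),
            fd_mean=float(r.fd_mean), fd_max=float(r.fd_max),
        )
        for r in df.itertuples()
    ]


def write_block_table(blocks: Sequence[BlockRecord], path) -> None:
    pd.DataFrame([vars(b) for b in blocks])[BLOCK_TABLE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_mask(path, p: int | None = None, name: str | None = None) -> NetworkMask:
    """Read a mask from TSV, either long-format (i, j, w) or dense P×P."""
    df = pd.read_csv(path, sep="\t")
    if {"i", "j", "w"}.issubset(df.columns):
        if p is None:
            raise ValueError("long-format masks require the parcel count p")
        pos = [(int(r.i), int(r.j)) for r in df.itertuples() if r.w == 1]
        neg = [(int(r.i), int(r.j)) for r in df.itertuples() if r.w == -1]
        return NetworkMask.from_edges(p, pos=pos, neg=neg, name=name or str(path))
    return NetworkMask(w=df.to_numpy(int), name=name or str(path))


def write_mask(mask: NetworkMask, path) -> None:
    """Write a mask as long-format TSV (i, j, w), one row per nonzero edge."""
    i, j = triu_index(mask.n_parcels)
    v = mask.w[i, j]
    keep = v != 0
    pd.DataFrame({"i": i[keep], "j": j[keep], "w": v[keep]}).to_csv(path, sep="\t", index=False)


def read_edge_matrix(path, p: int | None = None, **ids) -> EdgeMatrix:
    df = pd.read_csv(path, sep="\t")
    if {"i", "j", "z"}.issubset(df.columns):
        if p is None:
            raise ValueError("long-format edge files require the parcel count p")
        z = np.zeros((p, p))
        ii, jj, vv = df["i"].to_numpy(int), df["j"].to_numpy(int), df["z"].to_numpy(float)
        z[ii, jj] = vv
        z[jj, ii] = vv
        return EdgeMatrix(z=z, **ids)
    return EdgeMatrix(z=df.to_numpy(float), **ids)


def write_edge_matrix(em: EdgeMatrix, path, fmt: str = "dense") -> None:
    if fmt == "long":
        i, j = triu_index(em.n_parcels)
        pd.DataFrame({"i": i, "j": j, "z": em.z[i, j]}).to_csv(
            path, sep="\t", index=False, float_format="%.8f")
    else:
        pd.DataFrame(em.z).to_csv(path, sep="\t", index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLog:
    """Line-oriented record of motion (and aggregation) exclusions."""

    lines: list[str] = field(default_factory=list)

    def add(self, item: str, reason: str) -> None:
        self.lines.append(f"{item}\t{reason}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + ("\n" if self.lines else ""))

    def __len__(self) -> int:
        return len(self.lines)


def motion_filter(
    blocks: Sequence[BlockRecord],
    fd_mean_max: float = FD_STRICT[0],
    fd_max_max: float = FD_STRICT[1],
    on_missing: str = "error",
) -> tuple[list[BlockRecord], ExclusionLog]:
    """Drop blocks (or runs) exceeding framewise-displacement thresholds.

    Retention requires ``fd_mean < fd_mean_max`` AND ``fd_max < fd_max_max``
    with strict inequality — a block sitting exactly at a threshold is
    excluded.  The default profile (0.2 mm mean, 2 mm max) is the stringent
    criterion appropriate for youth task fMRI; ``FD_LIBERAL`` (0.5, 5.0)
    retains roughly double the sample.
    """
    retained: list[BlockRecord] = []
    log = ExclusionLog()
    for b in blocks:
        tag = f"{b.run_id}:block{b.block_index}"
        if not (np.isfinite(b.fd_mean) and np.isfinite(b.fd_max)):
            if on_missing == "error":
                raise ValueError(f"missing FD for {tag}")
            log.add(tag, "missing FD")
            continue
        if b.fd_mean >= fd_mean_max:
            log.add(tag, f"fd_mean {b.fd_mean:.4f} >= {fd_mean_max}")
        elif b.fd_max >= fd_max_max:
            log.add(tag, f"fd_max {b.fd_max:.4f} >= {fd_max_max}")
        else:
            retained.append(b)
    return retained, log


def denoise(
    ts: ParcelTimeSeries,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] | None = (0.008, 0.12),
) -> ParcelTimeSeries:
    """Confound regression followed by FFT band-pass, applied per run.

    Each parcel series is demeaned, residualized against the confound
    columns (least squares; redundant columns dropped with a warning), then
    band-passed by zeroing FFT bins outside ``[low, high]`` Hz.  A
    simplified parcel-level stand-in for voxelwise nuisance regression.
    """
    x = ts.values - ts.values.mean(axis=0, keepdims=True)
    if confounds is not None:
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != x.shape[0]:
            raise ValueError("confounds must be row-aligned with the time series")
        c = c - c.mean(axis=0, keepdims=True)
        rank = np.linalg.matrix_rank(c) if c.size else 0
        if c.size and rank < c.shape[1]:
            logger.warning("confound matrix rank-deficient (%d < %d); using pseudo-inverse",
                           rank, c.shape[1])
        if c.size:
            beta, *_ = np.linalg.lstsq(c, x, rcond=None)
            x = x - c @ beta
    if band is not None:
        low, high = band
        nyquist = 0.5 / ts.tr
        if not (0 <= low < high <= nyquist):
            raise ValueError(f"band {band} outside (0, Nyquist={nyquist:.4f})")
        freqs = np.fft.rfftfreq(x.shape[0], d=ts.tr)
        spectrum = np.fft.rfft(x, axis=0)
        spectrum[(freqs < low) | (freqs > high)] = 0.0
        x = np.fft.irfft(spectrum, n=x.shape[0], axis=0)
    x = x - x.mean(axis=0, keepdims=True)
    return replace(ts, values=x)


def block_fc(ts: ParcelTimeSeries, block: BlockRecord, lag_trs: int = 0) -> EdgeMatrix:
    """Pairwise Pearson correlation over one block window, Fisher-z transformed.

    ``lag_trs`` shifts the window to absorb hemodynamic delay (default 0).
    Raises if the window is shorter than 3 TRs or any parcel is constant
    within it (the offending parcel is named).
    """
    onset, offset = block.onset_tr + lag_trs, block.offset_tr + lag_trs
    if offset - onset < 3:
        raise ValueError(f"block window [{onset}, {offset}) shorter than 3 TRs")
    if onset < 0 or offset > ts.n_trs:
        raise ValueError(f"block window [{onset}, {offset}) outside run of {ts.n_trs} TRs")
    seg = ts.values[onset:offset]
    sd = seg.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance parcel(s) {dead.tolist()} in block "
                         f"{block.run_id}:{block.block_index}")
    r = np.corrcoef(seg, rowvar=False)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return EdgeMatrix(z=z, subject_id=ts.subject_id, run_id=block.run_id,
                      block_index=block.block_index)


def network_strength(em: EdgeMatrix | np.ndarray, mask: NetworkMask) -> float:
    """Signed sum of Fisher-z values over the mask's unique edges.

    Equals (sum over +1 edges) − (sum over −1 edges); each undirected edge
    is counted once.  Linear in the edge matrix and odd in the mask.
    """
    z = em.z if isinstance(em, EdgeMatrix) else np.asarray(em, dtype=float)
    if z.shape != mask.w.shape:
        raise ValueError(f"shape mismatch: edges {z.shape} vs mask {mask.w.shape}")
    i, j = triu_index(mask.n_parcels)
    return float(np.dot(z[i, j], mask.w[i, j]))


def standardize_connectome(em: EdgeMatrix) -> EdgeMatrix:
    """Z-score the unique edge values within one matrix (mean 0, SD 1).

    Used when strengths from matrices with different global scales must be
    comparable across participants.  Affine-invariant and idempotent.
    """
    v = em.vector()
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant edge matrix")
    z = unvectorize((v - v.mean()) / sd, em.n_parcels)
    return replace(em, z=z)


def condition_strengths(
    block_matrices: Mapping[str, Sequence[tuple[BlockRecord, EdgeMatrix]]],
    mask: NetworkMask,
    condition: str,
    zscore: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-subject mean network strength over a condition's retained blocks.

    Parameters
    ----------
    block_matrices
        Mapping subject_id → sequence of (block record, edge matrix) pairs,
        already motion-filtered.
    condition
        'zero_back' or 'two_back'.
    zscore
        If True, the subject scores are z-scored across included subjects.

    Returns the per-subject score Series and the per-block strength table
    (columns subject_id, run_id, block_index, condition, mask_name,
    strength).  Subjects with no retained block in the condition are
    dropped (logged), not imputed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rows = []
    scores: dict[str, float] = {}
    for sid, pairs in block_matrices.items():
        vals = []
        for blk, em in pairs:
            if blk.condition != condition:
                continue
            s = network_strength(em, mask)
            vals.append(s)
            rows.append((sid, blk.run_id, blk.block_index, condition, mask.name, s))
        if vals:
            scores[sid] = float(np.mean(vals))
        else:
            logger.info("subject %s has no retained %s blocks; dropped", sid, condition)
    if not scores:
        raise ValueError(f"no subject has retained blocks for condition {condition!r}")
    out = pd.Series(scores, name=f"{mask.name}_{condition}_strength")
    if zscore:
        sd = out.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot z-score constant strength scores")
        out = (out - out.mean()) / sd
    table = pd.DataFrame(rows, columns=[
        "subject_id", "run_id", "block_index", "condition", "mask_name", "strength"])
    return out, table
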