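"""Batch self-organizing map (3×1) on renal-panel triples.

Unlike the per-analyte mixture model, the SOM clusters subjects on the joint
(creatinine, urea, uric acid) vector.  Each variable is scaled to zero mean
and unit SD; a 3×1 map is initialized by PCA — three codebooks placed along
the first principal axis at −2.5, 0 and +2.5 SDs of the PC1 scores from the
centroid — and fitted by the batch algorithm: assign every subject to the
nearest codebook (Euclidean, scaled space), then re-estimate each codebook as
the neighborhood-kernel-weighted mean over its own and neighboring nodes'
members.  The Gaussian neighborhood width shrinks linearly to zero over the
first half of the iteration budget, after which updates are pure cluster
means — i.e. the map finishes as 1-D constrained k-means.  The middle node
(by mean scaled codebook value) represents subjects with normal renal
function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import Dataset

logger = logging.getLogger(__name__)

RENAL_TRIPLE = ("creatinine", "urea", "uric_acid")


@dataclass
class SOMFit:
    """Fitted 3×1 map in scaled space."""

    grid: tuple[int, int]
    codebooks: np.ndarray        # (3, n_vars)
    center: np.ndarray           # per-variable scaling center
    scale: np.ndarray            # per-variable scaling SD
    assignments: np.ndarray      # node index per subject
    n_iter: int
    converged: bool


def build_vectors(ds: Dataset, analytes: tuple[str, ...] = RENAL_TRIPLE) -> pd.DataFrame:
    """One row per subject holding all requested analytes (complete cases).

    Input should already be cleaned and deduplicated (one record per subject
    and analyte).  Subjects missing any analyte are dropped with a logged
    count.  Returns a DataFrame indexed by subject_id with one column per
    analyte.
    """
    df = ds.df
    sub = df.loc[df["analyte"].isin(analytes)]
    wide = sub.pivot_table(index="subject_id", columns="analyte", values="value",
                           aggfunc="first")
    missing_cols = [a for a in analytes if a not in wide.columns]
    for a in missing_cols:
        wide[a] = np.nan
    wide = wide[list(analytes)]
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("build_vectors: dropped %d incomplete subject(s)", dropped)
    return complete


def scale_columns(X: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to SD 1 (n−1 denominator).

    Returns (scaled matrix, centers, scales).  Zero-variance columns are a
    hard error.
    """
    A = np.asarray(X, float)
    if A.shape[0] < 10:
        raise ValueError("column scaling needs at least 10 rows")
    center = A.mean(axis=0)
    scale = A.std(axis=0, ddof=1)
    if np.any(scale == 0):
        raise ValueError("zero-variance column cannot be scaled")
    return (A - center) / scale, center, scale


def inverse_scale(Z: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return Z * scale + center


def init_grid_pca(Z: np.ndarray, grid: tuple[int, int] = (3, 1),
                  span_sd: float = 2.5) -> np.ndarray:
    """PCA initialization of the 3×1 codebooks.

    Nodes are laid out along the first principal axis at
    {−span_sd, 0, +span_sd} × (SD of PC1 scores) from the centroid.
    """
    if grid != (3, 1):
        raise ValueError("only the 3x1 grid is supported")
    Z = np.asarray(Z, float)
    if Z.shape[0] < grid[0] * grid[1]:
        raise ValueError("fewer rows than map nodes")
    centroid = Z.mean(axis=0)
    C = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    if evals[-1] <= 1e-12:
        raise ValueError("rank-deficient data: no principal axis")
    pc1 = evecs[:, -1]
    scores = (Z - centroid) @ pc1
    s = scores.std(ddof=1)
    # orient the axis so node order runs low -> high in data space
    if pc1.sum() < 0:
        pc1 = -pc1
    offsets = np.array([-span_sd, 0.0, span_sd]) * s
    return centroid[None, :] + offsets[:, None] * pc1[None, :]


def _neighborhood(width: float, n_nodes: int = 3) -> np.ndarray:
    """Node-to-node Gaussian kernel matrix over grid distance (3×1 chain)."""
    d = np.abs(np.arange(n_nodes)[:, None] - np.arange(n_nodes)[None, :])
    if width <= 0:
        return np.eye(n_nodes)
    return np.exp(-(d.astype(float) ** 2) / (2.0 * width ** 2))


def batch_som_fit(Z: np.ndarray, init_codebooks: np.ndarray,
                  max_iter: int = 200, kernel_width0: float = 1.0,
                  center: np.ndarray | None = None,
                  scale: np.ndarray | None = None) -> SOMFit:
    """Batch SOM iteration from given codebooks.

    Per iteration: nearest-codebook assignment, then codebook update as the
    kernel-weighted mean of node sums.  The kernel width decays linearly from
    ``kernel_width0`` to 0 over the first half of ``max_iter`` (with
    ``kernel_width0 = 0`` this is exactly Lloyd's k-means from the same
    init).  Stops when assignments are unchanged in the pure-mean regime.
    Empty nodes keep their codebook for that iteration (warning).
    """
    Z = np.asarray(Z, float)
    books = np.asarray(init_codebooks, float).copy()
    n_nodes = books.shape[0]
    if len({tuple(np.round(b, 12)) for b in books}) < n_nodes:
        raise ValueError("initial codebooks must be distinct")
    half = max(1, max_iter // 2)
    assign = np.full(Z.shape[0], -1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        width = kernel_width0 * max(0.0, 1.0 - (it - 1) / half)
        dist = cdist(Z, books)
        new_assign = np.argmin(dist, axis=1)
        if width <= 0 and np.array_equal(new_assign, assign):
            converged = True
            assign = new_assign
            break
        assign = new_assign
        H = _neighborhood(width, n_nodes)
        sums = np.zeros_like(books)
        counts = np.zeros(n_nodes)
        for k in range(n_nodes):
            members = Z[assign == k]
            counts[k] = members.shape[0]
            if counts[k]:
                sums[k] = members.sum(axis=0)
        if np.any(counts == 0):
            warnings.warn("empty SOM node; codebook held fixed this iteration")
        denom = H @ counts
        numer = H @ sums
        ok = denom > 0
        books[ok] = numer[ok] / denom[ok, None]
    if center is None:
        center = np.zeros(books.shape[1])
    if scale is None:
        scale = np.ones(books.shape[1])
    return SOMFit(grid=(n_nodes, 1), codebooks=books, center=np.asarray(center),
                  scale=np.asarray(scale), assignments=assign,
                  n_iter=it, converged=converged)


def select_normal_node(fit: SOMFit) -> tuple[int, np.ndarray]:
    """Middle node by mean scaled codebook value across the analytes.

    Returns (node index, boolean mask over subjects).  An ordering tie gets a
    warning and falls back to the largest node.
    """
    means = fit.codebooks.mean(axis=1)
    order = np.argsort(means, kind="stable")
    mid = int(order[1])
    if len(np.unique(np.round(means, 12))) < len(means):
        warnings.warn("tied codebook ordering; picking the largest node")
        counts = np.bincount(fit.assignments, minlength=len(means))
        mid = int(np.argmax(counts))
    return mid, fit.assignments == mid


def partition_triples(vectors: pd.DataFrame, max_iter: int = 200,
                      kernel_width0: float = 1.0) -> tuple[SOMFit, pd.Index]:
    """Scale → PCA init → batch fit → middle node, on a subject×analyte table.

    Returns the fit and the subject ids of the normal (middle) node.
    """
    Z, center, scale = scale_columns(vectors)
    books0 = init_grid_pca(Z)
    fit = batch_som_fit(Z, books0, max_iter=max_iter,
                        kernel_width0=kernel_width0, center=center, scale=scale)
    mid, mask = select_normal_node(fit)
    logger.info("SOM: n=%d, normal-node fraction %.3f", len(vectors), mask.mean())
    return fit, vectors.index[mask]
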