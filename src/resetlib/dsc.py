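"""Dispersion separability criteria for reference-library quality.

The Modified DSC scores a CpG set by how well it separates purified cell
types in beta-value space:

    MDSC = min(Db*) / min(Dw*)

where Db* is the vector of Euclidean distances between every unordered pair
of cell-type centroids (lexicographic pair order) and Dw* the vector of mean
sample-to-own-centroid distances per cell type. Taking minima (rather than
the trace-of-scatter ratio of the classic batch-effect DSC) rewards
libraries that keep even the most lineage-related pair of cell types apart.

The classic trace-based DSC (Db = tr(Sb), Dw = tr(Sw)) is provided for
reference; it uses sample-share weighted scatter matrices, so

    tr(Sb) = sum_k (n_k/N) ||c_k - c_bar||^2
    tr(Sw) = (1/N) sum_i ||x_i - c_{k(i)}||^2.

Leave-one-out MDSC contributions (the score of the library with one CpG
deleted) are computed incrementally: each CpG's additive share of every
squared centroid distance and every squared sample-to-centroid distance is
subtracted before the minima are re-taken, so the whole vector costs
O(J* (K^2 + N)) instead of O(J*^2 (K^2 + N)).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import CellTypeAnnotation, DispersionSummary, MethylationMatrix
from .exceptions import (
    DegenerateDispersionError,
    DegenerateGroupError,
    InsufficientGroupsError,
    LibraryTooSmallError,
)

__all__ = [
    "cell_type_centroids",
    "between_dispersion",
    "within_dispersion",
    "modified_dsc",
    "classic_dsc",
    "loo_dsc_contributions",
]


def _grouping(m: MethylationMatrix, ann: CellTypeAnnotation) -> tuple[np.ndarray, list, np.ndarray]:
    """(group index per column, cell types, one-hot/n_k matrix for group means)."""
    gidx, types = ann.group_indices(m.sample_ids)
    K = len(types)
    counts = np.bincount(gidx, minlength=K)
    if np.any(counts == 0):
        empty = [types[k] for k in np.flatnonzero(counts == 0)]
        raise DegenerateGroupError(f"cell types with no samples in matrix: {empty}")
    G = np.zeros((m.n_samples, K))
    G[np.arange(m.n_samples), gidx] = 1.0 / counts[gidx]
    return gidx, types, G


def cell_type_centroids(m: MethylationMatrix, ann: CellTypeAnnotation) -> pd.DataFrame:
    """Per-CpG mean beta value of each cell type (J x K, lexicographic columns)."""
    _, types, G = _grouping(m, ann)
    return pd.DataFrame(m.values @ G, index=m.cpg_ids, columns=types)


def _pair_labels(types: Sequence) -> list:
    return list(combinations(types, 2))


def between_dispersion(centroids: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Euclidean distance between every unordered pair of centroids (Db*).

    Returns the K(K-1)/2 distances in lexicographic pair order along with
    the pair labels.
    """
    types = sorted(centroids.columns)
    if len(types) < 2:
        raise InsufficientGroupsError("between-cell-type dispersion requires K >= 2 cell types")
    C = centroids[types].to_numpy(float)
    pairs = _pair_labels(types)
    d = np.array([np.linalg.norm(C[:, types.index(a)] - C[:, types.index(b)]) for a, b in pairs])
    return d, pairs


def within_dispersion(
    m: MethylationMatrix, ann: CellTypeAnnotation, centroids: pd.DataFrame | None = None
) -> np.ndarray:
    """Mean sample-to-own-centroid Euclidean distance per cell type (Dw*).

    d_wk = (1/n_k) sum_i c_ik with c_ik the distance of sample i of type k
    to that type's centroid; an unweighted mean with no n-1 correction.
    """
    gidx, types, G = _grouping(m, ann)
    C = centroids[types].to_numpy(float) if centroids is not None else m.values @ G
    resid = m.values - C[:, gidx]
    dist = np.sqrt(np.einsum("jn,jn->n", resid, resid))
    return dist @ G


def modified_dsc(m: MethylationMatrix, ann: CellTypeAnnotation) -> DispersionSummary:
    """Modified DSC summary: min pairwise-centroid distance over min within distance."""
    gidx, types, G = _grouping(m, ann)
    C = m.values @ G
    between, pairs = between_dispersion(pd.DataFrame(C, index=m.cpg_ids, columns=types))
    resid = m.values - C[:, gidx]
    within = np.sqrt(np.einsum("jn,jn->n", resid, resid)) @ G
    min_w = within.min()
    if min_w <= 0:
        raise DegenerateDispersionError(
            "minimum within-cell-type dispersion is zero (duplicate samples or a "
            "single-sample cell type); the Modified DSC is undefined"
        )
    return DispersionSummary(
        cell_types=types,
        pair_labels=pairs,
        between=between,
        within=within,
        mdsc=float(between.min() / min_w),
    )


def classic_dsc(m: MethylationMatrix, ann: CellTypeAnnotation) -> DispersionSummary:
    """Classic trace-based DSC with sample-share (n_k/N) weighted scatter matrices."""
    gidx, types, G = _grouping(m, ann)
    N = m.n_samples
    K = len(types)
    counts = np.bincount(gidx, minlength=K)
    C = m.values @ G
    grand = C @ (counts / N)
    db = float(((C - grand[:, None]) ** 2).sum(axis=0) @ (counts / N))
    resid = m.values - C[:, gidx]
    dw = float((resid**2).sum() / N)
    between, pairs = between_dispersion(pd.DataFrame(C, index=m.cpg_ids, columns=types))
    within = np.sqrt(np.einsum("jn,jn->n", resid, resid)) @ G
    if dw <= 0:
        raise DegenerateDispersionError("within-group scatter trace is zero; DSC undefined")
    return DispersionSummary(
        cell_types=types,
        pair_labels=pairs,
        between=between,
        within=within,
        mdsc=float(between.min() / within.min()) if within.min() > 0 else None,
        classic_db=db,
        classic_dw=dw,
        classic_dsc=db / dw,
    )


def _loo_core(
    values: np.ndarray, gidx: np.ndarray, K: int
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Shared incremental machinery for the full-library MDSC and its LOO vector.

    Returns (mdsc, loo vector, between distances, within distances) for the
    J x N submatrix ``values`` whose columns belong to groups ``gidx``.
    Raises DegenerateDispersionError if any within minimum (full or LOO)
    vanishes.
    """
    J, N = values.shape
    counts = np.bincount(gidx, minlength=K).astype(float)
    G = np.zeros((N, K))
    G[np.arange(N), gidx] = 1.0 / counts[gidx]
    C = values @ G  # J x K centroids

    ia, ib = np.triu_indices(K, k=1)
    # per-CpG additive share of each squared pairwise centroid distance / each
    # squared sample-to-centroid distance
    contrib_b = (C[:, ia] - C[:, ib]) ** 2  # J x npairs
    contrib_w = (values - C[:, gidx]) ** 2  # J x N
    tot_b = contrib_b.sum(axis=0)
    tot_w = contrib_w.sum(axis=0)

    between = np.sqrt(tot_b)
    within = np.sqrt(tot_w) @ G
    if within.min() <= 0:
        raise DegenerateDispersionError("zero within-cell-type dispersion; MDSC undefined")
    mdsc = float(between.min() / within.min())

    d_b = np.sqrt(np.maximum(tot_b[None, :] - contrib_b, 0.0))  # J x npairs
    d_w = np.sqrt(np.maximum(tot_w[None, :] - contrib_w, 0.0)) @ G  # J x K
    min_w = d_w.min(axis=1)
    if np.any(min_w <= 0):
        raise DegenerateDispersionError("zero within-cell-type dispersion after leaving one CpG out")
    loo = d_b.min(axis=1) / min_w
    return mdsc, loo, between, within


def loo_dsc_contributions(
    m: MethylationMatrix, ann: CellTypeAnnotation, library: Sequence
) -> np.ndarray:
    """Modified DSC of the library with each CpG removed in turn (MDSC_-j).

    Computed incrementally from per-CpG squared-distance shares; the result
    is identical (to floating-point) to recomputing the MDSC J* times on
    libraries of size J*-1.
    """
    if len(library) < 2:
        raise LibraryTooSmallError("leave-one-out scores need a library of at least 2 CpGs")
    sub = m.restrict(library)
    gidx, types = ann.group_indices(sub.sample_ids)
    _grouping(sub, ann)  # validates non-empty groups
    _, loo, _, _ = _loo_core(sub.values, gidx, len(types))
    return loo
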