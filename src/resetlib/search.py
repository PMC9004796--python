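"""Reference library construction: candidate pools, the RESET stochastic
search, and the Legacy top/bottom-t-statistic baseline.

The search maintains a selection probability pi_j over a candidate pool Q of
cell-specific differentially methylated loci (DMLs). Each iteration draws a
library without replacement with probabilities proportional to pi, scores it
with the Modified DSC, scores every member's leave-one-out contribution, and
multiplies each member's pi by r = MDSC / MDSC_-j (CpGs whose removal hurts
the score gain probability). Probabilities of non-members are left alone in
the update step; all P probabilities are then floored at a small epsilon and
rescaled to sum to one. The reported solution is the library that achieved
the largest Modified DSC over all iterations (earlier iteration wins ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CandidateSet,
    CellTypeAnnotation,
    MethylationMatrix,
    ReferenceLibrary,
    SearchConfig,
    SearchState,
)
from .dsc import _loo_core, cell_type_centroids
from .exceptions import (
    DegenerateDispersionError,
    DegenerateGroupError,
    InsufficientPoolError,
    NumericError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TStatTable",
    "one_vs_rest_tstats",
    "legacy_library",
    "build_candidate_set",
    "sample_library",
    "update_probabilities",
    "reset_search",
    "finalize_library",
]


@dataclass
class TStatTable:
    """One-vs-rest two-sample t statistics, one column per cell type.

    Positive t means hypermethylated in that cell type relative to the
    pooled remaining types.
    """

    cpg_ids: np.ndarray
    cell_types: list
    tstat: np.ndarray  # J x K

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tstat, index=self.cpg_ids, columns=self.cell_types)


def one_vs_rest_tstats(
    ref: MethylationMatrix, ann: CellTypeAnnotation, welch: bool = False
) -> TStatTable:
    """Two-sample t statistics of each cell type against the pooled rest.

    Pooled-variance t by default (the classical choice for purified-reference
    DML screens); ``welch=True`` uses unequal-variance standard errors.
    CpGs with zero variance in both groups get t = 0 so constant probes can
    never rank as DMLs.
    """
    gidx, types = ann.group_indices(ref.sample_ids)
    K = len(types)
    counts = np.bincount(gidx, minlength=K)
    if np.any(counts < 2):
        small = [types[k] for k in np.flatnonzero(counts < 2)]
        raise DegenerateGroupError(f"t statistics need n_k >= 2 per cell type; too few: {small}")
    X = ref.values
    N = ref.n_samples
    t = np.empty((ref.n_cpgs, K))
    n_zero = 0
    for k in range(K):
        in_k = gidx == k
        n1, n2 = int(in_k.sum()), int(N - in_k.sum())
        x1, x2 = X[:, in_k], X[:, ~in_k]
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
        if welch:
            se2 = v1 / n1 + v2 / n2
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tk = (m1 - m2) / np.sqrt(se2)
        zero = se2 <= 0
        n_zero += int(zero.sum())
        tk[zero] = 0.0
        t[:, k] = tk
    if n_zero:
        logger.warning("one_vs_rest_tstats: %d zero-variance comparisons set to t=0", n_zero)
    return TStatTable(ref.cpg_ids.copy(), types, t)


def _ranked(t: TStatTable, k: int) -> tuple[np.ndarray, np.ndarray]:
    """CpG indices sorted for 'top' (most positive first) and 'bottom' picks.

    Ties broken by CpG id (stable, reproducible).
    """
    col = t.tstat[:, k]
    ids = t.cpg_ids.astype(str)
    asc = np.lexsort((ids, col))  # most negative first
    return asc[::-1], asc


def legacy_library(t: TStatTable, per_type: int) -> list:
    """Legacy baseline: union of per_type most-hyper and per_type most-hypo
    CpGs for each cell type (minfi pickCompProbes-style), deduplicated.

    Returned sorted; final size is at most 2 * per_type * K.
    """
    if per_type < 1:
        raise ValidationError("per_type must be at least 1")
    J, K = t.tstat.shape
    if 2 * per_type * K > J:
        raise InsufficientPoolError(
            f"requested {2 * per_type * K} CpGs from a pool of {J}"
        )
    chosen: set = set()
    for k in range(K):
        desc, asc = _ranked(t, k)
        chosen.update(t.cpg_ids[desc[:per_type]])
        chosen.update(t.cpg_ids[asc[:per_type]])
    return sorted(chosen)


def build_candidate_set(t: TStatTable, L: int) -> CandidateSet:
    """Candidate pool Q: L/2 most-hyper and L/2 most-hypo CpGs per cell type.

    A CpG claimed by several cell types enters Q once (tagged with the first
    lexicographic claimant); initial selection probabilities are uniform,
    pi_j = 1/P.
    """
    if L < 2 or L % 2 != 0:
        raise ValidationError("the per-cell-type DML budget L must be an even integer >= 2")
    J, K = t.tstat.shape
    if L * K > 2 * J:
        raise InsufficientPoolError(f"candidate budget L*K={L * K} exceeds 2J={2 * J}")
    half = L // 2
    ids: list = []
    tags: list = []
    seen: set = set()
    for k in range(K):
        desc, asc = _ranked(t, k)
        for tag, picks in ((f"{t.cell_types[k]}:hyper", desc[:half]), (f"{t.cell_types[k]}:hypo", asc[:half])):
            for j in picks:
                c = t.cpg_ids[j]
                if c not in seen:
                    seen.add(c)
                    ids.append(c)
                    tags.append(tag)
    P = len(ids)
    return CandidateSet(
        cpg_ids=np.asarray(ids, object),
        probs=np.full(P, 1.0 / P),
        L=L,
        source_cell_type=np.asarray(tags, object),
    )


def _sample_indices(probs: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling of ``size`` distinct indices without replacement.

    Implemented with Gumbel top-k keys, which is distributionally identical
    to sequential draws with renormalized weights (Plackett-Luce) but runs
    in one vectorized pass. Returns indices in draw order.
    """
    P = probs.size
    if not (1 <= size <= P):
        raise ValidationError(f"library size must be in [1, P={P}]")
    keys = np.log(np.maximum(probs, 1e-300)) + rng.gumbel(size=P)
    top = np.argpartition(-keys, size - 1)[:size]
    return top[np.argsort(-keys[top])]


def sample_library(q: CandidateSet, size: int, rng: np.random.Generator) -> list:
    """Draw a library of ``size`` distinct CpGs from Q with probabilities pi."""
    idx = _sample_indices(q.probs, size, rng)
    return list(q.cpg_ids[idx])


def update_probabilities(
    q: CandidateSet,
    library: Sequence,
    mdsc: float,
    loo: np.ndarray,
    prob_floor: float = 1e-12,
) -> CandidateSet:
    """Multiplicative probability update pi_j <- pi_j * MDSC/MDSC_-j for library
    members, then floor at ``prob_floor`` and rescale all P probabilities to 1.

    The floor prevents the multiplicative update from driving a probability
    to exact zero, which would permanently remove a CpG from the search.
    """
    loo = np.asarray(loo, float)
    if not np.isfinite(mdsc) or mdsc <= 0 or np.any(~np.isfinite(loo)) or np.any(loo <= 0):
        raise NumericError("probability update requires positive finite MDSC and LOO values")
    pos = {c: i for i, c in enumerate(q.cpg_ids)}
    try:
        idx = np.array([pos[c] for c in library], dtype=int)
    except KeyError as e:  # pragma: no cover - guarded by callers
        raise ValidationError(f"library CpG {e} not in candidate pool") from e
    probs = q.probs.copy()
    probs[idx] *= mdsc / loo
    probs = np.maximum(probs, prob_floor)
    probs /= probs.sum()
    return replace(q, probs=probs)


def reset_search(
    ref: MethylationMatrix,
    ann: CellTypeAnnotation,
    q: CandidateSet,
    cfg: SearchConfig,
) -> SearchState:
    """Run the stochastic library search for ``cfg.iterations`` iterations.

    Fully reproducible from ``cfg.seed``. Iterations whose library has
    degenerate within-cell-type dispersion are skipped (probabilities left
    untouched, mdsc recorded as NaN in the trace).
    """
    gidx, types = ann.group_indices(ref.sample_ids)
    K = len(types)
    cfg.validate(q.P, K)
    rng = np.random.default_rng(cfg.seed)

    pool = ref.restrict(q.cpg_ids)  # P x N, row order = candidate order
    values = pool.values
    probs = q.probs.copy()

    best_mdsc = -np.inf
    best_library: list = []
    it_col = np.arange(cfg.iterations)
    size_col = np.zeros(cfg.iterations, dtype=int)
    mdsc_col = np.full(cfg.iterations, np.nan)
    best_col = np.full(cfg.iterations, np.nan)

    for it in range(cfg.iterations):
        if cfg.size_mode == "fixed":
            size = cfg.j_star
        else:
            size = int(rng.integers(cfg.j_min, cfg.j_max + 1))
        idx = _sample_indices(probs, size, rng)
        size_col[it] = size
        try:
            mdsc, loo, _, _ = _loo_core(values[idx], gidx, K)
        except DegenerateDispersionError:
            logger.info("iteration %d skipped: degenerate within-cell-type dispersion", it)
            best_col[it] = best_mdsc if np.isfinite(best_mdsc) else np.nan
            continue
        mdsc_col[it] = mdsc
        if mdsc > best_mdsc:
            best_mdsc = mdsc
            best_library = list(q.cpg_ids[idx])
            logger.info("iteration %d: new best MDSC %.6g (size %d)", it, mdsc, size)
        best_col[it] = best_mdsc
        probs[idx] *= mdsc / loo
        probs = np.maximum(probs, cfg.prob_floor)
        probs /= probs.sum()

    trace = pd.DataFrame(
        {"iteration": it_col, "size": size_col, "mdsc": mdsc_col, "best_mdsc": best_col}
    )
    return SearchState(
        iteration=cfg.iterations,
        probs=probs,
        best_library=best_library,
        best_mdsc=float(best_mdsc) if np.isfinite(best_mdsc) else float("nan"),
        trace=trace,
    )


def finalize_library(
    ref: MethylationMatrix, ann: CellTypeAnnotation, cpg_ids: Sequence
) -> ReferenceLibrary:
    """Assemble the signature matrix M: per-cell-type mean beta over the
    reference samples, restricted to the chosen CpGs."""
    sub = ref.restrict(cpg_ids)
    centroids = cell_type_centroids(sub, ann)
    return ReferenceLibrary(
        cpg_ids=sub.cpg_ids,
        mean_matrix=centroids.to_numpy(float),
        cell_types=list(centroids.columns),
    )
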