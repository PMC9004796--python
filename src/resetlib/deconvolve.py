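"""Reference-based cell-mixture deconvolution by constrained least squares.

Each bulk sample's beta-value vector Y over the library CpGs is modelled as
E[Y] = M w where M is the J* x K cell-type signature matrix; the fractions
w are estimated per sample by

    min_w || Y - M w ||^2   s.t.  w >= 0,  sum_k w_k <= 1

(Houseman-style constrained projection). The constraint is kept as an
inequality; estimates are not renormalized to sum to one, so the slack
1 - sum(w) absorbs cell types absent from the reference.

K is small (a handful of cell types), so the quadratic program is solved
exactly by enumerating active sets: for every subset of fractions allowed
to be positive, with the sum constraint either slack or tight, the
equality-constrained least-squares solution is computed and the feasible
candidate with the smallest residual is returned. The optimum of the convex
QP is among these candidates, and the KKT residual of the returned solution
is checked against a 1e-6 contract.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np

from .datatypes import EvaluationReport, MethylationMatrix, MixtureProportions, ReferenceLibrary
from .exceptions import NumericError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["solve_fractions", "kkt_residual", "deconvolute", "evaluate_predictions"]


def solve_fractions(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve min ||y - M w||^2 s.t. w >= 0, sum(w) <= 1 exactly (small K)."""
    J, K = M.shape
    if K > 16:
        raise ValidationError("active-set enumeration supports at most 16 cell types")
    best_w = np.zeros(K)
    best_obj = float(y @ y)  # w = 0 candidate
    ones = np.ones(K)
    for r in range(1, K + 1):
        for S in combinations(range(K), r):
            S = np.asarray(S)
            Ms = M[:, S]
            # sum constraint slack
            ws, *_ = np.linalg.lstsq(Ms, y, rcond=None)
            if np.all(ws >= -1e-12) and ws.sum() <= 1 + 1e-12:
                resid = y - Ms @ ws
                obj = float(resid @ resid)
                if obj < best_obj - 1e-14:
                    best_obj, best_w = obj, _expand(ws, S, K)
            # sum constraint tight: KKT system [MsᵀMs, 1; 1ᵀ, 0][w; nu] = [Msᵀy; 1]
            A = np.zeros((r + 1, r + 1))
            A[:r, :r] = Ms.T @ Ms
            A[:r, r] = 1.0
            A[r, :r] = 1.0
            b = np.concatenate([Ms.T @ y, [1.0]])
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            ws = sol[:r]
            if np.all(ws >= -1e-12):
                resid = y - Ms @ ws
                obj = float(resid @ resid)
                if obj < best_obj - 1e-14:
                    best_obj, best_w = obj, _expand(ws, S, K)
    w = np.clip(best_w, 0.0, None)
    if w.sum() > 1.0:
        w *= 1.0 / w.sum()
    return w


def _expand(ws: np.ndarray, S: np.ndarray, K: int) -> np.ndarray:
    w = np.zeros(K)
    w[S] = ws
    return w


def kkt_residual(M: np.ndarray, y: np.ndarray, w: np.ndarray, tol: float = 1e-9) -> float:
    """Max violation of the KKT conditions of the constrained LS problem at w.

    Checks primal feasibility, dual feasibility of the implied multipliers
    and complementary slackness; used to verify solver output.
    """
    g = M.T @ (M @ w - y)  # gradient of 0.5||y-Mw||^2 is Mᵀ(Mw-y); factor 2 immaterial
    active_sum = w.sum() > 1 - 1e-8
    # stationarity: g - lam + nu*1 = 0, lam >= 0 (w>=0), nu >= 0 (sum<=1)
    if active_sum:
        free = w > tol
        nu = float(-g[free].mean()) if free.any() else 0.0
    else:
        nu = 0.0
    lam = g + nu
    res = [
        float(max(0.0, -w.min())),  # primal w >= 0
        float(max(0.0, w.sum() - 1)),  # primal sum <= 1
        float(max(0.0, -nu)),
        float(max(0.0, -(lam.min()))),  # dual feasibility
        float(np.abs(lam * w).max()),  # complementary slackness (w_i>0 -> lam_i=0)
        float(abs(nu * (1 - w.sum()))),
    ]
    return max(res)


def deconvolute(mix: MethylationMatrix, lib: ReferenceLibrary) -> MixtureProportions:
    """Estimate cell-type fractions of every sample in ``mix`` from library ``lib``."""
    sub = mix.restrict(lib.cpg_ids)  # raises listing missing CpGs
    M = lib.mean_matrix
    if np.linalg.matrix_rank(M) < M.shape[1]:
        warnings.warn(
            "signature matrix is rank deficient (near-duplicate cell-type "
            "signatures); fractions may not be identifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    W = np.empty((sub.n_samples, M.shape[1]))
    for i in range(sub.n_samples):
        y = sub.values[:, i]
        w = solve_fractions(M, y)
        res = kkt_residual(M, y, w)
        if res > 1e-6 * max(1.0, float(np.abs(M.T @ y).max())):
            raise NumericError(f"QP solution for sample {sub.sample_ids[i]} failed KKT check ({res:.3g})")
        W[i] = w
    return MixtureProportions(sub.sample_ids.copy(), list(lib.cell_types), W)


def evaluate_predictions(
    true_w: MixtureProportions, pred_w: MixtureProportions
) -> EvaluationReport:
    """Per-cell-type accuracy of predicted fractions against known fractions.

    R^2 is the squared Pearson correlation between true and predicted
    fractions across samples; RMSE is reported in percentage points
    (fractions x 100). Cell types whose true fractions have zero variance
    get a missing (NaN) R^2; means are unweighted over cell types
    (NaN-skipping for R^2).
    """
    if list(true_w.cell_types) != list(pred_w.cell_types):
        raise ValidationError("true and predicted proportions must share cell types (same order)")
    pred = pred_w.align_to(true_w.sample_ids)
    n = true_w.sample_ids.size
    if n < 3:
        raise ValidationError("R^2 needs at least 3 samples")
    K = len(true_w.cell_types)
    r2 = np.full(K, np.nan)
    rmse = np.empty(K)
    for k in range(K):
        a, b = true_w.w[:, k], pred.w[:, k]
        rmse[k] = float(np.sqrt(np.mean((a - b) ** 2)) * 100.0)
        if np.std(a) > 0 and np.std(b) > 0:
            r2[k] = float(np.corrcoef(a, b)[0, 1] ** 2)
        elif np.std(a) > 0 or np.std(b) > 0:
            r2[k] = 0.0
    return EvaluationReport(
        cell_types=list(true_w.cell_types),
        per_type_r2=r2,
        per_type_rmse=rmse,
        mean_r2=float(np.nanmean(r2)) if np.any(np.isfinite(r2)) else float("nan"),
        mean_rmse=float(rmse.mean()),
    )
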