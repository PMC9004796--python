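"""Variance in methylation explained by cell-proportion estimates.

For each CpG independently, an ordinary least-squares model regresses the
beta values on the estimated cell proportions (intercept plus K-1 of the K
cell types; one is dropped for identifiability, with the slack absorbed by
the intercept) and the coefficient of determination R^2_j is recorded. Two
libraries are compared by Delta_j = R^2_{j,A} - R^2_{j,B} and the fraction
of CpGs with Delta_j strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix, MixtureProportions
from .exceptions import ValidationError

__all__ = ["EwasComparison", "variance_explained", "compare_variance_explained"]


@dataclass
class EwasComparison:
    """Per-CpG R^2 difference between two sets of proportion estimates."""

    cpg_ids: np.ndarray
    r2_a: np.ndarray
    r2_b: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.r2_a - self.r2_b

    @property
    def prop_positive(self) -> float:
        d = self.delta
        ok = np.isfinite(d)
        return float(np.mean(d[ok] > 0)) if ok.any() else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cpg_id": self.cpg_ids, "r2_a": self.r2_a, "r2_b": self.r2_b, "delta": self.delta}
        )


def variance_explained(
    beta: MethylationMatrix, w_hat: MixtureProportions, drop: str | None = None
) -> np.ndarray:
    """Per-CpG OLS R^2 of beta values on estimated cell proportions.

    ``drop`` names the cell type excluded from the design (default: the
    last in the proportions' column order); when the proportions sum to a
    constant the choice does not affect R^2. Returns NaN for CpGs with zero
    total variance.
    """
    w = w_hat.align_to(beta.sample_ids)
    n, K = w.w.shape
    if n < K + 2:
        raise ValidationError(f"variance_explained needs at least K+2={K + 2} samples, got {n}")
    keep = list(range(K))
    if drop is not None:
        if drop not in w.cell_types:
            raise ValidationError(f"unknown cell type to drop: {drop!r}")
        keep.remove(list(w.cell_types).index(drop))
    else:
        keep = keep[:-1]
    X = np.column_stack([np.ones(n), w.w[:, keep]])
    Y = beta.values.T  # n x J
    # projection via least squares; pinv handles a collinear design gracefully
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    ssr = (resid**2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, np.nan)
    return np.clip(r2, 0.0, 1.0, out=r2, where=np.isfinite(r2))


def compare_variance_explained(
    cpg_ids, r2_a: np.ndarray, r2_b: np.ndarray
) -> EwasComparison:
    """Pair two per-CpG R^2 vectors into an :class:`EwasComparison`."""
    cpg_ids = np.asarray(cpg_ids, object)
    r2_a = np.asarray(r2_a, float)
    r2_b = np.asarray(r2_b, float)
    if not (cpg_ids.size == r2_a.size == r2_b.size):
        raise ValidationError("R^2 vectors and CpG ids must have equal length")
    return EwasComparison(cpg_ids=cpg_ids, r2_a=r2_a, r2_b=r2_b)
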