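"""Core data containers.

The universal currency is a CpG x sample matrix of methylation beta values
(fractions of methylated alleles, in [0, 1] for real array data; the
proof-of-principle simulator relaxes the range to arbitrary finite reals).
Containers are thin dataclasses over numpy arrays with identifier bookkeeping
and invariant checks; pandas DataFrames are used at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AnnotationMismatchError, ValidationError


def _as_id_array(ids: Sequence, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    if len(set(arr)) != arr.size:
        seen, dups = set(), []
        for x in arr:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(map(str, dups)))[:5]}")
    return arr


@dataclass
class MethylationMatrix:
    """CpG x sample matrix of methylation values with identifiers.

    Parameters
    ----------
    cpg_ids : sequence of str
        Unique CpG (row) identifiers, length J.
    sample_ids : sequence of str
        Unique sample (column) identifiers, length N.
    values : ndarray of shape (J, N)
        Finite real values. Real beta values lie in [0, 1]; range
        enforcement is the reader's job so simulated Normal features pass
        through unchanged.
    """

    cpg_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = _as_id_array(self.cpg_ids, "CpG ids")
        self.sample_ids = _as_id_array(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.cpg_ids.size, self.sample_ids.size):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.cpg_ids.size} CpGs x {self.sample_ids.size} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("methylation values must be finite (no NaN/inf)")

    @property
    def n_cpgs(self) -> int:
        return self.cpg_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MethylationMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    def restrict(self, cpg_ids: Sequence) -> "MethylationMatrix":
        """Row-subset (and reorder) to ``cpg_ids``; unknown ids are an error."""
        pos = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [str(c) for c in cpg_ids if c not in pos]
        if missing:
            raise ValidationError(f"CpGs absent from matrix: {missing[:10]}")
        idx = np.array([pos[c] for c in cpg_ids], dtype=int)
        return MethylationMatrix(np.asarray(cpg_ids, object), self.sample_ids.copy(), self.values[idx])


@dataclass
class CellTypeAnnotation:
    """Maps purified reference samples to cell-type labels."""

    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_id_array(self.sample_ids, "annotation sample ids")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != self.sample_ids.shape:
            raise ValidationError("annotation labels and sample ids differ in length")

    @property
    def cell_types(self) -> list:
        """Distinct cell-type names in deterministic (lexicographic) order."""
        return sorted(set(self.labels))

    @property
    def K(self) -> int:
        return len(self.cell_types)

    @property
    def counts(self) -> dict:
        types, n = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(types.tolist(), n.tolist()))

    def group_indices(self, sample_ids: Sequence) -> tuple[np.ndarray, list]:
        """Return (integer group index per sample, ordered cell types).

        ``sample_ids`` gives column order of the matrix being grouped; every
        id must be annotated.
        """
        lab = {s: l for s, l in zip(self.sample_ids, self.labels)}
        missing = [str(s) for s in sample_ids if s not in lab]
        if missing:
            raise AnnotationMismatchError(f"samples without annotation: {missing[:10]}")
        types = self.cell_types
        t_idx = {t: k for k, t in enumerate(types)}
        gidx = np.array([t_idx[lab[s]] for s in sample_ids], dtype=int)
        return gidx, types


@dataclass
class DispersionSummary:
    """Between/within cell-type dispersion and the DSC-family scalars.

    ``between`` holds the K(K-1)/2 pairwise Euclidean distances between
    cell-type centroids (lexicographic pair order, labelled by
    ``pair_labels``); ``within`` holds the K mean sample-to-centroid
    distances; ``mdsc = min(between) / min(within)``. The classic
    trace-of-scatter DSC fields are populated by :func:`resetlib.dsc.classic_dsc`.
    """

    cell_types: list
    pair_labels: list
    between: np.ndarray
    within: np.ndarray
    mdsc: float | None = None
    classic_db: float | None = None
    classic_dw: float | None = None
    classic_dsc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "cell_types": list(map(str, self.cell_types)),
            "pair_labels": [list(map(str, p)) for p in self.pair_labels],
            "between": np.asarray(self.between, float).tolist(),
            "within": np.asarray(self.within, float).tolist(),
            "mdsc": self.mdsc,
        }
        if self.classic_dsc is not None:
            d.update(
                classic_db=self.classic_db,
                classic_dw=self.classic_dw,
                classic_dsc=self.classic_dsc,
            )
        return d


@dataclass
class CandidateSet:
    """The candidate pool Q of P cell-specific DMLs with selection probabilities."""

    cpg_ids: np.ndarray
    probs: np.ndarray
    L: int
    source_cell_type: np.ndarray  # e.g. "CD4T:hyper"; first-claiming tag after dedupe

    def __post_init__(self) -> None:
        self.cpg_ids = _as_id_array(self.cpg_ids, "candidate CpG ids")
        self.probs = np.asarray(self.probs, dtype=float)
        self.source_cell_type = np.asarray(self.source_cell_type, dtype=object)
        if self.probs.shape != self.cpg_ids.shape:
            raise ValidationError("probs and cpg_ids differ in length")
        if np.any(self.probs < 0) or not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValidationError("selection probabilities must be nonnegative and sum to 1")

    @property
    def P(self) -> int:
        return self.cpg_ids.size


@dataclass
class SearchConfig:
    """Configuration of the stochastic library search.

    ``size_mode='fixed'`` samples libraries of ``j_star`` CpGs every
    iteration; ``'random'`` redraws the size uniformly on
    [``j_min``, ``j_max``] each iteration.
    """

    iterations: int
    size_mode: str = "fixed"
    j_star: int | None = None
    j_min: int | None = None
    j_max: int | None = None
    seed: int | None = None
    prob_floor: float = 1e-12

    def validate(self, P: int, K: int) -> None:
        if self.iterations < 0:
            raise ValidationError("iterations must be nonnegative")
        if self.size_mode == "fixed":
            if self.j_star is None or not (K <= self.j_star <= P):
                raise ValidationError(f"fixed library size must satisfy K={K} <= j_star <= P={P}")
        elif self.size_mode == "random":
            if self.j_min is None or self.j_max is None:
                raise ValidationError("random size mode requires j_min and j_max")
            if not (K <= self.j_min <= self.j_max <= P):
                raise ValidationError(f"random size bounds must satisfy K={K} <= j_min <= j_max <= P={P}")
        else:
            raise ValidationError(f"unknown size_mode {self.size_mode!r}")
        if not (0 < self.prob_floor < 1):
            raise ValidationError("prob_floor must be in (0, 1)")


@dataclass
class SearchState:
    """Result of a search run: final probabilities, best library and trace."""

    iteration: int
    probs: np.ndarray
    best_library: list
    best_mdsc: float
    trace: pd.DataFrame  # columns: iteration, size, mdsc, best_mdsc


@dataclass
class ReferenceLibrary:
    """A chosen CpG subset plus its J* x K cell-type mean signature matrix M."""

    cpg_ids: np.ndarray
    mean_matrix: np.ndarray
    cell_types: list

    def __post_init__(self) -> None:
        self.cpg_ids = _as_id_array(self.cpg_ids, "library CpG ids")
        self.mean_matrix = np.asarray(self.mean_matrix, dtype=float)
        if self.mean_matrix.shape != (self.cpg_ids.size, len(self.cell_types)):
            raise ValidationError("mean matrix shape does not match library CpGs x cell types")
        if not np.all(np.isfinite(self.mean_matrix)):
            raise ValidationError("mean matrix must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_matrix, index=self.cpg_ids, columns=self.cell_types)


@dataclass
class MixtureProportions:
    """Sample x cell-type fraction matrix; rows in [0,1] with sum <= 1."""

    sample_ids: np.ndarray
    cell_types: list
    w: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_id_array(self.sample_ids, "proportion sample ids")
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (self.sample_ids.size, len(self.cell_types)):
            raise ValidationError("proportions shape does not match samples x cell types")
        if np.any(self.w < -1e-8) or np.any(self.w > 1 + 1e-8):
            raise ValidationError("cell proportions must lie in [0, 1]")
        if np.any(self.w.sum(axis=1) > 1 + 1e-6):
            raise ValidationError("cell proportions of a sample must sum to at most 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MixtureProportions":
        return cls(df.index.to_numpy(object), list(df.columns), df.to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.sample_ids, columns=self.cell_types)

    def align_to(self, sample_ids: Sequence) -> "MixtureProportions":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [str(s) for s in sample_ids if s not in pos]
        if missing:
            raise AnnotationMismatchError(f"samples without proportions: {missing[:10]}")
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return MixtureProportions(np.asarray(sample_ids, object), list(self.cell_types), self.w[idx])


@dataclass
class EvaluationReport:
    """Deconvolution accuracy: per-cell-type R^2 and RMSE (percentage points)."""

    cell_types: list
    per_type_r2: np.ndarray
    per_type_rmse: np.ndarray
    mean_r2: float
    mean_rmse: float

    @property
    def mspe(self) -> np.ndarray:
        """Mean squared prediction error tau^2 per cell type (percentage points squared)."""
        return np.asarray(self.per_type_rmse, float) ** 2

    def to_dict(self) -> dict:
        return {
            "cell_types": list(map(str, self.cell_types)),
            "per_type_r2": np.asarray(self.per_type_r2, float).tolist(),
            "per_type_rmse": np.asarray(self.per_type_rmse, float).tolist(),
            "mean_r2": self.mean_r2,
            "mean_rmse": self.mean_rmse,
            "mspe": self.mspe.tolist(),
        }


@dataclass
class BetaMixtureModel:
    """Per-CpG beta-distribution model of heterogeneous-tissue methylation.

    A bulk sample with cell fractions w has mean methylation m = w . mu_j
    at CpG j and variance m(1-m)/(1+phi_j); mu_j is the K-vector of
    cell-type mean beta values and phi_j > 0 the precision.
    """

    cpg_ids: np.ndarray
    cell_types: list
    mu: np.ndarray  # J x K, entries in (0, 1)
    phi: np.ndarray  # J, positive
    converged: np.ndarray | None = None  # per-CpG MLE convergence flag when fitted

    def __post_init__(self) -> None:
        self.cpg_ids = _as_id_array(self.cpg_ids, "model CpG ids")
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.mu.shape != (self.cpg_ids.size, len(self.cell_types)):
            raise ValidationError("mu shape does not match CpGs x cell types")
        if np.any(self.mu <= 0) or np.any(self.mu >= 1):
            raise ValidationError("cell-type mean beta values must lie strictly in (0, 1)")
        if self.phi.shape != self.cpg_ids.shape or np.any(self.phi <= 0):
            raise ValidationError("precision parameters must be positive, one per CpG")
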