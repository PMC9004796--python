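"""Synthetic-data generators for the package's study designs.

Four families of simulators live here:

* a proof-of-principle generator of Normal-distributed "methylation"
  features for three cell types, used to map how the Modified DSC responds
  to the fraction of differential features and their effect magnitude;
* a beta-distributed model of heterogeneous-tissue methylation with mean
  w . mu_j and precision phi_j, plus a per-CpG maximum-likelihood fitter;
* a null two-group EWAS simulation measuring the false-positive proportion
  of cell-composition-adjusted per-CpG regressions; and
* a purified-reference generator with planted cell-specific DMLs for
  end-to-end tests of library search and deconvolution.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import (
    BetaMixtureModel,
    CellTypeAnnotation,
    MethylationMatrix,
    MixtureProportions,
)
from .dsc import modified_dsc
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PopSimConfig",
    "FDRSimConfig",
    "simulate_celltype_features",
    "dsc_grid",
    "simulate_beta_methylation",
    "fit_beta_model",
    "random_beta_model",
    "sample_group_proportions",
    "perturb_proportions",
    "fdr_simulation",
    "FdrResult",
    "synth_reference",
    "WHOLE_BLOOD_BASE",
]

#: Whole-blood-like mean cell-type composition (granulocyte dominant), the
#: default base profile for the two-group composition simulator.
WHOLE_BLOOD_BASE = {
    "B": 0.027,
    "CD4T": 0.132,
    "CD8T": 0.060,
    "Gran": 0.690,
    "Mono": 0.062,
    "NK": 0.029,
}


@dataclass
class PopSimConfig:
    """Proof-of-principle generator settings.

    ``frac_diff`` of the ``n_features`` features are differential: each such
    feature independently assigns the mean triple (0, +delta, -delta) to the
    three cell types in a uniformly random order; all other features (and
    all noise) are standard Normal.
    """

    n_features: int = 100
    K: int = 3
    n_per: int = 6
    frac_diff: float = 0.0
    delta: float = 1.0
    seed: int | None = None

    def validate(self) -> None:
        if self.K != 3:
            raise ValidationError("the mean-triple (0, +delta, -delta) scheme requires K = 3")
        if not 0 <= self.frac_diff <= 1:
            raise ValidationError("frac_diff must lie in [0, 1]")
        if self.n_per < 2:
            raise ValidationError("need at least 2 samples per cell type")


def simulate_celltype_features(
    cfg: PopSimConfig,
) -> tuple[MethylationMatrix, CellTypeAnnotation]:
    """Generate the Normal-feature cell-type dataset of the proof-of-principle design."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    J, K, n = cfg.n_features, cfg.K, cfg.n_per
    n_diff = int(round(cfg.frac_diff * J))
    diff_rows = rng.choice(J, size=n_diff, replace=False)
    means = np.zeros((J, K))
    triple = np.array([0.0, cfg.delta, -cfg.delta])
    for j in diff_rows:
        means[j] = rng.permutation(triple)
    values = rng.normal(loc=np.repeat(means, n, axis=1), scale=1.0, size=(J, K * n))
    cpg_ids = np.array([f"f{j:04d}" for j in range(J)], object)
    types = [f"cell{chr(65 + k)}" for k in range(K)]
    sample_ids = np.array([f"{t}_s{i}" for t in types for i in range(n)], object)
    labels = np.array([t for t in types for _ in range(n)], object)
    return (
        MethylationMatrix(cpg_ids, sample_ids, values),
        CellTypeAnnotation(sample_ids, labels),
    )


def dsc_grid(
    deltas=tuple(range(1, 11)),
    fracs=tuple(np.round(np.arange(0, 1.05, 0.05), 2)),
    reps: int = 20,
    seed: int | None = None,
    n_features: int = 100,
    n_per: int = 6,
) -> pd.DataFrame:
    """Mean (and sd) Modified DSC over replicates for each (fraction, delta) cell.

    The default grid is 21 fractions x 10 magnitudes = 210 cells.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for frac in fracs:
        for delta in deltas:
            child = ss.spawn(1)[0]
            seeds = child.generate_state(reps) % (2**31)
            vals = np.empty(reps)
            for r in range(reps):
                cfg = PopSimConfig(
                    n_features=n_features,
                    frac_diff=float(frac),
                    delta=float(delta),
                    n_per=n_per,
                    seed=int(seeds[r]),
                )
                m, ann = simulate_celltype_features(cfg)
                vals[r] = modified_dsc(m, ann).mdsc
            rows.append(
                {
                    "frac_diff": float(frac),
                    "delta": float(delta),
                    "mean_mdsc": float(vals.mean()),
                    "sd_mdsc": float(vals.std(ddof=1)) if reps > 1 else 0.0,
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta-distributed heterogeneous methylation


def simulate_beta_methylation(
    w: MixtureProportions, model: BetaMixtureModel, seed: int | None = None
) -> MethylationMatrix:
    """Draw bulk beta values: Y_ij ~ Beta with mean m_ij = w_i . mu_j and
    precision phi_j (shapes a = m phi, b = (1-m) phi)."""
    if list(w.cell_types) != list(model.cell_types):
        raise ValidationError("proportions and model must share cell types (same order)")
    rng = np.random.default_rng(seed)
    m = w.w @ model.mu.T  # N x J
    if np.any(m <= 0) or np.any(m >= 1):
        raise ValidationError("mixture means w . mu must lie strictly in (0, 1)")
    a = m * model.phi[None, :]
    b = (1.0 - m) * model.phi[None, :]
    y = rng.beta(a, b)
    # guard against exact 0/1 from floating-point underflow at extreme shapes
    y = np.clip(y, 1e-12, 1 - 1e-12)
    return MethylationMatrix(model.cpg_ids.copy(), w.sample_ids.copy(), y.T)


def _fit_one_beta(y: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Constrained MLE of (mu in (0,1)^K, phi > 0) for one CpG.

    The mean is identity-linked in the fractions, m_i = w_i . mu, with mu
    box-constrained via a logistic transform and phi via log. Falls back to
    the method-of-moments start on non-convergence.
    """
    n, K = W.shape

    def unpack(theta):
        mu = special.expit(theta[:K])
        phi = np.exp(theta[K])
        return mu, phi

    def nll(theta):
        mu, phi = unpack(theta)
        m = W @ mu
        if np.any(m <= 1e-10) or np.any(m >= 1 - 1e-10):
            return 1e10
        a, b = m * phi, (1 - m) * phi
        return -np.sum(stats.beta.logpdf(y, a, b))

    # method-of-moments start: LS for mu, variance relation for phi
    mu0, *_ = np.linalg.lstsq(W, y, rcond=None)
    mu0 = np.clip(mu0, 0.02, 0.98)
    m0 = np.clip(W @ mu0, 1e-3, 1 - 1e-3)
    resid = y - m0
    v = float(np.mean(resid**2))
    phi0 = max(float(np.mean(m0 * (1 - m0)) / max(v, 1e-8) - 1.0), 1.0)
    theta0 = np.concatenate([special.logit(mu0), [np.log(phi0)]])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    if res.success and np.isfinite(res.fun):
        mu, phi = unpack(res.x)
        return mu, phi, True
    return mu0, phi0, False


def fit_beta_model(beta: MethylationMatrix, w: MixtureProportions) -> BetaMixtureModel:
    """Per-CpG beta-regression fit of cell-type means and precision.

    Requires the fractions to vary across samples; CpGs whose MLE does not
    converge fall back to method-of-moments estimates and are flagged in
    ``converged``.
    """
    wal = w.align_to(beta.sample_ids)
    n, K = wal.w.shape
    if n < K + 2:
        raise ValidationError(f"beta-model fitting needs at least K+2={K + 2} samples")
    if np.linalg.matrix_rank(wal.w) < K:
        raise ValidationError(
            "cell fractions are collinear across samples; cell-type means are unidentifiable"
        )
    J = beta.n_cpgs
    mu = np.empty((J, K))
    phi = np.empty(J)
    conv = np.zeros(J, dtype=bool)
    for j in range(J):
        mu[j], phi[j], conv[j] = _fit_one_beta(beta.values[j], wal.w)
    if not conv.all():
        logger.warning("fit_beta_model: %d/%d CpGs used method-of-moments fallback", int((~conv).sum()), J)
    mu = np.clip(mu, 1e-4, 1 - 1e-4)
    return BetaMixtureModel(
        cpg_ids=beta.cpg_ids.copy(),
        cell_types=list(wal.cell_types),
        mu=mu,
        phi=phi,
        converged=conv,
    )


def random_beta_model(
    n_cpgs: int,
    cell_types=tuple(sorted(WHOLE_BLOOD_BASE)),
    phi_range: tuple[float, float] = (20.0, 100.0),
    seed: int | None = None,
) -> BetaMixtureModel:
    """A synthetic per-CpG model with cell-type-structured means.

    Each CpG gets a baseline mean in (0.1, 0.9) plus independent cell-type
    deviations, mimicking the mixture of shared and cell-specific loci on a
    methylation array; precisions are uniform on ``phi_range``.
    """
    rng = np.random.default_rng(seed)
    K = len(cell_types)
    base = rng.uniform(0.1, 0.9, size=n_cpgs)
    dev = rng.normal(0.0, 0.15, size=(n_cpgs, K))
    mu = np.clip(base[:, None] + dev, 0.02, 0.98)
    phi = rng.uniform(*phi_range, size=n_cpgs)
    ids = np.array([f"cg{j:06d}" for j in range(n_cpgs)], object)
    return BetaMixtureModel(ids, list(cell_types), mu, phi)


# ---------------------------------------------------------------------------
# two-group composition and the null EWAS / FDR study


def sample_group_proportions(
    n1: int,
    n2: int,
    dissimilarity: float,
    base: dict | None = None,
    concentration: float = 50.0,
    seed: int | None = None,
) -> tuple[MixtureProportions, np.ndarray]:
    """Dirichlet cell compositions for two groups with a mean-composition shift.

    Group 1 is centred at ``base``; group 2 at ``base`` with ``dissimilarity/2``
    of mass moved from the largest base component to the smallest, so the
    total absolute difference of the group mean compositions equals
    ``dissimilarity``. ``concentration`` scales the Dirichlet parameters and
    controls within-group variability. Returns the stacked proportions and a
    0/1 group indicator.
    """
    base = dict(WHOLE_BLOOD_BASE) if base is None else dict(base)
    types = sorted(base)
    p = np.array([base[t] for t in types], float)
    p = p / p.sum()
    shift = np.zeros_like(p)
    donor, recip = int(np.argmax(p)), int(np.argmin(p))
    shift[donor] -= dissimilarity / 2.0
    shift[recip] += dissimilarity / 2.0
    p2 = p + shift
    if np.any(p2 <= 0) or np.any(p <= 0):
        raise ValidationError("composition shift pushes a group mean proportion to <= 0")
    rng = np.random.default_rng(seed)
    w1 = rng.dirichlet(p * concentration, size=n1)
    w2 = rng.dirichlet(p2 * concentration, size=n2)
    w = np.vstack([w1, w2])
    ids = np.array([f"s{i:04d}" for i in range(n1 + n2)], object)
    group = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])
    return MixtureProportions(ids, types, w), group


def perturb_proportions(
    w: MixtureProportions, tau2, seed: int | None = None
) -> MixtureProportions:
    """Emulate deconvolution error: add Normal(0, tau_k^2) noise per cell type.

    ``tau2`` is the mean squared prediction error per cell type in
    percentage points squared (the scale on which deconvolution RMSEs are
    reported); it is converted to the fraction scale internally. Results are
    clipped to [0, 1] and rows exceeding unit sum are rescaled.
    """
    tau2 = np.asarray(tau2, float)
    if tau2.ndim == 0:
        tau2 = np.full(len(w.cell_types), float(tau2))
    if tau2.size != len(w.cell_types) or np.any(tau2 < 0):
        raise ValidationError("tau2 must be a nonnegative value per cell type")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(tau2) / 100.0
    noisy = w.w + rng.normal(0.0, 1.0, size=w.w.shape) * sd[None, :]
    noisy = np.clip(noisy, 0.0, 1.0)
    rowsum = noisy.sum(axis=1)
    over = rowsum > 1.0 + 1e-12  # tolerate float round-off on exact-simplex rows
    noisy[over] /= rowsum[over, None]
    return MixtureProportions(w.sample_ids.copy(), list(w.cell_types), noisy)


@dataclass
class FDRSimConfig:
    """Null two-group EWAS simulation settings.

    Methylation is simulated with **no** group effect; the groups differ
    only in cell composition (controlled by ``dissimilarity``), so every
    rejection of the group coefficient at ``alpha`` is a false positive.
    ``adjustment`` selects the composition covariates entered into the
    per-CpG regression: ``"none"``, ``"true"`` (the simulated fractions) or
    ``"noisy"`` (fractions perturbed with per-type MSPE ``tau2``, emulating
    a deconvolution method with that error profile).
    """

    n1: int = 100
    n2: int = 100
    n_cpgs: int = 1000
    dissimilarity: float = 0.0
    alpha: float = 0.05
    adjustment: str = "true"
    tau2: np.ndarray | float | None = None
    base: dict | None = None
    concentration: float = 50.0
    n_reps: int = 10
    seed: int | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.adjustment not in ("none", "true", "noisy"):
            raise ValidationError("adjustment must be 'none', 'true' or 'noisy'")
        if self.adjustment == "noisy" and self.tau2 is None:
            raise ValidationError("noisy adjustment requires tau2")


@dataclass
class FdrResult:
    """False-positive proportion of the null EWAS simulation."""

    fdr: float  # mean over replicates of the fraction of null CpGs with p < alpha
    per_replicate: np.ndarray
    pvalues: np.ndarray  # last replicate's per-CpG p-values
    config: FDRSimConfig


def _group_pvalues(Y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the group coefficient (column 1 of the design)
    from per-CpG OLS fits, vectorized across CpGs."""
    n, p = design.shape
    XtX_inv = np.linalg.pinv(design.T @ design)
    H = XtX_inv @ design.T
    coef = H @ Y  # p x J
    resid = Y - design @ coef
    df = n - np.linalg.matrix_rank(design)
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef[1] / se
    return 2.0 * stats.t.sf(np.abs(tstat), df)


def fdr_simulation(cfg: FDRSimConfig, model: BetaMixtureModel) -> FdrResult:
    """Estimate the false-positive proportion of cell-composition-adjusted EWAS.

    Per replicate: draw two groups' cell compositions, simulate null beta
    values from ``model``, regress each CpG on intercept + group indicator +
    K-1 composition covariates (per ``cfg.adjustment``), and record the
    fraction of CpGs rejected at ``cfg.alpha``. All CpGs are null, so the
    rejection fraction is an empirical type-I error proportion.
    """
    cfg.validate()
    if model.cpg_ids.size < cfg.n_cpgs:
        raise ValidationError("model has fewer CpGs than requested")
    ss = np.random.SeedSequence(cfg.seed)
    per_rep = np.empty(cfg.n_reps)
    pvals = None
    for rep, child in enumerate(ss.spawn(cfg.n_reps)):
        s = child.generate_state(4) % (2**31)
        rng = np.random.default_rng(int(s[0]))
        sub = np.sort(rng.choice(model.cpg_ids.size, size=cfg.n_cpgs, replace=False))
        sub_model = BetaMixtureModel(
            model.cpg_ids[sub], list(model.cell_types), model.mu[sub], model.phi[sub]
        )
        w, group = sample_group_proportions(
            cfg.n1, cfg.n2, cfg.dissimilarity, cfg.base, cfg.concentration, seed=int(s[1])
        )
        bulk = simulate_beta_methylation(w, sub_model, seed=int(s[2]))
        cols = [np.ones(cfg.n1 + cfg.n2), group.astype(float)]
        if cfg.adjustment != "none":
            w_cov = w
            if cfg.adjustment == "noisy":
                w_cov = perturb_proportions(w, cfg.tau2, seed=int(s[3]))
            cols.append(w_cov.w[:, :-1])  # K-1 covariates
        design = np.column_stack(cols)
        pvals = _group_pvalues(bulk.values.T, design)
        per_rep[rep] = float(np.mean(pvals < cfg.alpha))
    return FdrResult(float(per_rep.mean()), per_rep, pvals, cfg)


# ---------------------------------------------------------------------------
# synthetic purified references with planted DMLs


def synth_reference(
    n_cpgs: int = 500,
    K: int = 4,
    n_per: int = 6,
    n_dml_per_type: int = 10,
    effect: float = 0.3,
    phi: float = 60.0,
    seed: int | None = None,
) -> tuple[MethylationMatrix, CellTypeAnnotation, pd.DataFrame]:
    """Beta-distributed purified-cell reference with planted cell-specific DMLs.

    Per cell type, ``n_dml_per_type`` CpGs have their mean shifted by
    ``effect`` in that cell type only (half hypermethylated, half
    hypomethylated); the rest share a common mean per CpG. Returns the
    reference matrix, the annotation and a truth table (cpg_id, cell_type,
    direction) for enrichment tests.
    """
    if n_dml_per_type * K > n_cpgs:
        raise ValidationError("more planted DMLs than CpGs")
    if not 0 <= effect < 0.9:
        raise ValidationError("effect must lie in [0, 0.9)")
    rng = np.random.default_rng(seed)
    types = [f"cell{chr(65 + k)}" for k in range(K)]
    cpg_ids = np.array([f"cg{j:05d}" for j in range(n_cpgs)], object)
    lo, hi = 0.05, 0.95
    mu = np.tile(rng.uniform(lo, hi, size=n_cpgs)[:, None], (1, K))
    order = rng.permutation(n_cpgs)
    truth_rows = []
    pos = 0
    for k, t in enumerate(types):
        for d in range(n_dml_per_type):
            j = order[pos]
            pos += 1
            hyper = d < (n_dml_per_type + 1) // 2
            if hyper:
                baseline = rng.uniform(lo, hi - effect)
                mu[j, :] = baseline
                mu[j, k] = baseline + effect
            else:
                baseline = rng.uniform(lo + effect, hi)
                mu[j, :] = baseline
                mu[j, k] = baseline - effect
            truth_rows.append({"cpg_id": cpg_ids[j], "cell_type": t,
                               "direction": "hyper" if hyper else "hypo"})
    mu = np.clip(mu, 0.02, 0.98)
    a, b = mu * phi, (1 - mu) * phi
    values = np.empty((n_cpgs, K * n_per))
    sample_ids = []
    labels = []
    for k, t in enumerate(types):
        draws = rng.beta(np.tile(a[:, k][:, None], (1, n_per)), np.tile(b[:, k][:, None], (1, n_per)))
        values[:, k * n_per : (k + 1) * n_per] = draws
        sample_ids += [f"{t}_s{i}" for i in range(n_per)]
        labels += [t] * n_per
    values = np.clip(values, 1e-12, 1 - 1e-12)
    m = MethylationMatrix(cpg_ids, np.array(sample_ids, object), values)
    ann = CellTypeAnnotation(np.array(sample_ids, object), np.array(labels, object))
    truth = pd.DataFrame(truth_rows)
    return m, ann, truth
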