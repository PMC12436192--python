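"""Technical-variance and cell-composition adjustment of methylation.

The adjustment proceeds in three steps: beta values are mapped to
M values (log2 of the methylated/unmethylated odds, clipped away from 0
and 1), technical structure is summarised by the leading principal
components of the control-probe matrix, white-blood-cell composition is
estimated by constrained projection onto six reference signatures, and
finally M values are residualized on those nuisance covariates probe by
probe with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data import CELL_TYPES, CellReference

DEFAULT_OFFSET = 1e-3


@dataclass
class MValueMatrix:
    m: pd.DataFrame  # samples x probes
    offset_used: float

    @property
    def sample_ids(self) -> pd.Index:
        return self.m.index


@dataclass
class ControlPCs:
    scores: pd.DataFrame  # samples x k
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class CellComposition:
    fractions: pd.DataFrame  # samples x 6 cell types
    residual_norm: pd.Series


@dataclass
class AdjustedMatrix:
    residuals: pd.DataFrame  # samples x probes
    covariates_used: list


def beta_to_m(betas, offset: float = DEFAULT_OFFSET) -> MValueMatrix:
    """M = log2(beta / (1 - beta)) with betas clipped to [offset, 1-offset]."""
    if not 0 < offset < 0.5:
        raise ValueError("offset must lie in (0, 0.5)")
    frame = betas if isinstance(betas, pd.DataFrame) else pd.DataFrame(betas)
    vals = frame.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(vals, offset, 1 - offset)
    m = np.log2(clipped / (1 - clipped))
    return MValueMatrix(pd.DataFrame(m, index=frame.index, columns=frame.columns),
                        offset_used=offset)


def m_to_beta(m) -> pd.DataFrame:
    vals = np.asarray(m if not isinstance(m, MValueMatrix) else m.m, float)
    beta = np.exp2(vals) / (np.exp2(vals) + 1)
    if isinstance(m, MValueMatrix):
        return pd.DataFrame(beta, index=m.m.index, columns=m.m.columns)
    return beta


def impute_probe_means(betas: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing entries per probe (column)."""
    out = betas.copy()
    means = out.mean(axis=0, skipna=True)
    return out.fillna(means)


def control_pcs(control_betas: pd.DataFrame, k: int = 10) -> ControlPCs:
    """Top-k principal components of the column-centered control matrix.

    Columns are centered but not variance-scaled, preserving the relative
    intensity structure of the control classes. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    n, p = control_betas.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(samples-1, control probes)="
                         f"{min(n - 1, p)}")
    x = control_betas.to_numpy(float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each right vector positive
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u[:, :k] * s[:k]
    var = (s ** 2) / max(n - 1, 1)
    explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    frame = pd.DataFrame(scores, index=control_betas.index,
                         columns=[f"ctrlPC{j + 1}" for j in range(k)])
    return ControlPCs(scores=frame, explained_variance=explained)


def _constrained_fractions(y: np.ndarray, r: np.ndarray,
                           penalty: float = 1e6) -> np.ndarray:
    """Solve min ||y - R w||^2 s.t. w >= 0 and sum(w) <= 1.

    The sum constraint is imposed exactly in the limit via a heavily
    weighted slack equation sum(w) + u = 1 with u >= 0, solved by
    Lawson-Hanson non-negative least squares; with the default penalty the
    constraint violation is far below any fraction tolerance.
    """
    p, c = r.shape
    a = np.zeros((p + 1, c + 1))
    a[:p, :c] = r
    a[p, :c] = penalty
    a[p, c] = penalty
    b = np.concatenate([y, [penalty]])
    w, _ = nnls(a, b)
    return w[:c]


def estimate_cell_fractions(betas_ref: pd.DataFrame,
                            reference: CellReference) -> CellComposition:
    """Reference-based leukocyte deconvolution by constrained projection.

    Per sample, the six cell fractions minimise the squared distance
    between the observed reference-CpG betas and the mixture of reference
    signatures, subject to non-negativity and a total of at most one
    (the unexplained remainder is allowed to be positive).
    """
    r = reference.betas.to_numpy(float)
    if betas_ref.shape[1] != r.shape[0]:
        raise ValueError("sample matrix columns must match reference probes")
    cond = reference.condition_number
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(f"reference matrix is rank-deficient "
                         f"(condition number {cond:.3g})")
    y_all = impute_probe_means(betas_ref).to_numpy(float)
    frac = np.empty((len(betas_ref), r.shape[1]))
    resid = np.empty(len(betas_ref))
    for i, y in enumerate(y_all):
        w = _constrained_fractions(y, r)
        frac[i] = w
        resid[i] = float(np.linalg.norm(y - r @ w))
    fractions = pd.DataFrame(frac, index=betas_ref.index, columns=list(CELL_TYPES))
    return CellComposition(fractions=fractions,
                           residual_norm=pd.Series(resid, index=betas_ref.index,
                                                   name="residual_norm"))


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    x = np.column_stack([np.ones(len(covariates)),
                         covariates.to_numpy(float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name offending columns via near-zero R diagonal of the QR
        rdiag = np.abs(np.diag(np.linalg.qr(x)[1]))
        tol = rdiag.max() * 1e-10
        names = ["intercept"] + list(covariates.columns)
        bad = [names[j] for j in range(x.shape[1]) if rdiag[j] < tol]
        raise ValueError(f"collinear covariates: {bad or names}")
    return x


def residualize_within(m: MValueMatrix,
                       covariates: pd.DataFrame,
                       person: pd.Series,
                       cross_fit: bool = False) -> AdjustedMatrix:
    """Remove technical covariates with coefficients fit on within-person
    variation (person fixed effects).

    For repeated arrays of the same person, covariate coefficients are
    estimated after demeaning both M values and covariates within person,
    so between-person biological variance cannot leak into them. With
    ``cross_fit`` the persons are split into two deterministic folds and
    each fold's arrays are adjusted with coefficients estimated on the
    other fold, removing the residual overfitting correlation between the
    nuisance fit and downstream paired tests. The returned residuals keep
    each person's mean level (person effects cancel exactly in
    within-person differences, which is where this adjustment is meant to
    be consumed).
    """
    if not m.m.index.equals(covariates.index):
        covariates = covariates.loc[m.m.index]
    cat = pd.Categorical(person.loc[m.m.index])
    codes = np.asarray(cat.codes)
    y = impute_probe_means(m.m).to_numpy(float)
    x = covariates.to_numpy(float)
    n_groups = codes.max() + 1
    counts = np.bincount(codes, minlength=n_groups).astype(float)

    def group_demean(v):
        gm = np.zeros((n_groups, v.shape[1]))
        np.add.at(gm, codes, v)
        gm /= counts[:, None]
        return v - gm[codes]

    yd = group_demean(y)
    xd = group_demean(x)
    resid = np.empty_like(y)
    if cross_fit and n_groups >= 4:
        fold_of_person = np.arange(n_groups) % 2  # persons in category order
        folds = fold_of_person[codes]
        for f in (0, 1):
            train, apply_ = folds != f, folds == f
            gamma, *_ = np.linalg.lstsq(xd[train], yd[train], rcond=None)
            resid[apply_] = y[apply_] - x[apply_] @ gamma
    else:
        gamma, *_ = np.linalg.lstsq(xd, yd, rcond=None)
        resid = y - x @ gamma
    return AdjustedMatrix(
        residuals=pd.DataFrame(resid, index=m.m.index, columns=m.m.columns),
        covariates_used=list(covariates.columns) + ["person_fixed_effects"],
    )


def residualize(m: MValueMatrix, covariates: pd.DataFrame) -> AdjustedMatrix:
    """Per-probe OLS residuals of M values on [intercept | covariates].

    Missing M entries (from undetected probes) are mean-imputed per probe
    before projection; residuals are orthogonal to every covariate column
    and have mean ~0 per probe.
    """
    if not m.m.index.equals(covariates.index):
        covariates = covariates.loc[m.m.index]
    x = _design_matrix(covariates)
    q, _ = np.linalg.qr(x)
    y = impute_probe_means(m.m).to_numpy(float)
    resid = y - q @ (q.T @ y)
    return AdjustedMatrix(
        residuals=pd.DataFrame(resid, index=m.m.index, columns=m.m.columns),
        covariates_used=["intercept"] + list(covariates.columns),
    )
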