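"""Per-CpG association designs.

Three primary designs: (1) baseline case-control comparison of adjusted
M values by a non-paired Welch test (unequal group sizes and variances);
(2) prediction of treatment response from baseline methylation by
logistic regression with technical and clinical covariates in one model
(plus a continuous variant on the percentage HAM-A change); (3) a
within-patient longitudinal design testing adjusted methylation change
between timepoints against zero with a one-sample t-test, stratified by
responder status. Auxiliaries: a post-hoc linear model separating the
case-control signal from comorbid depression, a robust (Huber) smoking
EWAS on beta values, and a hypergeometric overlap test between hit lists.

Effect columns deliberately report raw-beta differences (delta beta)
where the test itself runs on residualized M values, matching how array
EWAS tables pair test statistics with interpretable methylation
differences.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import MethylationDataset
from .preprocess import AdjustedMatrix, MValueMatrix

RESULT_COLUMNS = ["probe_id", "statistic", "p_value", "effect", "effect_pct",
                  "se", "df", "n_used", "flag"]


def _finish(rows: list, test: str) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out["test"] = test
    return out.set_index("probe_id")


def welch_case_control(adjusted: AdjustedMatrix,
                       group: pd.Series,
                       betas: MethylationDataset | pd.DataFrame) -> pd.DataFrame:
    """Welch two-sample t-test per probe on adjusted M values.

    ``group`` is boolean (True = patient) over the samples of
    ``adjusted``. The effect column is the raw-beta group difference
    (patient minus control means), with effect_pct = 100 * delta_beta /
    control mean beta.
    """
    r = adjusted.residuals
    g = group.loc[r.index].to_numpy(bool)
    if int(g.sum()) < 2 or int((~g).sum()) < 2:
        raise ValueError("both groups need at least two samples")
    beta_frame = betas.betas if isinstance(betas, MethylationDataset) else betas
    beta_frame = beta_frame.loc[r.index, r.columns]
    # complete-case per probe: residual entries whose underlying beta was
    # missing (undetected probe) do not enter the test
    ok = np.isfinite(beta_frame.to_numpy(float)) & np.isfinite(r.to_numpy(float))
    rv = np.where(ok, r.to_numpy(float), np.nan)

    def _stats(sel):
        x = rv[sel]
        n = np.isfinite(x).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(x, axis=0)
            var = np.nanvar(x, axis=0, ddof=1)
        return n, mean, var

    n1, m1, v1 = _stats(g)
    n2, m2, v2 = _stats(~g)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(np.abs(t), df)

    bvals = beta_frame.to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bpat = np.nanmean(np.where(g[:, None], bvals, np.nan), axis=0)
        bcon = np.nanmean(np.where(~g[:, None], bvals, np.nan), axis=0)
        delta = bpat - bcon
        pct = 100.0 * delta / bcon

    degenerate = ~np.isfinite(se2) | (se2 == 0) | (n1 < 2) | (n2 < 2)
    rows = []
    for j, pid in enumerate(r.columns):
        if degenerate[j]:
            rows.append([pid, np.nan, np.nan, delta[j], pct[j], np.nan,
                         np.nan, int(n1[j] + n2[j]), "degenerate"])
        else:
            rows.append([pid, t[j], p[j], delta[j], pct[j],
                         float(np.sqrt(se2[j])), df[j], int(n1[j] + n2[j]), ""])
    return _finish(rows, "welch_case_control")


def posthoc_depression_adjust(adjusted: AdjustedMatrix,
                              group: pd.Series,
                              depression: pd.Series,
                              probe_subset: list,
                              sig: float = None,
                              suggestive: float = 1e-5) -> pd.DataFrame:
    """Linear model m ~ group + depression for selected probes.

    Re-tests the case-control contrast with comorbid depression as a
    second binary predictor and, when thresholds are given, classifies
    each probe as remaining significant, suggestive, or dropped.
    """
    if not probe_subset:
        raise ValueError("probe_subset must be nonempty")
    r = adjusted.residuals[list(probe_subset)]
    g = group.loc[r.index].to_numpy(float)
    d = depression.loc[r.index].to_numpy(float)
    if d.min() == d.max():
        # constant depression: degenerate covariate drops out and the
        # group test reduces to a pooled-variance two-sample t-test
        x = np.column_stack([np.ones(len(r)), g])
    else:
        x = np.column_stack([np.ones(len(r)), g, d])
        if np.linalg.matrix_rank(x) < 3:
            raise ValueError("group and depression are collinear")
    y = r.to_numpy(float)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = len(r) - x.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se_g = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = coef[1] / se_g
    p = 2 * stats.t.sf(np.abs(t), dof)
    out = pd.DataFrame({
        "probe_id": r.columns,
        "statistic": t,
        "p_value": p,
        "effect": coef[1],
        "effect_pct": np.nan,
        "se": se_g,
        "df": float(dof),
        "n_used": len(r),
        "flag": "",
    }).set_index("probe_id")
    out["test"] = "group_adjusted_for_depression"
    if sig is not None:
        out["status"] = np.where(out["p_value"] <= sig, "significant",
                                 np.where(out["p_value"] < suggestive,
                                          "suggestive", "dropped"))
    return out


def _binary_response(response: pd.Series) -> pd.Series:
    if response.dtype == object or str(response.dtype) == "string":
        usable = response.isin(["responder", "non-responder"])
        return (response[usable] == "responder").astype(float)
    return response.dropna().astype(float)


def predict_response_logistic(m: MValueMatrix,
                              response: pd.Series,
                              covariates: pd.DataFrame,
                              maxiter: int = 100) -> pd.DataFrame:
    """Logistic regression of treatment response on baseline methylation.

    One model per probe: response ~ M + covariates, fit by maximum
    likelihood. A positive coefficient means higher baseline methylation
    predicts higher response odds. Probes with perfect separation or
    non-converged fits are flagged and carry no p-value.
    """
    y = _binary_response(response)
    ids = [s for s in m.m.index if s in y.index]
    if len(ids) <= covariates.shape[1] + 2:
        raise ValueError("fewer usable samples than model parameters")
    yv = y.loc[ids].to_numpy(float)
    if yv.min() == yv.max():
        raise ValueError("response has no contrast")
    c = covariates.loc[ids].to_numpy(float)
    mm = m.m.loc[ids]
    x = np.column_stack([np.ones(len(ids)), np.zeros(len(ids)), c])
    if np.linalg.matrix_rank(x) < x.shape[1] - 1:  # probe column still zeroed
        raise ValueError("covariate matrix is rank deficient")
    rows = []
    mvals = mm.to_numpy(float)
    for j, pid in enumerate(mm.columns):
        x[:, 1] = mvals[:, j]
        ok = np.isfinite(x[:, 1])  # complete-case per probe
        n_ok = int(ok.sum())
        flag, coef, se, z, p = "", np.nan, np.nan, np.nan, np.nan
        if n_ok <= x.shape[1] or yv[ok].min() == yv[ok].max():
            rows.append([pid, z, p, coef, np.nan, se, np.nan, n_ok,
                         "insufficient"])
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(yv[ok], x[ok]).fit(disp=0, maxiter=maxiter)
            if not fit.mle_retvals.get("converged", False):
                flag = "no_convergence"
            elif not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e4:
                flag = "separation"
            else:
                coef, se = float(fit.params[1]), float(fit.bse[1])
                z = coef / se
                # t reference with residual df; the normal reference is
                # anticonservative when covariates are many relative to n
                p = 2 * stats.t.sf(abs(z), n_ok - x.shape[1])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            flag = "separation"
        rows.append([pid, z, p, coef, np.nan, se,
                     float(n_ok - x.shape[1]), n_ok, flag])
    return _finish(rows, "response_logistic")


def response_continuous(m: MValueMatrix,
                        pct_change: pd.Series,
                        covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS of percentage HAM-A change on baseline methylation + covariates.

    Vectorized across probes via projection onto the covariate
    complement (the per-probe slope, SE and t equal the full-model ones
    by the Frisch-Waugh theorem).
    """
    y = pct_change.dropna()
    ids = [s for s in m.m.index if s in y.index]
    n = len(ids)
    n_par = covariates.shape[1] + 2
    if n <= n_par:
        raise ValueError("fewer samples than model parameters")
    c = np.column_stack([np.ones(n), covariates.loc[ids].to_numpy(float)])
    q, _ = np.linalg.qr(c)
    yv = y.loc[ids].to_numpy(float)
    yt = yv - q @ (q.T @ yv)
    mm = m.m.loc[ids].to_numpy(float)
    # probes with missing calls (e.g. undetected chrY in females) are
    # mean-imputed; the bulk of probes are complete and unaffected
    col_means = np.nanmean(np.where(np.isfinite(mm), mm, np.nan), axis=0)
    mm = np.where(np.isfinite(mm), mm, col_means)
    mt = mm - q @ (q.T @ mm)
    ss_m = (mt ** 2).sum(axis=0)
    dof = n - n_par
    rows = []
    if np.allclose(yt, 0):
        for pid in m.m.columns:
            rows.append([pid, np.nan, np.nan, 0.0, np.nan, np.nan,
                         float(dof), n, "zero_variance_outcome"])
        return _finish(rows, "response_continuous")
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (mt * yt[:, None]).sum(axis=0) / ss_m
        rss = (yt ** 2).sum() - slope ** 2 * ss_m
        se = np.sqrt(np.maximum(rss, 0) / dof / ss_m)
        t = slope / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    for j, pid in enumerate(m.m.columns):
        if ss_m[j] == 0 or not np.isfinite(t[j]):
            rows.append([pid, np.nan, np.nan, np.nan, np.nan, np.nan,
                         float(dof), n, "degenerate"])
        else:
            rows.append([pid, t[j], p[j], slope[j], np.nan, se[j],
                         float(dof), n, ""])
    return _finish(rows, "response_continuous")


def longitudinal_delta_test(adjusted_t0: AdjustedMatrix,
                            adjusted_tk: AdjustedMatrix,
                            responder_mask: pd.Series,
                            betas_t0: pd.DataFrame | None = None,
                            betas_tk: pd.DataFrame | None = None,
                            min_n: int = 3) -> dict:
    """One-sample t-test on within-patient adjusted methylation change.

    Differences adjusted_tk - adjusted_t0 are formed per patient present
    at both timepoints and tested against zero separately in responders
    and non-responders. The effect column is the mean raw-beta change
    when beta matrices are supplied. Strata with fewer than ``min_n``
    patients are skipped with a warning.
    """
    shared = [s for s in adjusted_tk.residuals.index
              if s in adjusted_t0.residuals.index and s in responder_mask.index]
    if not shared:
        raise ValueError("no patients shared between the two timepoints")
    cols = adjusted_t0.residuals.columns
    if not cols.equals(adjusted_tk.residuals.columns):
        raise ValueError("probe sets differ between timepoints")
    d = (adjusted_tk.residuals.loc[shared].to_numpy(float)
         - adjusted_t0.residuals.loc[shared, cols].to_numpy(float))
    if betas_t0 is not None and betas_tk is not None:
        db = (betas_tk.loc[shared, cols].to_numpy(float)
              - betas_t0.loc[shared, cols].to_numpy(float))
    else:
        db = np.full_like(d, np.nan)
    mask = responder_mask.loc[shared].to_numpy(bool)
    out = {}
    for name, sel in (("responder", mask), ("non-responder", ~mask)):
        n = int(sel.sum())
        if n < min_n:
            warnings.warn(f"stratum {name!r} has {n} < {min_n} patients; skipped",
                          stacklevel=2)
            continue
        ds = d[sel]
        mean = ds.mean(axis=0)
        sd = ds.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(np.abs(t), n - 1)
        eff = np.nanmean(db[sel], axis=0) if np.isfinite(db).any() \
            else np.full(len(cols), np.nan)
        rows = []
        for j, pid in enumerate(cols):
            if sd[j] == 0 or not np.isfinite(t[j]):
                rows.append([pid, np.nan, np.nan, eff[j], np.nan, np.nan,
                             float(n - 1), n, "degenerate"])
            else:
                rows.append([pid, t[j], p[j], eff[j], np.nan,
                             sd[j] / np.sqrt(n), float(n - 1), n, ""])
        out[name] = _finish(rows, f"longitudinal_delta[{name}]")
    return out


def smoking_ewas_robust(betas: MethylationDataset | pd.DataFrame,
                        smoking: pd.Series,
                        covariates: pd.DataFrame,
                        huber_t: float = 1.345,
                        maxiter: int = 50) -> pd.DataFrame:
    """Robust (Huber M-estimation) regression of beta values on smoking.

    Run within the patient group; covariates carry sex, age, cell
    composition and control-probe PCs. The Huber tuning constant 1.345
    gives 95% efficiency under Gaussian errors.
    """
    frame = betas.betas if isinstance(betas, MethylationDataset) else betas
    sm_known = smoking.dropna()
    ids = [s for s in frame.index if s in sm_known.index]
    sv = sm_known.loc[ids].astype(float).to_numpy()
    if sv.min() == sv.max():
        raise ValueError("smoking status is constant; no contrast to test")
    c = covariates.loc[ids].to_numpy(float)
    x = np.column_stack([np.ones(len(ids)), sv, c])
    y_all = frame.loc[ids]
    y_all = y_all.fillna(y_all.mean(axis=0))
    yv = y_all.to_numpy(float)
    norm = sm.robust.norms.HuberT(t=huber_t)
    # joint location-scale estimation (Huber's proposal 2); the simpler
    # MAD scale understates SEs on skewed bounded outcomes at modest n
    scale_est = sm.robust.scale.HuberScale()
    rows = []
    for j, pid in enumerate(frame.columns):
        flag, z, p, coef, se = "", np.nan, np.nan, np.nan, np.nan
        try:
            fit = sm.RLM(yv[:, j], x, M=norm).fit(maxiter=maxiter,
                                                  scale_est=scale_est)
            coef, se = float(fit.params[1]), float(fit.bse[1])
            if se > 0 and np.isfinite(se):
                # t reference with residual df: the normal reference is
                # mildly anticonservative at modest n with many covariates
                dof = len(ids) - x.shape[1]
                z = coef / se
                p = 2 * stats.t.sf(abs(z), dof)
            else:
                flag = "degenerate"
        except (np.linalg.LinAlgError, ValueError):
            flag = "no_convergence"
        rows.append([pid, z, p, coef, np.nan, se,
                     float(len(ids) - x.shape[1]), len(ids), flag])
    return _finish(rows, "smoking_robust")


def overlap_test(hits_a, hits_b, universe_n: int):
    """Overlap count and upper-tail hypergeometric p between two hit sets."""
    a, b = set(hits_a), set(hits_b)
    if universe_n < len(a) or universe_n < len(b):
        raise ValueError("universe smaller than a hit set")
    count = len(a & b)
    p = float(stats.hypergeom.sf(count - 1, universe_n, len(a), len(b)))
    return count, min(p, 1.0)
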