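"""Per-batch case-control association at each CpG.

Within each batch, adjusted beta values are Van der Waerden (rank-based
inverse normal) transformed per probe and regressed on the case
indicator with the study covariates:

    Y_ij = alpha_j + beta_j X_i + gamma_j' Z_i + e_ij,   e_ij ~ N(0, s_j^2)

Covariates: parity/age-at-first-birth combination, alcohol use, smoking
status, enrollment year (continuous), and recruitment state. Categorical
covariates carry an explicit ``missing`` level so samples are never
dropped for missing covariates. Two-sided p-values come from the t
distribution with residual degrees of freedom.

The batch scan uses a vectorized least-squares path (one shared design
matrix, all probes at once); the single-probe entry point
:func:`fit_cpg_model` fits the identical model through statsmodels OLS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import (
    ALCOHOL_LEVELS,
    PARITY_LEVELS,
    SMOKING_LEVELS,
    STATE_LEVELS,
)

__all__ = [
    "vanderwaerden_transform",
    "build_design",
    "fit_cpg_model",
    "run_batch_association",
    "genomic_inflation",
]

#: Reference level of each categorical covariate (dropped from dummies).
COVARIATE_LEVELS = {
    "parity_age_first_birth": PARITY_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "smoking": SMOKING_LEVELS,
    "state": STATE_LEVELS,
}
ENROLLMENT_CENTER = 2005.0


def vanderwaerden_transform(values) -> np.ndarray:
    """Map values to normal quantiles of rank/(n+1); ties get average ranks.

    NaN entries stay NaN and do not contribute to n. Output order
    matches input order. The transform depends only on the ordering, so
    any strictly monotone transform of the input gives the same output.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all values missing")
    ranks = stats.rankdata(v[ok], method="average")
    out[ok] = stats.norm.ppf(ranks / (n + 1))
    return out


def _vdw_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise Van der Waerden transform; rows with NaN handled singly."""
    out = np.empty_like(mat, dtype=float)
    complete = ~np.isnan(mat).any(axis=1)
    if complete.any():
        n = mat.shape[1]
        ranks = stats.rankdata(mat[complete], method="average", axis=1)
        out[complete] = stats.norm.ppf(ranks / (n + 1))
    for i in np.flatnonzero(~complete):
        out[i] = vanderwaerden_transform(mat[i])
    return out


def build_design(
    sheet: pd.DataFrame, include_case: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix for the association model (intercept first).

    Returns ``(X, dropped)`` where ``dropped`` lists dummy columns
    removed because their level is empty in this batch (encoding stays
    identical across batches up to those empty levels).
    """
    cols = {"intercept": np.ones(len(sheet))}
    if include_case:
        cols["case"] = (sheet["case_status"] == "case").astype(float).to_numpy()
    for cov, levels in COVARIATE_LEVELS.items():
        # first listed level is the reference and gets no dummy
        vals = sheet[cov].astype(object).where(sheet[cov].notna(), "missing")
        for lev in levels[1:]:
            cols[f"{cov}[{lev}]"] = (vals == lev).astype(float).to_numpy()
    year = pd.to_numeric(sheet["enrollment_year"], errors="coerce")
    cols["enrollment_year"] = (year.fillna(year.mean()) - ENROLLMENT_CENTER).to_numpy()
    X = pd.DataFrame(cols, index=sheet.index)
    empty = [c for c in X.columns if c != "intercept" and X[c].abs().sum() == 0]
    return X.drop(columns=empty), empty


def fit_cpg_model(y, x, z: pd.DataFrame | None = None) -> dict:
    """OLS of a transformed probe on the case indicator plus covariates.

    ``y`` are the (already transformed) methylation values, ``x`` the
    0/1 case indicator, ``z`` an optional covariate matrix. Returns the
    case coefficient with SE, t-based two-sided p, and a normal-theory
    95% CI. Degenerate fits (zero residual variance) and rank-deficient
    designs are flagged, not dropped.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    X = pd.DataFrame({"intercept": np.ones_like(x), "case": x})
    if z is not None:
        X = pd.concat([X, z.reset_index(drop=True)], axis=1)
    ok = np.isfinite(y)
    res = sm.OLS(y[ok], X.loc[ok]).fit()
    flag = None
    if np.linalg.matrix_rank(X.loc[ok].to_numpy()) < X.shape[1]:
        flag = "rank_deficient"
    elif res.ssr <= 1e-12 * max(res.centered_tss, 1e-300):
        flag = "degenerate"
    beta, se = res.params["case"], res.bse["case"]
    p = float(res.pvalues["case"])
    return dict(
        beta_hat=float(beta),
        se=float(se),
        p=p,
        ci_low=float(beta - 1.96 * se),
        ci_high=float(beta + 1.96 * se),
        n_used=int(ok.sum()),
        df_resid=float(res.df_resid),
        flag=flag,
    )


def _ols_scan(X: np.ndarray, Y: np.ndarray, coef_idx: int):
    """OLS of every column of Y on shared design X; returns (b, se, p, df)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    q, r = np.linalg.qr(X)
    coefs = np.linalg.solve(r, q.T @ Y)
    resid = Y - X @ coefs
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    rinv = np.linalg.inv(r)
    xtx_inv_kk = (rinv @ rinv.T)[coef_idx, coef_idx]
    se = np.sqrt(sigma2 * xtx_inv_kk)
    b = coefs[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = b / se
    p = 2 * stats.t.sf(np.abs(tstat), df)
    return b, se, p, df


def run_batch_association(
    adjusted: dict[int, "object"],
    sheet: pd.DataFrame,
    probe_set,
    min_samples: int = 20,
) -> pd.DataFrame:
    """Association scan per batch over the analysis probe set.

    ``adjusted`` maps batch number to an adjusted :class:`BetaMatrix`
    (or a bare beta DataFrame). The Van der Waerden transform is
    computed within batch, per probe, on study samples only. Returns one
    row per probe per batch.
    """
    probe_set = pd.Index(sorted(probe_set))
    frames = []
    for batch in sorted(adjusted):
        bm = adjusted[batch]
        beta_df = bm.beta if hasattr(bm, "beta") else bm
        sub = sheet[
            (sheet["batch"] == batch)
            & (sheet["role"] == "study")
            & sheet["sample_id"].isin(beta_df.columns)
        ]
        if len(sub) < min_samples:
            raise ValueError(f"batch {batch}: only {len(sub)} study samples (<{min_samples})")
        probes = probe_set.intersection(beta_df.index)
        mat = beta_df.loc[probes, sub["sample_id"]].to_numpy(dtype=float)
        Y = _vdw_rows(mat).T  # samples x probes
        X, _ = build_design(sub)
        case_idx = list(X.columns).index("case")
        Xv = X.to_numpy()

        nan_cols = np.isnan(Y).any(axis=0)
        b = np.full(len(probes), np.nan)
        se = np.full(len(probes), np.nan)
        p = np.full(len(probes), np.nan)
        if (~nan_cols).any():
            b0, se0, p0, _ = _ols_scan(Xv, Y[:, ~nan_cols], case_idx)
            b[~nan_cols], se[~nan_cols], p[~nan_cols] = b0, se0, p0
        for j in np.flatnonzero(nan_cols):
            ok = np.isfinite(Y[:, j])
            bj, sej, pj, _ = _ols_scan(Xv[ok], Y[ok, j][:, None], case_idx)
            b[j], se[j], p[j] = bj[0], sej[0], pj[0]

        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probes,
                    "batch": batch,
                    "beta_hat": b,
                    "se": se,
                    "p": p,
                    "ci_low": b - 1.96 * se,
                    "ci_high": b + 1.96 * se,
                    "n_used": len(sub),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median observed chi-square over median null."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
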