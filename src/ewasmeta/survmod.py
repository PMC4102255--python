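"""Per-CpG overall-survival models: Cox PH with left truncation.

Cases enter the risk set at enrollment (entry time, years since
diagnosis) and leave at death or censoring (exit time), i.e. start-stop
counting-process input with delayed entry. Models adjust for age at
diagnosis, tumor stage (III/IV vs I/II), ascites (yes/no/missing) and
debulking outcome (optimal/suboptimal/missing); methylation enters on
the same Van der Waerden-transformed scale as the case-control model,
so hazard ratios are per rank-normal SD of methylation. Ties are
handled with the Efron approximation (lifelines' default).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .assoc import _vdw_rows
from .containers import ASCITES_LEVELS, DEBULKING_LEVELS, STAGE_LEVELS

__all__ = [
    "build_surv_design",
    "fit_cox_left_truncated",
    "schoenfeld_ph_check",
    "run_survival_association",
]


def build_surv_design(sub: pd.DataFrame) -> pd.DataFrame:
    """Clinical covariate matrix for the survival model (no intercept)."""
    cols = {"age_dx": pd.to_numeric(sub["age_dx"], errors="coerce").fillna(
        pd.to_numeric(sub["age_dx"], errors="coerce").mean())}
    for cov, levels in (("stage", STAGE_LEVELS), ("ascites", ASCITES_LEVELS),
                        ("debulking", DEBULKING_LEVELS)):
        vals = sub[cov].astype(object).where(sub[cov].notna(), "missing")
        for lev in levels[1:]:
            col = (vals == lev).astype(float)
            if col.sum() > 0:
                cols[f"{cov}[{lev}]"] = col.to_numpy()
    return pd.DataFrame(cols, index=sub.index)


def fit_cox_left_truncated(
    records: pd.DataFrame,
    values=None,
    value_col: str = "meth",
    retry_penalizer: float = 0.01,
) -> dict:
    """Cox PH fit with delayed entry; reports the methylation coefficient.

    ``records`` needs columns ``entry_time``, ``exit_time``, ``event``
    plus covariates; ``values`` (optional) adds the per-subject
    methylation column ``value_col``. With all entry times zero this
    reduces exactly to a standard Cox fit. Returns log-HR, SE, HR,
    two-sided Wald p and CI for ``value_col`` (or, absent a methylation
    column, the full fitted summary).
    """
    df = records.copy()
    if values is not None:
        df[value_col] = np.asarray(values, dtype=float)
    if df["event"].sum() < 1:
        raise ValueError("no events")
    pred_cols = [c for c in df.columns if c not in ("entry_time", "exit_time", "event")]
    for c in pred_cols:
        if df[c].std() == 0:
            raise ValueError(f"zero-variance predictor {c!r}")
    flag = None
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="exit_time",
                event_col="event",
                entry_col="entry_time",
            )
    except Exception as exc:
        # monotone partial likelihood (e.g. a rare dummy level whose only
        # carrier has an early event) halts Newton-Raphson; retry with a
        # small ridge penalty, else flag the probe rather than raise
        if retry_penalizer > 0:
            try:
                cph = CoxPHFitter(penalizer=retry_penalizer)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="exit_time", event_col="event",
                            entry_col="entry_time")
                flag = "ridge_stabilized"
            except Exception as exc2:
                return dict(log_hr=np.nan, se=np.nan, hr=np.nan, p=np.nan,
                            ci_low=np.nan, ci_high=np.nan,
                            flag=f"no_convergence: {exc2}", fitter=None, data=df)
        else:
            return dict(log_hr=np.nan, se=np.nan, hr=np.nan, p=np.nan,
                        ci_low=np.nan, ci_high=np.nan,
                        flag=f"no_convergence: {exc}", fitter=None, data=df)
    if value_col in df.columns:
        log_hr = float(cph.params_[value_col])
        se = float(cph.standard_errors_[value_col])
        p = float(cph.summary.loc[value_col, "p"])
    else:
        log_hr = se = p = np.nan
    return dict(
        log_hr=log_hr,
        se=se,
        hr=float(np.exp(log_hr)),
        p=p,
        ci_low=float(np.exp(log_hr - 1.96 * se)),
        ci_high=float(np.exp(log_hr + 1.96 * se)),
        flag=flag,
        fitter=cph,
        data=df,
    )


def schoenfeld_ph_check(fit: dict) -> pd.DataFrame:
    """Scaled-Schoenfeld proportional-hazards diagnostic per covariate.

    Scaled Schoenfeld residuals are computed over the left-truncation
    risk sets (entry < t <= exit) and correlated with the rank of event
    time; the p-value is the two-sided t test on that correlation.
    Diagnostic only; results are never gated on it. Returns an empty
    table with a warning when there are fewer than 3 events.
    """
    from scipy import stats

    cph, df = fit.get("fitter"), fit.get("data")
    if cph is None or df is None or df["event"].sum() < 3:
        warnings.warn("fewer than 3 events (or no fit): PH check skipped")
        return pd.DataFrame(columns=["covariate", "test_statistic", "p"])
    pred_cols = list(cph.params_.index)
    X = df[pred_cols].to_numpy(dtype=float)
    entry = df["entry_time"].to_numpy(dtype=float)
    exit_ = df["exit_time"].to_numpy(dtype=float)
    event = df["event"].to_numpy() > 0
    beta = cph.params_.to_numpy()
    w = np.exp(X @ beta)

    ev_order = np.argsort(exit_[event], kind="mergesort")
    ev_idx = np.flatnonzero(event)[ev_order]
    d = len(ev_idx)
    resid = np.empty((d, X.shape[1]))
    vbar = np.zeros((X.shape[1], X.shape[1]))
    for k, i in enumerate(ev_idx):
        t = exit_[i]
        at_risk = (entry < t) & (t <= exit_)
        ww = w[at_risk]
        xx = X[at_risk]
        xbar = ww @ xx / ww.sum()
        resid[k] = X[i] - xbar
        xc = xx - xbar
        vbar += (xc.T * ww) @ xc / ww.sum()
    vbar /= d
    scaled = d * resid @ np.linalg.pinv(vbar) + beta  # Grambsch-Therneau scaling
    g = stats.rankdata(exit_[ev_idx], method="average")
    rows = []
    for j, cov in enumerate(pred_cols):
        rho = np.corrcoef(scaled[:, j], g)[0, 1]
        tstat = rho * np.sqrt((d - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * stats.t.sf(abs(tstat), d - 2))
        rows.append(dict(covariate=cov, test_statistic=float(tstat), p=p))
    return pd.DataFrame(rows)


def run_survival_association(
    adjusted: dict[int, "object"],
    sheet: pd.DataFrame,
    probe_set,
    min_events: int = 1,
) -> pd.DataFrame:
    """Per-batch survival scan over the probe set, cases only.

    Methylation is Van der Waerden transformed within batch across the
    cases entering the model. Batches with zero events are skipped with
    a warning (they cannot contribute to the meta-analysis).
    """
    probe_set = pd.Index(sorted(probe_set))
    frames = []
    for batch in sorted(adjusted):
        bm = adjusted[batch]
        beta_df = bm.beta if hasattr(bm, "beta") else bm
        sub = sheet[
            (sheet["batch"] == batch)
            & (sheet["role"] == "study")
            & (sheet["case_status"] == "case")
            & sheet["sample_id"].isin(beta_df.columns)
            & sheet["exit_time"].notna()
        ]
        if sub["event"].sum() < min_events:
            warnings.warn(f"batch {batch}: no events; excluded from survival meta")
            continue
        base = sub[["entry_time", "exit_time", "event"]].reset_index(drop=True)
        Z = build_surv_design(sub).reset_index(drop=True)
        records = pd.concat([base, Z], axis=1)
        probes = probe_set.intersection(beta_df.index)
        mat = beta_df.loc[probes, sub["sample_id"]].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            Yt = _vdw_rows(np.log(mat / (1 - mat)))
        rows = []
        for j, probe in enumerate(probes):
            try:
                fit = fit_cox_left_truncated(records, Yt[j])
            except ValueError as exc:
                fit = dict(log_hr=np.nan, se=np.nan, hr=np.nan, p=np.nan,
                           ci_low=np.nan, ci_high=np.nan, flag=str(exc))
            rows.append(
                dict(probe_id=probe, batch=batch, log_hr=fit["log_hr"], se=fit["se"],
                     hr=fit["hr"], p=fit["p"], ci_low=fit["ci_low"],
                     ci_high=fit["ci_high"], n_used=len(sub),
                     n_events=int(sub["event"].sum()), flag=fit["flag"])
            )
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(
            columns=["probe_id", "batch", "log_hr", "se", "hr", "p",
                     "ci_low", "ci_high", "n_used", "n_events", "flag"]
        )
    return pd.concat(frames, ignore_index=True)
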