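"""Batch-effect adjustment of beta values and PCA diagnostics.

The "adjusted beta" procedure: per probe, fit a one-way fixed-effects
linear model of the logit-transformed beta on a technical factor (plate,
or chip-within-plate), save the unstandardized residuals, add back the
probe's mean logit, and map back to the (0, 1) scale. Residualization on
a one-way factor amounts to subtracting level means, so the adjusted
values are exactly orthogonal to the factor on the logit scale and the
per-probe mean logit is preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import BetaMatrix

__all__ = ["logit", "inv_logit", "adjust_batch_effects", "pca_diagnostics", "anova_r2"]


def logit(beta, eps: float = 1e-3):
    """Logit with boundary clamping to ``[eps, 1-eps]``.

    Raises for values outside [0, 1]; NaN passes through.
    """
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((b < 0) | (b > 1)):
            raise ValueError("beta values outside [0, 1]")
    b = np.clip(b, eps, 1 - eps)
    return np.log(b / (1 - b))


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


def adjust_batch_effects(
    bm: BetaMatrix, factor: pd.Series, eps: float = 1e-3
) -> BetaMatrix:
    """Remove a one-way technical factor from each probe on the logit scale.

    ``factor`` maps sample id to its level (plate or chip-within-plate)
    and must cover every column of ``bm``. Missing betas are excluded
    from the fit and stay missing. Levels with a single sample are
    retained with a warning (their residuals are zero within level).
    """
    factor = factor.reindex(bm.sample_ids)
    if factor.isna().any():
        missing = list(factor.index[factor.isna()])
        raise ValueError(f"factor level missing for samples: {missing[:5]}")
    counts = factor.value_counts()
    if (counts < 2).any():
        warnings.warn(f"factor levels with <2 samples: {list(counts.index[counts < 2])}")
    if len(counts) < 2:
        warnings.warn("single factor level: adjustment is the identity")

    x = logit(bm.beta.to_numpy(), eps=eps)
    x = pd.DataFrame(x, index=bm.probe_ids, columns=bm.sample_ids)
    probe_mean = x.mean(axis=1)
    level_means = x.T.groupby(factor).transform("mean").T
    adjusted = x - level_means
    adjusted = adjusted.add(probe_mean, axis=0)
    out = pd.DataFrame(inv_logit(adjusted.to_numpy()), index=x.index, columns=x.columns)
    out[bm.beta.isna()] = np.nan
    return BetaMatrix(out, bm.detp.copy())


def anova_r2(values: np.ndarray, labels: pd.Series) -> float:
    """One-way ANOVA R-squared of ``values`` on a categorical factor."""
    v = np.asarray(values, dtype=float)
    lab = pd.Series(np.asarray(labels), dtype="object")
    grand = v.mean()
    sst = ((v - grand) ** 2).sum()
    if sst == 0:
        return 0.0
    ssb = sum(
        len(idx) * (v[idx].mean() - grand) ** 2
        for _, idx in pd.Series(range(len(v))).groupby(lab).groups.items()
    )
    return float(ssb / sst)


def pca_diagnostics(
    bm: BetaMatrix,
    sheet: pd.DataFrame,
    factors: tuple = ("plate", "chip", "batch", "case_status"),
    n_pc: int = 10,
    eps: float = 1e-3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PC scores of samples on logit betas plus factor-association table.

    PCA treats samples as observations with probes centered (no
    scaling). Returns ``(scores, assoc)`` where ``assoc`` holds the
    one-way ANOVA R-squared of each PC on each available factor.
    """
    x = logit(bm.beta.to_numpy(), eps=eps)
    keep = ~np.isnan(x).any(axis=1)
    x = x[keep]
    x = x - x.mean(axis=1, keepdims=True)
    n_pc_eff = min(n_pc, x.shape[1] - 1, x.shape[0])
    if n_pc_eff < n_pc:
        warnings.warn(f"requested {n_pc} PCs, rank allows {n_pc_eff}")
    pca = PCA(n_components=n_pc_eff, svd_solver="full")
    scores = pca.fit_transform(x.T)
    scores = pd.DataFrame(
        scores, index=bm.sample_ids, columns=[f"PC{i + 1}" for i in range(n_pc_eff)]
    )
    meta = sheet.set_index("sample_id").reindex(bm.sample_ids)
    rows = []
    for pc in scores.columns:
        row = {"pc": pc, "var_explained": float(pca.explained_variance_ratio_[int(pc[2:]) - 1])}
        for f in factors:
            if f not in meta.columns:
                continue
            lab = meta[f]
            ok = lab.notna().to_numpy()
            if ok.sum() < 3 or lab[ok].nunique() < 2:
                row[f"r2_{f}"] = np.nan
            else:
                row[f"r2_{f}"] = anova_r2(scores[pc].to_numpy()[ok], lab[ok])
        rows.append(row)
    return scores, pd.DataFrame(rows)
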