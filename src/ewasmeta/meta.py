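"""Random-effects meta-analysis across array batches.

Per-batch estimates (rank-scale regression coefficients, or log hazard
ratios) are combined with the DerSimonian-Laird moment estimator:

    w_k   = 1 / se_k^2
    theta_FE = sum(w theta) / sum(w)
    Q     = sum w_k (theta_k - theta_FE)^2
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_k  = 1 / (se_k^2 + tau^2)
    theta_DL = sum(w* theta) / sum(w*),  se = (sum w*)^(-1/2)

with the combined p from the normal approximation (no Knapp-Hartung).
Q doubles as Woolf's homogeneity statistic, referred to chi-square with
k-1 degrees of freedom. Per-batch SEs can be recovered from printed
(estimate, two-sided p) pairs via the normal-quantile identity, which is
how the shipped worked examples are reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "se_from_estimate_p",
    "fixed_effect",
    "dersimonian_laird",
    "woolf_homogeneity",
    "flag_significance",
    "meta_table",
    "MetaResult",
]

SIGNIFICANCE_THRESHOLD = 5e-6


@dataclass
class MetaResult:
    estimate: float
    se: float
    p: float
    tau2: float
    Q: float
    q_p: float
    k: int

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_THRESHOLD


def se_from_estimate_p(estimate: float, p: float) -> float:
    """Recover a standard error from a point estimate and two-sided p.

    Inverts z = |estimate| / se with p = 2 * (1 - Phi(z)).
    """
    if not (0 < p < 1):
        raise ValueError("p must lie strictly between 0 and 1")
    if estimate == 0:
        raise ValueError("estimate must be nonzero")
    return abs(estimate) / stats.norm.ppf(1 - p / 2)


def _validate(theta, se):
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    if theta.size == 0:
        raise ValueError("no studies to combine")
    if theta.shape != se.shape:
        raise ValueError("estimate and SE vectors differ in length")
    if np.any(se <= 0) or not np.all(np.isfinite(se)) or not np.all(np.isfinite(theta)):
        raise ValueError("SEs must be positive and finite")
    return theta, se


def fixed_effect(theta, se) -> tuple[float, float]:
    """Inverse-variance weighted mean and its SE."""
    theta, se = _validate(theta, se)
    w = 1.0 / se**2
    est = float((w * theta).sum() / w.sum())
    return est, float(w.sum() ** -0.5)


def woolf_homogeneity(theta, se) -> tuple[float, float]:
    """Woolf/Cochran homogeneity statistic Q and its chi-square p.

    Q is referred to chi-square with k-1 df. With a single study Q = 0
    and q_p = 1 by convention.
    """
    theta, se = _validate(theta, se)
    k = theta.size
    if k == 1:
        import warnings

        warnings.warn("single study: homogeneity test undefined, q_p = 1")
        return 0.0, 1.0
    fe, _ = fixed_effect(theta, se)
    w = 1.0 / se**2
    Q = float((w * (theta - fe) ** 2).sum())
    return Q, float(stats.chi2.sf(Q, k - 1))


def dersimonian_laird(theta, se) -> MetaResult:
    """DerSimonian-Laird random-effects combination of k estimates."""
    theta, se = _validate(theta, se)
    k = theta.size
    fe, fe_se = fixed_effect(theta, se)
    if k == 1:
        return MetaResult(fe, fe_se, 2 * stats.norm.sf(abs(fe / fe_se)), 0.0, 0.0, 1.0, 1)
    w = 1.0 / se**2
    Q = float((w * (theta - fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    est = float((w_star * theta).sum() / w_star.sum())
    se_comb = float(w_star.sum() ** -0.5)
    p = float(2 * stats.norm.sf(abs(est / se_comb)))
    q_p = float(stats.chi2.sf(Q, k - 1))
    return MetaResult(est, se_comb, p, tau2, Q, q_p, k)


def flag_significance(results: pd.DataFrame, threshold: float = SIGNIFICANCE_THRESHOLD,
                      p_col: str = "p") -> pd.DataFrame:
    """Add a strict ``p < threshold`` significance flag column."""
    out = results.copy()
    out["significant"] = out[p_col] < threshold
    return out


def meta_table(
    batch_results: pd.DataFrame,
    estimate_col: str = "beta_hat",
    scale: str = "linear",
    min_batches: int | None = None,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> pd.DataFrame:
    """Combine per-batch result rows probe by probe.

    ``batch_results`` stacks the per-batch tables (columns ``probe_id``,
    ``batch``, ``estimate_col``, ``se``). ``scale='log'`` is for hazard
    ratios: combination happens on the given (log) column and an ``hr``
    column is added on output. Probes missing from any batch are
    excluded unless ``min_batches`` relaxes this to a smaller count.
    """
    n_batches = batch_results["batch"].nunique()
    need = n_batches if min_batches is None else min_batches
    rows = []
    for probe, g in batch_results.groupby("probe_id", sort=True):
        g = g.dropna(subset=[estimate_col, "se"])
        if g["batch"].nunique() < need or len(g) == 0:
            continue
        r = dersimonian_laird(g[estimate_col].to_numpy(), g["se"].to_numpy())
        row = dict(probe_id=probe, estimate=r.estimate, se=r.se, p=r.p,
                   tau2=r.tau2, Q=r.Q, q_p=r.q_p, k=r.k)
        if scale == "log":
            row["hr"] = float(np.exp(r.estimate))
            row["hr_ci_low"] = float(np.exp(r.estimate - 1.96 * r.se))
            row["hr_ci_high"] = float(np.exp(r.estimate + 1.96 * r.se))
        else:
            row["ci_low"] = r.estimate - 1.96 * r.se
            row["ci_high"] = r.estimate + 1.96 * r.se
        rows.append(row)
    base_cols = ["probe_id", "estimate", "se", "p", "tau2", "Q", "q_p", "k"]
    if scale == "log":
        base_cols += ["hr", "hr_ci_low", "hr_ci_high"]
    else:
        base_cols += ["ci_low", "ci_high"]
    out = pd.DataFrame(rows, columns=base_cols)
    return flag_significance(out, threshold=threshold)
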