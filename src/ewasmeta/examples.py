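"""Published per-batch worked examples for the meta-analysis.

Per-batch disease-status estimates (rank-transformed scale) and hazard
ratios, with their two-sided p-values, as printed in the result tables
of the three-batch blood-methylation ovarian-cancer study this pipeline
models. Batch SEs are not printed; they are recovered from the
(estimate, p) pairs via the normal-quantile identity
(:func:`ewasmeta.meta.se_from_estimate_p`), after which the
DerSimonian-Laird combination reproduces the printed combined values.
"""

from __future__ import annotations

import numpy as np

from .meta import MetaResult, dersimonian_laird, se_from_estimate_p

__all__ = ["RISK_EXAMPLES", "SURVIVAL_EXAMPLES", "combine_risk_example", "combine_survival_example"]

#: Disease-status worked examples: per-batch estimates (batches 1-3) and
#: two-sided p-values; ``published_meta`` is the printed combined estimate.
RISK_EXAMPLES = {
    "cg04834572": dict(
        estimates=(-0.82, -0.55, -0.73),
        p_values=(2.1e-4, 6.0e-6, 1.1e-6),
        published_meta=-0.65,
        published_meta_p=1.6e-14,
        nearest_gene="DUSP13",
    ),
    "cg10414058": dict(
        estimates=(-1.13, -0.71, -1.05),
        p_values=(3.5e-8, 7.1e-10, 9.0e-14),
        published_meta=-0.94,
        published_meta_p=6.3e-12,
        nearest_gene="HDAC3",
    ),
}

#: Overall-survival worked example: per-batch hazard ratios, combined on
#: the log scale.
SURVIVAL_EXAMPLES = {
    "cg10276549": dict(
        hazard_ratios=(0.96, 0.97, 0.94),
        p_values=(0.32, 0.19, 2.9e-4),
        published_meta_hr=0.95,
        published_meta_p=5.8e-5,
        nearest_gene="GABRE",
    ),
}


def combine_risk_example(probe_id: str) -> MetaResult:
    """DL combination of a risk worked example from its printed values."""
    ex = RISK_EXAMPLES[probe_id]
    se = [se_from_estimate_p(b, p) for b, p in zip(ex["estimates"], ex["p_values"])]
    return dersimonian_laird(np.asarray(ex["estimates"]), np.asarray(se))


def combine_survival_example(probe_id: str) -> tuple[float, MetaResult]:
    """DL combination of a survival example on the log-HR scale.

    Returns ``(combined_hr, MetaResult)``; the MetaResult estimate is
    the combined log hazard ratio.
    """
    ex = SURVIVAL_EXAMPLES[probe_id]
    log_hr = np.log(ex["hazard_ratios"])
    se = [se_from_estimate_p(b, p) for b, p in zip(log_hr, ex["p_values"])]
    res = dersimonian_laird(log_hr, np.asarray(se))
    return float(np.exp(res.estimate)), res
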