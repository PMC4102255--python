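"""Probe- and sample-level quality control.

Probe rules, applied in this fixed order for primary-reason reporting:

1. ``y_chromosome`` / ``snp_at_probe`` — annotation-based exclusion
   (X-chromosome probes are retained).
2. ``negative_control_high`` — probe mean beta across negative bisulfite
   controls beyond ``k_sd`` standard deviations above the grand mean of
   probe means.
3. ``low_detection`` — detected (detection p below the cut) in strictly
   less than ``min_rate`` of study samples.

Sample rules, in order: ``low_call_rate``, ``bisulfite_failure``,
``low_mean_beta`` (mean beta below median minus 4 robust MADs).

Replicate concordance reports pairwise Pearson correlations and the
one-way random-effects intraclass correlation ICC(1,1) per replicate
group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import BetaMatrix, QCReport

__all__ = [
    "detection_filter",
    "negative_control_filter",
    "annotation_filter",
    "sample_qc",
    "replicate_concordance",
    "run_probe_qc",
    "run_sample_qc",
]

PROBE_REASON_ORDER = ("y_chromosome", "snp_at_probe", "negative_control_high", "low_detection")
SAMPLE_REASON_ORDER = ("low_call_rate", "bisulfite_failure", "low_mean_beta")


def detection_filter(
    bm: BetaMatrix,
    detp_cut: float = 0.05,
    min_rate: float = 0.70,
    sample_ids=None,
) -> set:
    """Probes detected in strictly less than ``min_rate`` of samples.

    ``sample_ids`` restricts the denominator (typically to study
    samples). The boundary is strict: a probe detected in exactly
    ``min_rate`` of samples passes.
    """
    detp = bm.detp if sample_ids is None else bm.detp[list(sample_ids)]
    if detp.shape[0] == 0 or detp.shape[1] == 0:
        raise ValueError("empty matrix")
    rate = (detp < detp_cut).mean(axis=1)
    return set(rate.index[rate < min_rate])


def negative_control_filter(
    bm: BetaMatrix, negative_sample_ids, k_sd: float = 4.0
) -> set:
    """Probes with high signal in negative bisulfite-conversion controls.

    Each probe's mean beta across the negative controls is compared with
    the grand mean and SD of those probe means; probes beyond
    ``k_sd`` SDs above the grand mean fail.
    """
    neg = [s for s in negative_sample_ids if s in bm.beta.columns]
    if len(neg) < 2:
        raise ValueError("need at least 2 negative-control samples")
    probe_means = bm.beta[neg].mean(axis=1)
    mu, sd = probe_means.mean(), probe_means.std(ddof=1)
    return set(probe_means.index[probe_means > mu + k_sd * sd])


def annotation_filter(ann: pd.DataFrame, probe_ids=None) -> tuple[set, set]:
    """Probes on the Y chromosome or positioned at a SNP.

    Returns ``(failing, unannotated)``; probes absent from the
    annotation are reported separately, never silently dropped.
    X-chromosome probes are retained.
    """
    if probe_ids is None:
        probe_ids = ann.index
    probe_ids = pd.Index(probe_ids)
    unannotated = set(probe_ids.difference(ann.index))
    sub = ann.loc[probe_ids.intersection(ann.index)]
    bad = sub.index[(sub["chromosome"].astype(str) == "Y") | sub["snp_at_probe"].astype(bool)]
    return set(bad), unannotated


def sample_qc(
    bm: BetaMatrix,
    bisulfite_ratio: pd.Series | None = None,
    call_rate_min: float = 0.95,
    bisulfite_min: float = 0.90,
    detp_cut: float = 0.05,
    mad_k: float = 4.0,
    sample_ids=None,
) -> dict:
    """Failing samples with their primary reason.

    A sample fails if its call rate (fraction of probes detected at
    ``detp_cut``) is below ``call_rate_min``, its bisulfite conversion
    ratio is below ``bisulfite_min``, or its mean beta lies below the
    across-sample median minus ``mad_k`` scaled MADs.
    """
    cols = list(bm.beta.columns if sample_ids is None else sample_ids)
    reasons: dict = {}
    call_rate = (bm.detp[cols] < detp_cut).mean(axis=0)
    for s in call_rate.index[call_rate < call_rate_min]:
        reasons.setdefault(s, "low_call_rate")
    if bisulfite_ratio is not None:
        br = bisulfite_ratio.reindex(cols)
        for s in br.index[br < bisulfite_min]:
            reasons.setdefault(s, "bisulfite_failure")
    mean_beta = bm.beta[cols].mean(axis=0)
    med = mean_beta.median()
    mad = (mean_beta - med).abs().median() * 1.4826
    if mad > 0:
        for s in mean_beta.index[mean_beta < med - mad_k * mad]:
            reasons.setdefault(s, "low_mean_beta")
    return reasons


def _icc1(mat: np.ndarray) -> float:
    """One-way random-effects ICC(1,1); rows = targets, cols = raters."""
    n, k = mat.shape
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((mat - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    return float((msb - msw) / denom) if denom > 0 else np.nan


def replicate_concordance(bm: BetaMatrix, replicate_groups: dict) -> pd.DataFrame:
    """Pairwise Pearson correlation and ICC(1,1) per replicate group.

    ``replicate_groups`` maps a group label to the sample ids assayed
    from the same source material. Groups of size 1 are skipped with a
    warning.
    """
    rows = []
    for grp, members in replicate_groups.items():
        members = [m for m in members if m in bm.beta.columns]
        if len(members) < 2:
            warnings.warn(f"replicate group {grp!r} has <2 members; skipped")
            continue
        sub = bm.beta[members].dropna()
        corr = sub.corr().to_numpy()
        iu = np.triu_indices(len(members), k=1)
        rows.append(
            dict(
                group=grp,
                n_members=len(members),
                min_pairwise_r=float(corr[iu].min()),
                mean_pairwise_r=float(corr[iu].mean()),
                icc=_icc1(sub.to_numpy()),
            )
        )
    return pd.DataFrame(rows, columns=["group", "n_members", "min_pairwise_r", "mean_pairwise_r", "icc"])


def run_probe_qc(
    bm: BetaMatrix,
    ann: pd.DataFrame,
    negative_sample_ids,
    study_sample_ids,
    detp_cut: float = 0.05,
    min_rate: float = 0.70,
    k_sd: float = 4.0,
) -> QCReport:
    """Apply all probe rules; primary reason follows the fixed order."""
    ann_fail, unannot = annotation_filter(ann, bm.probe_ids)
    sub_ann = ann.loc[ann.index.intersection(bm.probe_ids)]
    y_fail = set(sub_ann.index[sub_ann["chromosome"].astype(str) == "Y"])
    snp_fail = set(sub_ann.index[sub_ann["snp_at_probe"].astype(bool)])
    neg_fail = negative_control_filter(bm, negative_sample_ids, k_sd)
    det_fail = detection_filter(bm, detp_cut, min_rate, sample_ids=study_sample_ids)

    reasons: dict = {}
    for reason, ids in (
        ("y_chromosome", y_fail),
        ("snp_at_probe", snp_fail),
        ("negative_control_high", neg_fail),
        ("low_detection", det_fail),
    ):
        for p in ids:
            reasons.setdefault(p, reason)
    for p in unannot:
        reasons.setdefault(p, "unannotated")
    report = QCReport(
        excluded_probes=pd.DataFrame(
            sorted(reasons.items()), columns=["probe_id", "reason"]
        )
    )
    return report


def run_sample_qc(
    bm: BetaMatrix,
    sheet: pd.DataFrame,
    call_rate_min: float = 0.95,
    bisulfite_min: float = 0.90,
    detp_cut: float = 0.05,
) -> QCReport:
    """Apply sample rules to study samples; add replicate concordance."""
    in_batch = sheet[sheet["sample_id"].isin(bm.sample_ids)]
    study_ids = in_batch.loc[in_batch["role"] == "study", "sample_id"]
    br = in_batch.set_index("sample_id").get("bisulfite_ratio")
    reasons = sample_qc(
        bm, bisulfite_ratio=br, call_rate_min=call_rate_min,
        bisulfite_min=bisulfite_min, detp_cut=detp_cut, sample_ids=study_ids,
    )
    groups = {
        grp: list(g["sample_id"])
        for grp, g in in_batch[in_batch["replicate_group"].notna()].groupby("replicate_group")
    }
    return QCReport(
        excluded_samples=pd.DataFrame(
            sorted(reasons.items()), columns=["sample_id", "reason"]
        ),
        concordance=replicate_concordance(bm, groups),
    )
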