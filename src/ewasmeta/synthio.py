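"""Synthetic three-batch blood-methylation cohorts with known truth.

The generator emulates the data structure of a three-batch case-control
methylation study run on two overlapping array panels: batches 1 and 2 on
a small panel, batch 3 on a larger panel sharing a probe subset with the
small one. Methylation is generated additively on the logit scale,

    logit(beta_ij) = mu_j + b_j X_i + l_j (c_i - c0) + plate_i + chip_i + e_ij,

with ``X_i`` the case indicator, ``b_j`` a disease effect at designated
risk probes, ``l_j`` a cell-type loading at designated cell-type probes
acting on the sample's first leukocyte-compartment fraction ``c_i``
(drawn from a Dirichlet whose mean differs between cases and controls,
so cell composition confounds case status), and plate/chip technical
offsets. Because the model is logit-additive, the downstream
logit-linear batch adjustment holds exactly under the generator.

Assay control samples (CEPH replicates, positive and negative bisulfite
controls, study duplicates) and injected QC failures (low-detection
probes, negative-control outlier probes, low-call-rate / bisulfite-failure
/ low-mean-beta samples) are generated alongside, with all truth labels
returned for recovery testing.

Overall-survival outcomes for cases are exponential with hazard scaled by
``exp(log-HR x standardized methylation)`` at designated survival probes,
left-truncated by a uniform entry time in the first year after diagnosis
and administratively censored at a fixed horizon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ALCOHOL_LEVELS,
    ASCITES_LEVELS,
    DEBULKING_LEVELS,
    PARITY_LEVELS,
    SMOKING_LEVELS,
    STAGE_LEVELS,
    STATE_LEVELS,
    BetaMatrix,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SizingError",
    "ConsistencyError",
    "simulate_cohort",
    "simulate_beta",
    "simulate_survival",
    "simulate_annotation",
    "write_outputs",
]


class SizingError(ValueError):
    """Inconsistent sample counts versus batch/plate layout."""


class ConsistencyError(ValueError):
    """Sheet, truth and config do not describe the same cohort."""


# Covariate category frequencies for study samples, matching the source
# cohort's marginal distributions. The parity/age-at-first-birth split
# within parity groups is not tabulated anywhere; a 30/70 split of
# age<=20 vs >20 is assumed.
_PARITY_P = (0.14, 0.108, 0.252, 0.135, 0.315, 0.05)
_ALCOHOL_P = (0.21, 0.16, 0.54, 0.09)
_SMOKING_P = (0.87, 0.07, 0.06)
_STATE_P = (0.70, 0.30)
_STAGE_P = (0.22, 0.78)
_ASCITES_P = (0.54, 0.29, 0.17)
_DEBULKING_P = (0.85, 0.14, 0.01)

_CHIPS_PER_PLATE = 8
_SAMPLES_PER_CHIP = 12
_PLATE_CAPACITY = _CHIPS_PER_PLATE * _SAMPLES_PER_CHIP  # 96


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Sample sizes default to the post-QC per-batch counts of the cohort
    the pipeline models (69/87, 146/176, 121/135 cases/controls). Probe
    panel sizes are scaled down from real arrays to keep simulation
    tractable; effects are on the logit scale.
    """

    n_cases_per_batch: tuple = (69, 146, 121)
    n_controls_per_batch: tuple = (87, 176, 135)

    n_probes_panel_small: int = 800
    n_probes_panel_large: int = 1200
    n_overlap: int = 600

    n_true_risk_probes: int = 15
    risk_effect_size: float = 0.5  # logit-scale case-control shift
    n_celltype_probes: int = 60
    celltype_shift: float = 3.0  # logit per unit cell fraction
    cellfrac_case_shift: float = 0.08  # mean shift of 1st compartment in cases
    cellfrac_concentration: float = 60.0

    plate_effect_sd: float = 0.4
    chip_effect_sd: float = 0.2
    noise_sd: float = 0.5
    baseline_logit_sd: float = 1.8

    n_true_survival_probes: int = 8
    survival_loghr: float = 0.3  # per SD of methylation (logit scale)
    baseline_hazard: float = 0.2  # events per year
    censor_horizon: float = 11.4  # years, administrative

    # assay controls per batch
    n_ceph_per_batch: int = 3
    n_positive_per_batch: int = 2
    n_negative_per_batch: int = 4
    n_duplicate_pairs_per_batch: int = 2

    # injected QC failures (truth-labelled)
    detp_fail_rate: float = 0.005
    n_lowdetect_probes: int = 6
    lowdetect_fail_frac: float = 0.5
    n_negctrl_outlier_probes: int = 5
    negctrl_outlier_shift: float = 3.5
    n_lowcallrate_samples: int = 2
    lowcallrate_fail_frac: float = 0.4
    n_bisulfite_fail_samples: int = 1
    n_lowmeanbeta_samples: int = 1
    lowmeanbeta_shift: float = -4.0
    na_rate: float = 0.0

    # annotation stand-ins
    n_y_probes: int = 5
    n_snp_probes: int = 10
    n_crossreactive_probes: int = 40

    max_plates_per_batch: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_cases_per_batch = tuple(int(x) for x in self.n_cases_per_batch)
        self.n_controls_per_batch = tuple(int(x) for x in self.n_controls_per_batch)
        if len(self.n_cases_per_batch) != 3 or len(self.n_controls_per_batch) != 3:
            raise SizingError("exactly three batches are required")
        if min(self.n_cases_per_batch) <= 0 or min(self.n_controls_per_batch) <= 0:
            raise SizingError("per-batch sample counts must be positive")
        if self.n_overlap > min(self.n_probes_panel_small, self.n_probes_panel_large):
            raise SizingError("n_overlap exceeds a panel size")
        n_truth = (
            self.n_true_risk_probes
            + self.n_celltype_probes
            + self.n_true_survival_probes
        )
        if n_truth > self.n_overlap:
            raise SizingError("truth probe sets do not fit in the overlap panel")
        for name in ("risk_effect_size", "plate_effect_sd", "chip_effect_sd", "noise_sd"):
            if getattr(self, name) < 0 and name != "risk_effect_size":
                raise SizingError(f"{name} must be >= 0")
        if self.max_plates_per_batch is not None:
            cap = self.max_plates_per_batch * _PLATE_CAPACITY
            for b in range(3):
                if self._batch_total(b) > cap:
                    raise SizingError(
                        f"batch {b + 1} needs {self._batch_total(b)} wells but "
                        f"max_plates_per_batch={self.max_plates_per_batch} allows {cap}"
                    )

    def _batch_total(self, b: int) -> int:
        return (
            self.n_cases_per_batch[b]
            + self.n_controls_per_batch[b]
            + self.n_ceph_per_batch
            + self.n_positive_per_batch
            + self.n_negative_per_batch
            + 2 * self.n_duplicate_pairs_per_batch
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["n_cases_per_batch"] = list(self.n_cases_per_batch)
        d["n_controls_per_batch"] = list(self.n_controls_per_batch)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort (all labels the generator used)."""

    baseline_logit: pd.Series
    risk_effects: pd.Series  # probe -> logit-scale case effect
    celltype_loadings: pd.Series  # probe -> logit per unit cell fraction
    survival_loghr: pd.Series  # probe -> log-HR per methylation SD
    cell_fractions: pd.DataFrame  # sample x 3 compartments
    plate_offsets: pd.Series
    chip_offsets: pd.Series
    small_panel: pd.Index
    large_panel: pd.Index
    lowdetect_probes: pd.Index = field(default_factory=lambda: pd.Index([]))
    negctrl_outlier_probes: pd.Index = field(default_factory=lambda: pd.Index([]))
    lowcallrate_samples: pd.Index = field(default_factory=lambda: pd.Index([]))
    bisulfite_fail_samples: pd.Index = field(default_factory=lambda: pd.Index([]))
    lowmeanbeta_samples: pd.Index = field(default_factory=lambda: pd.Index([]))
    y_probes: pd.Index = field(default_factory=lambda: pd.Index([]))
    snp_probes: pd.Index = field(default_factory=lambda: pd.Index([]))
    crossreactive_probes: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def overlap_panel(self) -> pd.Index:
        return self.small_panel.intersection(self.large_panel)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _draw_cat(rng, levels, probs, n):
    return rng.choice(levels, size=n, p=np.asarray(probs) / np.sum(probs))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw the sample sheet and the generative truth.

    Returns the sheet (one row per assayed sample, study and control
    roles alike) and a :class:`SimTruth` with every label the beta and
    survival generators will use.
    """
    rng = _rng(config, 1)

    # --- probe universe -------------------------------------------------
    n_small_only = config.n_probes_panel_small - config.n_overlap
    n_large_only = config.n_probes_panel_large - config.n_overlap
    n_probes = config.n_overlap + n_small_only + n_large_only
    probes = pd.Index([f"cg_sim{i:06d}" for i in range(n_probes)], name="probe_id")
    overlap = probes[: config.n_overlap]
    small_panel = overlap.append(probes[config.n_overlap : config.n_overlap + n_small_only])
    large_panel = overlap.append(probes[config.n_overlap + n_small_only :])

    perm = rng.permutation(config.n_overlap)
    k_risk, k_ct, k_surv = (
        config.n_true_risk_probes,
        config.n_celltype_probes,
        config.n_true_survival_probes,
    )
    risk_ids = overlap[perm[:k_risk]]
    ct_ids = overlap[perm[k_risk : k_risk + k_ct]]
    surv_ids = overlap[perm[k_risk + k_ct : k_risk + k_ct + k_surv]]
    rest = probes.difference(risk_ids.union(ct_ids).union(surv_ids))

    baseline = pd.Series(
        rng.normal(0.0, config.baseline_logit_sd, n_probes), index=probes
    )
    risk_effects = pd.Series(config.risk_effect_size, index=risk_ids, dtype=float)
    # loadings vary around the configured shift with random sign
    signs = rng.choice([-1.0, 1.0], size=k_ct)
    loadings = pd.Series(
        signs * config.celltype_shift * rng.normal(1.0, 0.25, k_ct), index=ct_ids
    )
    surv_signs = rng.choice([-1.0, 1.0], size=k_surv)
    survival_loghr = pd.Series(surv_signs * config.survival_loghr, index=surv_ids)

    pick = rng.permutation(len(rest))
    lowdetect = rest[pick[: config.n_lowdetect_probes]]
    negout = rest[
        pick[config.n_lowdetect_probes : config.n_lowdetect_probes + config.n_negctrl_outlier_probes]
    ]
    off = config.n_lowdetect_probes + config.n_negctrl_outlier_probes
    y_probes = rest[pick[off : off + config.n_y_probes]]
    off += config.n_y_probes
    snp_probes = rest[pick[off : off + config.n_snp_probes]]
    # cross-reactive stand-ins drawn from the overlap so the exclusion
    # bookkeeping exercises the analysis set
    xr_pool = overlap.difference(
        risk_ids.union(ct_ids).union(surv_ids).union(lowdetect).union(negout)
    )
    crossreactive = xr_pool[
        rng.permutation(len(xr_pool))[: config.n_crossreactive_probes]
    ]

    # --- samples --------------------------------------------------------
    rows = []
    for b in range(3):
        batch = b + 1
        n_ca, n_co = config.n_cases_per_batch[b], config.n_controls_per_batch[b]
        for i in range(n_ca):
            rows.append(dict(sample_id=f"b{batch}_case{i:04d}", batch=batch, role="study", case_status="case"))
        for i in range(n_co):
            rows.append(dict(sample_id=f"b{batch}_ctrl{i:04d}", batch=batch, role="study", case_status="control"))
        for i in range(config.n_ceph_per_batch):
            rows.append(dict(sample_id=f"b{batch}_ceph{i}", batch=batch, role="cephrep",
                             case_status=None, replicate_group=f"ceph_b{batch}"))
        for i in range(config.n_positive_per_batch):
            rows.append(dict(sample_id=f"b{batch}_pos{i}", batch=batch, role="positive_bsm", case_status=None))
        for i in range(config.n_negative_per_batch):
            rows.append(dict(sample_id=f"b{batch}_neg{i}", batch=batch, role="negative_bsm", case_status=None))
        for i in range(config.n_duplicate_pairs_per_batch):
            for r in range(2):
                rows.append(dict(sample_id=f"b{batch}_dup{i}_{r}", batch=batch, role="duplicate",
                                 case_status=None, replicate_group=f"dup{i}_b{batch}"))
    sheet = pd.DataFrame(rows)
    if "replicate_group" not in sheet:
        sheet["replicate_group"] = None
    sheet["replicate_group"] = sheet["replicate_group"].astype(object)

    # plate / chip layout: shuffle within batch, fill chips of 12, 8 chips per plate
    plates, chips = {}, {}
    for batch, idx in sheet.groupby("batch").groups.items():
        order = rng.permutation(np.asarray(idx))
        for pos, row_i in enumerate(order):
            p, c = divmod(pos, _PLATE_CAPACITY)[0], (pos // _SAMPLES_PER_CHIP) % _CHIPS_PER_PLATE
            plates[row_i] = f"b{batch}_plate{divmod(pos, _PLATE_CAPACITY)[0] + 1}"
            chips[row_i] = f"{plates[row_i]}_chip{c + 1}"
    sheet["plate"] = pd.Series(plates)
    sheet["chip"] = pd.Series(chips)

    # --- covariates (study samples only) --------------------------------
    study = sheet["role"] == "study"
    n_study = int(study.sum())
    is_case = (sheet["case_status"] == "case") & study
    n_case = int(is_case.sum())

    for col in ("parity_age_first_birth", "alcohol", "smoking", "state",
                "stage", "ascites", "debulking"):
        sheet[col] = pd.Series([None] * len(sheet), dtype=object)
    sheet.loc[study, "parity_age_first_birth"] = _draw_cat(rng, PARITY_LEVELS, _PARITY_P, n_study)
    sheet.loc[study, "alcohol"] = _draw_cat(rng, ALCOHOL_LEVELS, _ALCOHOL_P, n_study)
    sheet.loc[study, "smoking"] = _draw_cat(rng, SMOKING_LEVELS, _SMOKING_P, n_study)
    sheet.loc[study, "state"] = _draw_cat(rng, STATE_LEVELS, _STATE_P, n_study)
    sheet["enrollment_year"] = np.nan
    sheet.loc[study, "enrollment_year"] = rng.integers(2000, 2010, n_study).astype(float)
    sheet["age_dx"] = np.nan
    sheet.loc[is_case, "age_dx"] = np.clip(rng.normal(62.3, 12.1, n_case), 28, 91)
    ctrl = study & ~is_case
    sheet.loc[ctrl, "age_dx"] = np.clip(rng.normal(62.2, 12.2, int(ctrl.sum())), 27, 89)
    sheet.loc[is_case, "stage"] = _draw_cat(rng, STAGE_LEVELS, _STAGE_P, n_case)
    sheet.loc[is_case, "ascites"] = _draw_cat(rng, ASCITES_LEVELS, _ASCITES_P, n_case)
    sheet.loc[is_case, "debulking"] = _draw_cat(rng, DEBULKING_LEVELS, _DEBULKING_P, n_case)
    for col in ("entry_time", "exit_time", "event"):
        sheet[col] = np.nan

    # bisulfite conversion ratio, with injected failures among study samples
    sheet["bisulfite_ratio"] = np.clip(rng.normal(0.995, 0.003, len(sheet)), 0, 1)
    study_ids = sheet.loc[study, "sample_id"].to_numpy()
    qpick = rng.permutation(len(study_ids))
    lowcall = pd.Index(study_ids[qpick[: config.n_lowcallrate_samples]])
    bsfail = pd.Index(
        study_ids[qpick[config.n_lowcallrate_samples : config.n_lowcallrate_samples + config.n_bisulfite_fail_samples]]
    )
    off = config.n_lowcallrate_samples + config.n_bisulfite_fail_samples
    lowmean = pd.Index(study_ids[qpick[off : off + config.n_lowmeanbeta_samples]])
    sheet.loc[sheet["sample_id"].isin(bsfail), "bisulfite_ratio"] = rng.uniform(0.60, 0.75, len(bsfail))

    # cell fractions: Dirichlet with case/control mean shift (confounding)
    mean_ctrl = np.array([0.60, 0.30, 0.10])
    s = config.cellfrac_case_shift
    mean_case = np.array([0.60 - s, 0.30 + s, 0.10])
    fracs = np.empty((len(sheet), 3))
    conc = config.cellfrac_concentration
    for i, (role, status) in enumerate(zip(sheet["role"], sheet["case_status"])):
        m = mean_case if (role == "study" and status == "case") else mean_ctrl
        fracs[i] = rng.dirichlet(m * conc)
    cell_fractions = pd.DataFrame(
        fracs, index=sheet["sample_id"], columns=["frac_gran", "frac_lymph", "frac_mono"]
    )

    plate_ids = pd.Index(sorted(sheet["plate"].unique()))
    chip_ids = pd.Index(sorted(sheet["chip"].unique()))
    plate_offsets = pd.Series(rng.normal(0, config.plate_effect_sd, len(plate_ids)), index=plate_ids)
    chip_offsets = pd.Series(rng.normal(0, config.chip_effect_sd, len(chip_ids)), index=chip_ids)

    truth = SimTruth(
        baseline_logit=baseline,
        risk_effects=risk_effects,
        celltype_loadings=loadings,
        survival_loghr=survival_loghr,
        cell_fractions=cell_fractions,
        plate_offsets=plate_offsets,
        chip_offsets=chip_offsets,
        small_panel=small_panel,
        large_panel=large_panel,
        lowdetect_probes=lowdetect,
        negctrl_outlier_probes=negout,
        lowcallrate_samples=lowcall,
        bisulfite_fail_samples=bsfail,
        lowmeanbeta_samples=lowmean,
        y_probes=y_probes,
        snp_probes=snp_probes,
        crossreactive_probes=crossreactive,
    )
    return sheet, truth


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_beta(
    sheet: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> dict[int, BetaMatrix]:
    """Generate per-batch beta and detection-p matrices.

    Batches 1-2 are assayed on the small panel, batch 3 on the large
    panel. Returns ``{batch: BetaMatrix}``.
    """
    if not set(sheet["sample_id"]) <= set(truth.cell_fractions.index):
        raise ConsistencyError("sheet contains samples unknown to truth")
    rng = _rng(config, 2)
    out: dict[int, BetaMatrix] = {}
    ct_centered = truth.cell_fractions["frac_gran"] - 0.60

    for batch in (1, 2, 3):
        panel = truth.small_panel if batch in (1, 2) else truth.large_panel
        sub = sheet[sheet["batch"] == batch]
        n_p, n_s = len(panel), len(sub)
        mu = truth.baseline_logit.reindex(panel).to_numpy()[:, None]
        logit = np.tile(mu, (1, n_s)) + rng.normal(0, config.noise_sd, (n_p, n_s))

        probe_pos = pd.Series(np.arange(n_p), index=panel)
        is_study = (sub["role"] == "study").to_numpy()
        is_case = (sub["case_status"] == "case").to_numpy() & is_study
        # disease effects
        r_idx = probe_pos.reindex(truth.risk_effects.index).dropna().astype(int)
        logit[np.ix_(r_idx.to_numpy(), np.flatnonzero(is_case))] += (
            truth.risk_effects.loc[r_idx.index].to_numpy()[:, None]
        )
        # cell-type loadings act on every non-assay-control sample
        c_idx = probe_pos.reindex(truth.celltype_loadings.index).dropna().astype(int)
        frac = ct_centered.loc[sub["sample_id"]].to_numpy()
        logit[np.ix_(c_idx.to_numpy(), np.flatnonzero(is_study))] += np.outer(
            truth.celltype_loadings.loc[c_idx.index].to_numpy(), frac[is_study]
        )
        # technical offsets (all samples)
        logit += truth.plate_offsets.reindex(sub["plate"]).to_numpy()[None, :]
        logit += truth.chip_offsets.reindex(sub["chip"]).to_numpy()[None, :]

        # assay controls overwrite the biological signal
        neg = (sub["role"] == "negative_bsm").to_numpy()
        pos = (sub["role"] == "positive_bsm").to_numpy()
        if neg.any():
            base = rng.normal(-4.0, 0.3, (n_p, int(neg.sum())))
            o_idx = probe_pos.reindex(truth.negctrl_outlier_probes).dropna().astype(int)
            base[o_idx.to_numpy(), :] += config.negctrl_outlier_shift
            logit[:, neg] = base
        if pos.any():
            logit[:, pos] = rng.normal(3.0, 0.3, (n_p, int(pos.sum())))
        # replicate groups share an underlying profile; small assay noise on top
        for grp, gsub in sub[sub["replicate_group"].notna()].groupby("replicate_group"):
            cols = np.flatnonzero(sub["sample_id"].isin(gsub["sample_id"]).to_numpy())
            shared = truth.baseline_logit.reindex(panel).to_numpy() + rng.normal(0, 0.6, n_p)
            logit[:, cols] = shared[:, None] + rng.normal(0, 0.15, (n_p, len(cols)))

        # injected low-mean-beta samples
        lm = sub["sample_id"].isin(truth.lowmeanbeta_samples).to_numpy()
        logit[:, lm] += config.lowmeanbeta_shift

        beta = _expit(logit)
        np.clip(beta, 1e-12, 1 - 1e-12, out=beta)

        # detection p-values: uniform below the cut when detected
        fail_p = np.full((n_p, n_s), config.detp_fail_rate)
        ld_idx = probe_pos.reindex(truth.lowdetect_probes).dropna().astype(int)
        fail_p[ld_idx.to_numpy(), :] = config.lowdetect_fail_frac
        lc = sub["sample_id"].isin(truth.lowcallrate_samples).to_numpy()
        fail_p[:, lc] = np.maximum(fail_p[:, lc], config.lowcallrate_fail_frac)
        failed = rng.random((n_p, n_s)) < fail_p
        detp = np.where(failed, rng.uniform(0.2, 1.0, (n_p, n_s)), rng.uniform(0.0, 0.049, (n_p, n_s)))

        if config.na_rate > 0:
            beta[rng.random((n_p, n_s)) < config.na_rate] = np.nan

        cols = sub["sample_id"].to_numpy()
        out[batch] = BetaMatrix(
            pd.DataFrame(beta, index=panel, columns=cols),
            pd.DataFrame(detp, index=panel, columns=cols),
        )
    return out


def simulate_survival(
    sheet: pd.DataFrame,
    truth: SimTruth,
    beta: dict[int, BetaMatrix],
    config: SimConfig,
) -> pd.DataFrame:
    """Fill entry/exit/event survival fields for cases (left-truncated).

    The per-subject hazard is ``baseline_hazard * exp(sum_j loghr_j z_j)``
    with ``z_j`` the within-batch standardized logit methylation at the
    truth survival probes. Entry is uniform on [0, 1) year after
    diagnosis; event times landing before entry are redrawn (ascertained
    subjects must survive to enrollment). Censoring emulates a fixed
    analysis date with staggered enrollment: each subject's censoring
    time is uniform on (entry, ``censor_horizon``], so maximum follow-up
    is the horizon and, at the default hazard, roughly 55-60% of cases
    die in follow-up.
    """
    rng = _rng(config, 3)
    sheet = sheet.copy()
    for batch in (1, 2, 3):
        bm = beta[batch]
        sub = sheet[(sheet["batch"] == batch) & (sheet["role"] == "study") & (sheet["case_status"] == "case")]
        if sub.empty:
            continue
        ids = sub["sample_id"].to_numpy()
        loghr = np.zeros(len(ids))
        surv_ids = truth.survival_loghr.index.intersection(bm.probe_ids)
        if len(surv_ids):
            vals = np.log(bm.beta.loc[surv_ids, ids] / (1 - bm.beta.loc[surv_ids, ids]))
            z = (vals.sub(vals.mean(axis=1), axis=0)).div(vals.std(axis=1, ddof=1), axis=0)
            loghr = truth.survival_loghr.loc[surv_ids].to_numpy() @ z.to_numpy()
        hazard = config.baseline_hazard * np.exp(loghr)
        entry = rng.uniform(0.0, 1.0, len(ids))
        t = rng.exponential(1.0 / hazard)
        for _ in range(1000):
            bad = t <= entry
            if not bad.any():
                break
            t[bad] = rng.exponential(1.0 / hazard[bad])
        censor = rng.uniform(entry, config.censor_horizon)
        event = (t <= censor).astype(float)
        exit_t = np.minimum(t, censor)
        sheet.loc[sub.index, "entry_time"] = entry
        sheet.loc[sub.index, "exit_time"] = exit_t
        sheet.loc[sub.index, "event"] = event
    return sheet


def simulate_annotation(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Synthetic probe annotation table (stand-in for a manifest).

    Chromosome/position/nearest-gene assignments are arbitrary but
    deterministic; the Y-chromosome, SNP, cross-reactive and cell-type
    flags mirror the generator truth so QC and probe-set assembly can be
    validated against it.
    """
    rng = _rng(config, 4)
    probes = truth.baseline_logit.index
    n = len(probes)
    chroms = rng.choice([str(c) for c in range(1, 23)] + ["X"], size=n)
    chroms[probes.isin(truth.y_probes)] = "Y"
    pos = rng.integers(10_000, 250_000_000, n)
    gstart = pos - rng.integers(500, 20_000, n)
    gend = gstart + rng.integers(2_000, 50_000, n)
    ann = pd.DataFrame(
        {
            "probe_id": probes,
            "chromosome": chroms,
            "position": pos,
            "nearest_gene": [f"GENE{i:05d}" for i in range(n)],
            "gene_start": gstart,
            "gene_end": gend,
            "island_relation": rng.choice(
                ["island", "shore", "shelf", "open_sea"], size=n, p=[0.3, 0.25, 0.1, 0.35]
            ),
            "on_small_panel": probes.isin(truth.small_panel),
            "on_large_panel": probes.isin(truth.large_panel),
            "snp_at_probe": probes.isin(truth.snp_probes),
            "cross_reactive": probes.isin(truth.crossreactive_probes),
            "celltype_associated": probes.isin(truth.celltype_loadings.index),
        }
    ).set_index("probe_id")
    return ann


def write_outputs(
    out_dir,
    config: SimConfig,
    sheet: pd.DataFrame,
    truth: SimTruth,
    beta: dict[int, BetaMatrix],
    ann: pd.DataFrame | None = None,
) -> None:
    """Write the cohort to plain-text files under ``out_dir``.

    Per-batch beta/detp TSV (probe rows), sample sheet CSV, truth tables
    TSV, exclusion lists (one probe id per line), config YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    sheet.to_csv(out / "sample_sheet.csv", index=False)
    for batch, bm in beta.items():
        bm.beta.to_csv(out / f"beta_batch{batch}.tsv", sep="\t")
        bm.detp.to_csv(out / f"detp_batch{batch}.tsv", sep="\t")
    pd.DataFrame(
        {
            "probe_id": truth.risk_effects.index,
            "kind": "risk",
            "value": truth.risk_effects.to_numpy(),
        }
    ).to_csv(out / "truth_probes.tsv", sep="\t", index=False, mode="w")
    with open(out / "truth_probes.tsv", "a") as fh:
        pd.DataFrame(
            {"probe_id": truth.celltype_loadings.index, "kind": "celltype",
             "value": truth.celltype_loadings.to_numpy()}
        ).to_csv(fh, sep="\t", index=False, header=False)
        pd.DataFrame(
            {"probe_id": truth.survival_loghr.index, "kind": "survival",
             "value": truth.survival_loghr.to_numpy()}
        ).to_csv(fh, sep="\t", index=False, header=False)
    truth.cell_fractions.to_csv(out / "cell_fractions.tsv", sep="\t")
    if ann is not None:
        ann.to_csv(out / "probe_annotation.tsv", sep="\t")
        ann.index[ann["celltype_associated"]].to_series().to_csv(
            out / "exclude_celltype.txt", index=False, header=False
        )
        ann.index[ann["cross_reactive"]].to_series().to_csv(
            out / "exclude_crossreactive.txt", index=False, header=False
        )
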