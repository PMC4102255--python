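"""Synthetic cohort generator: structure, determinism, effect calibration."""

import numpy as np
import pandas as pd
import pytest

from ewasmeta.synthio import (
    SimConfig,
    SizingError,
    simulate_beta,
    simulate_cohort,
    simulate_survival,
    write_outputs,
    simulate_annotation,
)


def small_cfg(**kw):
    base = dict(
        n_cases_per_batch=(12, 14, 13),
        n_controls_per_batch=(13, 15, 14),
        n_probes_panel_small=60,
        n_probes_panel_large=80,
        n_overlap=50,
        n_true_risk_probes=4,
        n_celltype_probes=6,
        n_true_survival_probes=3,
        n_crossreactive_probes=5,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateCohort:
    def test_study_design_batch_counts(self):
        """The default configuration reproduces the three-batch study arms."""
        cfg = SimConfig(n_probes_panel_small=30, n_probes_panel_large=30,
                        n_overlap=25, n_true_risk_probes=2, n_celltype_probes=3,
                        n_true_survival_probes=2, n_crossreactive_probes=2)
        assert cfg.n_cases_per_batch == (69, 146, 121)
        sheet, _ = simulate_cohort(cfg)
        study = sheet[sheet["role"] == "study"]
        assert (study["case_status"] == "case").sum() == 336
        assert (study["case_status"] == "control").sum() == 398
        per_batch = study.groupby(["batch", "case_status"]).size()
        assert per_batch[(1, "case")] == 69 and per_batch[(1, "control")] == 87
        assert per_batch[(2, "case")] == 146 and per_batch[(2, "control")] == 176
        assert per_batch[(3, "case")] == 121 and per_batch[(3, "control")] == 135

    def test_seed_determinism(self):
        cfg = small_cfg()
        s1, t1 = simulate_cohort(cfg)
        s2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_series_equal(t1.baseline_logit, t2.baseline_logit)

    def test_batch_length_mismatch_raises(self):
        with pytest.raises(SizingError):
            small_cfg(n_cases_per_batch=(100,))

    def test_plate_capacity(self):
        sheet, _ = simulate_cohort(small_cfg())
        assert sheet.groupby("plate").size().max() <= 96
        assert sheet.groupby("chip").size().max() <= 12
        with pytest.raises(SizingError):
            small_cfg(max_plates_per_batch=0)

    def test_nonstudy_roles_have_no_case_status(self):
        sheet, _ = simulate_cohort(small_cfg())
        assert sheet.loc[sheet["role"] != "study", "case_status"].isna().all()

    def test_truth_probe_sets_disjoint(self):
        _, truth = simulate_cohort(small_cfg())
        sets = [set(truth.risk_effects.index), set(truth.celltype_loadings.index),
                set(truth.survival_loghr.index)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])


class TestSimulateBeta:
    def test_degenerate_generator_returns_baseline(self):
        cfg = small_cfg(risk_effect_size=0.0, celltype_shift=0.0, noise_sd=0.0,
                        plate_effect_sd=0.0, chip_effect_sd=0.0,
                        n_lowmeanbeta_samples=0)
        sheet, truth = simulate_cohort(cfg)
        beta = simulate_beta(sheet, truth, cfg)
        study = sheet[(sheet["batch"] == 1) & (sheet["role"] == "study")]["sample_id"]
        expected = 1 / (1 + np.exp(-truth.baseline_logit.reindex(truth.small_panel)))
        got = beta[1].beta[study]
        assert np.allclose(got.to_numpy(), expected.to_numpy()[:, None], atol=1e-12)

    def test_beta_strictly_inside_unit_interval(self, tiny_cohort):
        _, _, beta = tiny_cohort
        for bm in beta.values():
            v = bm.beta.to_numpy()
            assert np.all((v > 0) & (v < 1))

    def test_case_control_logit_difference_matches_configured_effect(self):
        """Monte-Carlo mean logit difference at risk probes ~ configured 0.5."""
        cfg = small_cfg(n_cases_per_batch=(600, 10, 10), n_controls_per_batch=(600, 10, 10),
                        celltype_shift=0.0, plate_effect_sd=0.0, chip_effect_sd=0.0,
                        risk_effect_size=0.5, seed=5)
        sheet, truth = simulate_cohort(cfg)
        beta = simulate_beta(sheet, truth, cfg)
        sub = sheet[(sheet["batch"] == 1) & (sheet["role"] == "study")]
        logit = np.log(beta[1].beta / (1 - beta[1].beta))
        cases = sub.loc[sub["case_status"] == "case", "sample_id"]
        ctrls = sub.loc[sub["case_status"] == "control", "sample_id"]
        diff = logit[cases].mean(axis=1) - logit[ctrls].mean(axis=1)
        on = diff.reindex(truth.risk_effects.index).mean()
        off = diff.drop(truth.risk_effects.index).mean()
        assert on == pytest.approx(0.5, abs=0.1)
        assert off == pytest.approx(0.0, abs=0.05)

    def test_negative_control_outliers_separate_from_grand_mean(self, tiny_cohort):
        sheet, truth, beta = tiny_cohort
        neg = sheet[(sheet["batch"] == 1) & (sheet["role"] == "negative_bsm")]["sample_id"]
        means = beta[1].beta[list(neg)].mean(axis=1)
        mu, sd = means.mean(), means.std(ddof=1)
        flagged = means.index[means > mu + 4 * sd]
        injected = truth.negctrl_outlier_probes.intersection(beta[1].probe_ids)
        assert set(injected) <= set(flagged)

    def test_celltype_confounding_without_risk_effect(self):
        """Marginal case-control difference at cell-type probes is nonzero
        even with a null disease effect, because cell fractions differ."""
        cfg = small_cfg(n_cases_per_batch=(700, 10, 10), n_controls_per_batch=(700, 10, 10),
                        risk_effect_size=0.0, celltype_shift=4.0, cellfrac_case_shift=0.10,
                        plate_effect_sd=0.0, chip_effect_sd=0.0, seed=11)
        sheet, truth = simulate_cohort(cfg)
        beta = simulate_beta(sheet, truth, cfg)
        sub = sheet[(sheet["batch"] == 1) & (sheet["role"] == "study")]
        logit = np.log(beta[1].beta / (1 - beta[1].beta))
        cases = sub.loc[sub["case_status"] == "case", "sample_id"]
        ctrls = sub.loc[sub["case_status"] == "control", "sample_id"]
        diff = (logit[cases].mean(axis=1) - logit[ctrls].mean(axis=1)).abs()
        ct = diff.reindex(truth.celltype_loadings.index).mean()
        null = diff.drop(truth.celltype_loadings.index.union(truth.risk_effects.index)).mean()
        assert ct > 5 * null

    def test_sheet_truth_mismatch_raises(self, tiny_cohort):
        sheet, truth, _ = tiny_cohort
        bad = sheet.copy()
        bad.loc[bad.index[0], "sample_id"] = "alien"
        with pytest.raises(ValueError):
            simulate_beta(bad, truth, small_cfg())


class TestSimulateSurvival:
    def test_exponential_mean_before_censoring(self):
        cfg = small_cfg(n_cases_per_batch=(800, 10, 10), n_controls_per_batch=(10, 10, 10),
                        survival_loghr=0.0, baseline_hazard=0.2, censor_horizon=1e9, seed=2)
        sheet, truth = simulate_cohort(cfg)
        beta = simulate_beta(sheet, truth, cfg)
        out = simulate_survival(sheet, truth, beta, cfg)
        t = out.loc[out["event"].notna() & (out["batch"] == 1), "exit_time"]
        # exit = entry-truncated exponential: E[T] = E[entry] + 1/hazard = 0.5 + 5
        assert t.mean() == pytest.approx(5.5, rel=0.1)

    def test_administrative_censoring_horizon(self, tiny_config, tiny_cohort):
        sheet, truth, beta = tiny_cohort
        out = simulate_survival(sheet, truth, beta, tiny_config)
        surv = out[out["exit_time"].notna()]
        assert surv["exit_time"].max() <= 11.4 + 1e-12
        assert (surv["entry_time"] < surv["exit_time"]).all()
        assert set(surv["event"].unique()) <= {0.0, 1.0}

    def test_null_loghr_event_rate_independent_of_methylation(self):
        cfg = small_cfg(n_cases_per_batch=(600, 10, 10), n_controls_per_batch=(10, 10, 10),
                        survival_loghr=0.0, seed=9)
        sheet, truth = simulate_cohort(cfg)
        beta = simulate_beta(sheet, truth, cfg)
        out = simulate_survival(sheet, truth, beta, cfg)
        probe = truth.survival_loghr.index[0]
        cases = out[(out["batch"] == 1) & out["event"].notna()]
        vals = beta[1].beta.loc[probe, cases["sample_id"]]
        tert = pd.qcut(vals, 3, labels=False)
        rates = cases.groupby(tert.to_numpy())["event"].mean()
        assert rates.max() - rates.min() < 0.12


class TestWriteOutputs:
    def test_round_trip_files(self, tmp_path, tiny_config, tiny_cohort):
        sheet, truth, beta = tiny_cohort
        ann = simulate_annotation(truth, tiny_config)
        write_outputs(tmp_path, tiny_config, sheet, truth, beta, ann)
        assert (tmp_path / "beta_batch3.tsv").exists()
        back = pd.read_csv(tmp_path / "beta_batch1.tsv", sep="\t", index_col=0)
        pd.testing.assert_frame_equal(back, beta[1].beta, check_exact=False)
        cfg2 = SimConfig.from_yaml(tmp_path / "config.yaml")
        assert cfg2 == tiny_config
        excl = (tmp_path / "exclude_celltype.txt").read_text().split()
        assert set(excl) == set(truth.celltype_loadings.index)
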