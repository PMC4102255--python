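"""Probe/sample QC rules and replicate concordance."""

import numpy as np
import pandas as pd
import pytest

from ewasmeta.containers import BetaMatrix
from ewasmeta.qc import (
    _icc1,
    annotation_filter,
    detection_filter,
    negative_control_filter,
    replicate_concordance,
    run_probe_qc,
    run_sample_qc,
    sample_qc,
)
from ewasmeta.synthio import simulate_annotation


def make_bm(beta, detp=None):
    beta = pd.DataFrame(beta)
    beta.index = [f"p{i}" for i in range(beta.shape[0])]
    beta.columns = [f"s{j}" for j in range(beta.shape[1])]
    if detp is None:
        detp = pd.DataFrame(0.001, index=beta.index, columns=beta.columns)
    else:
        detp = pd.DataFrame(np.asarray(detp), index=beta.index, columns=beta.columns)
    return BetaMatrix(beta, detp)


class TestDetectionFilter:
    @pytest.mark.parametrize("n_detected,fails", [(65, True), (70, False), (100, False)])
    def test_boundary_is_strict_less_than(self, n_detected, fails):
        detp = np.full((1, 100), 0.5)
        detp[0, :n_detected] = 0.01
        bm = make_bm(np.full((1, 100), 0.5), detp)
        assert (("p0" in detection_filter(bm)) == fails)

    def test_empty_matrix_raises(self):
        bm = make_bm(np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            detection_filter(bm, sample_ids=[])


class TestNegativeControlFilter:
    def test_identical_probes_none_fail(self):
        bm = make_bm(np.full((5, 3), 0.02))
        assert negative_control_filter(bm, bm.sample_ids) == set()

    def test_outlier_probe_fails(self):
        vals = np.full((50, 4), 0.02) + np.random.default_rng(0).normal(0, 0.002, (50, 4))
        vals[7] = 0.5
        bm = make_bm(np.clip(vals, 0, 1))
        assert negative_control_filter(bm, bm.sample_ids) == {"p7"}

    def test_requires_two_negatives(self):
        bm = make_bm(np.full((3, 1), 0.02))
        with pytest.raises(ValueError):
            negative_control_filter(bm, ["s0"])

    def test_round_trip_with_generator_truth(self, tiny_cohort):
        sheet, truth, beta = tiny_cohort
        neg = sheet[(sheet["batch"] == 3) & (sheet["role"] == "negative_bsm")]["sample_id"]
        flagged = negative_control_filter(beta[3], neg)
        injected = set(truth.negctrl_outlier_probes.intersection(beta[3].probe_ids))
        assert injected <= flagged  # full recall of injected outliers


class TestAnnotationFilter:
    def test_rules(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["Y", "X", "1", "2"],
                "snp_at_probe": [False, False, True, False],
            },
            index=["pY", "pX", "pSNP", "pOK"],
        )
        bad, unannot = annotation_filter(ann, ["pY", "pX", "pSNP", "pOK", "pMissing"])
        assert bad == {"pY", "pSNP"}
        assert unannot == {"pMissing"}  # reported, not silently dropped


class TestSampleQC:
    def test_low_call_rate_fails(self):
        detp = np.full((100, 3), 0.001)
        detp[:50, 0] = 0.5  # sample s0: call rate 0.5
        bm = make_bm(np.full((100, 3), 0.5), detp)
        assert sample_qc(bm) == {"s0": "low_call_rate"}

    def test_identical_samples_all_pass(self):
        bm = make_bm(np.full((50, 5), 0.4))
        assert sample_qc(bm) == {}

    def test_bisulfite_failure(self):
        bm = make_bm(np.full((20, 3), 0.4))
        br = pd.Series([0.99, 0.7, 0.99], index=["s0", "s1", "s2"])
        assert sample_qc(bm, bisulfite_ratio=br) == {"s1": "bisulfite_failure"}

    def test_low_mean_beta_outlier(self, rng):
        vals = np.clip(rng.normal(0.5, 0.01, (200, 20)), 0, 1)
        vals[:, 3] = 0.05  # far more than 4 MADs low
        bm = make_bm(vals)
        assert sample_qc(bm) == {"s3": "low_mean_beta"}

    def test_generator_injected_failures_recovered(self, tiny_config, tiny_cohort):
        """Recall of injected failing samples is 1.0 with correct reasons."""
        sheet, truth, beta = tiny_cohort
        found = {}
        for batches in ((1, 2), (3,)):
            bm = BetaMatrix(
                pd.concat([beta[b].beta for b in batches], axis=1),
                pd.concat([beta[b].detp for b in batches], axis=1),
            )
            rep = run_sample_qc(bm, sheet)
            found.update(dict(zip(rep.excluded_samples["sample_id"], rep.excluded_samples["reason"])))
        for s in truth.lowcallrate_samples:
            assert found.get(s) == "low_call_rate"
        for s in truth.bisulfite_fail_samples:
            assert found.get(s) == "bisulfite_failure"
        for s in truth.lowmeanbeta_samples:
            assert found.get(s) == "low_mean_beta"


class TestReplicateConcordance:
    def test_identical_replicates(self):
        base = np.random.default_rng(5).uniform(0.1, 0.9, 100)
        bm = make_bm(np.column_stack([base, base, base]))
        out = replicate_concordance(bm, {"g": ["s0", "s1", "s2"]})
        assert out.loc[0, "min_pairwise_r"] == pytest.approx(1.0)
        assert out.loc[0, "icc"] == pytest.approx(1.0)

    def test_independent_noise_icc_near_zero(self, rng):
        bm = make_bm(np.clip(rng.normal(0.5, 0.05, (2000, 3)), 0, 1))
        out = replicate_concordance(bm, {"g": ["s0", "s1", "s2"]})
        assert abs(out.loc[0, "icc"]) < 0.05

    def test_variance_components_closed_form(self, rng):
        """ICC ~ var(truth) / (var(truth) + var(noise))."""
        truth = rng.normal(0.5, 0.15, 5000)
        noise_sd = 0.05
        mat = truth[:, None] + rng.normal(0, noise_sd, (5000, 3))
        expected = 0.15**2 / (0.15**2 + noise_sd**2)
        assert _icc1(mat) == pytest.approx(expected, abs=0.02)

    def test_singleton_group_skipped_with_warning(self):
        bm = make_bm(np.full((10, 2), 0.5))
        with pytest.warns(UserWarning):
            out = replicate_concordance(bm, {"g": ["s0"]})
        assert len(out) == 0

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        mat = rng.normal(0.5, 0.1, (40, 3)) + rng.normal(0, 0.03, (40, 3))
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(40), 3),
                "rater": np.tile(np.arange(3), 40),
                "score": mat.ravel(),
            }
        )
        icc_pg = pg.intraclass_corr(long, targets="target", raters="rater",
                                    ratings="score").set_index("Type").loc["ICC(1,1)", "ICC"]
        assert _icc1(mat) == pytest.approx(icc_pg, abs=1e-9)


class TestProbeQCIntegration:
    def test_primary_reason_order_and_idempotence(self, tiny_config, tiny_cohort):
        sheet, truth, beta = tiny_cohort
        ann = simulate_annotation(truth, tiny_config)
        bm = BetaMatrix(
            pd.concat([beta[b].beta for b in (1, 2)], axis=1),
            pd.concat([beta[b].detp for b in (1, 2)], axis=1),
        )
        sub = sheet[sheet["sample_id"].isin(bm.sample_ids)]
        neg = sub.loc[sub["role"] == "negative_bsm", "sample_id"]
        study = sub.loc[sub["role"] == "study", "sample_id"]
        rep = run_probe_qc(bm, ann, neg, study)
        reasons = dict(zip(rep.excluded_probes["probe_id"], rep.excluded_probes["reason"]))
        # injected failures on this panel are all recovered
        for p in truth.lowdetect_probes.intersection(bm.probe_ids):
            assert p in reasons
        for p in truth.y_probes.intersection(bm.probe_ids):
            assert reasons[p] == "y_chromosome"
        # one primary reason per probe; rerunning on the filtered matrix excludes nothing new
        assert rep.excluded_probes["probe_id"].is_unique
        kept = bm.subset_probes(set(bm.probe_ids) - rep.excluded_probe_ids)
        rep2 = run_probe_qc(kept, ann, neg, study)
        injected = set(truth.lowdetect_probes) | set(truth.negctrl_outlier_probes) | \
            set(truth.y_probes) | set(truth.snp_probes)
        assert not (rep2.excluded_probe_ids & injected)
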