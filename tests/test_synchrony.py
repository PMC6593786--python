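"""The D statistic, mixed-model analyses, correlation and robustness."""

import numpy as np
import pandas as pd
import pytest

from gesturesync import (
    GestureAnnotation,
    KinematicAnchors,
    PeakPitch,
    compute_D,
    csh_SDD_analysis,
    csh_absolute_D_analysis,
    descriptive_rates,
    eh_shift_analysis,
    fit_random_intercept_model,
    leave_two_out_robustness,
    likelihood_ratio_test,
    sd_mean_correlation,
    summarize_D,
)
from gesturesync.io import ConditionSchedule
from gesturesync.mixedlm import SingularModelError
from gesturesync.synchrony import D_COLUMNS, records_long


def _peak(t):
    return PeakPitch(t_peak_s=t, f0_peak_hz=180.0, found=True)


def _anchors(t_on, t_acc, t_vel, t_dec):
    return KinematicAnchors(t_onset=t_on, t_peak_acc=t_acc, t_peak_vel=t_vel,
                            t_peak_dec=t_dec, v_peak=30.0)


class TestComputeD:
    def test_gesture_peak_before_pitch_peak_is_negative(self):
        # anchor precedes the pitch peak: the offset must come out negative
        a = _anchors(0.9, 0.93, 0.966, 1.0)
        rec = compute_D(a, _peak(1.0), "p", "DAF", "beat")
        assert rec["D_peak_vel"] == pytest.approx(-34.0)

    def test_simultaneous_peaks_give_zero(self):
        a = _anchors(0.9, 0.95, 1.0, 1.05)
        rec = compute_D(a, _peak(1.0), "p", "DAF", "beat")
        assert rec["D_peak_vel"] == 0.0

    def test_offsets_monotone_over_anchors(self):
        a = _anchors(1.0, 1.1, 1.2, 1.3)
        rec = compute_D(a, _peak(1.15), "p", "NODAF", "iconic")
        got = [rec[c] for c in D_COLUMNS]
        assert got == pytest.approx([-150.0, -50.0, 50.0, 150.0])
        assert got == sorted(got)

    def test_missing_peak_rejected(self):
        a = _anchors(1.0, 1.1, 1.2, 1.3)
        with pytest.raises(ValueError):
            compute_D(a, PeakPitch(np.nan, np.nan, found=False), "p", "DAF", "beat")


def _records(rows):
    base = {"participant": "p1", "event_id": None, "condition": "DAF",
            "gesture_type": "beat", "t_peak_pitch": 0.0}
    return pd.DataFrame([base | r for r in rows])


class TestSummarize:
    def test_mean_and_sample_sd(self):
        rows = [{"event_id": i, "D_onset": d - 30, "D_peak_acc": d - 10,
                 "D_peak_vel": d, "D_peak_dec": d + 10} for i, d in enumerate([-10.0, 0.0, 10.0])]
        s = summarize_D(_records(rows))
        vel = s[s["anchor"] == "peak_vel"].iloc[0]
        assert vel["n"] == 3
        assert vel["mean_D"] == pytest.approx(0.0)
        assert vel["sd_D"] == pytest.approx(10.0)

    def test_single_observation_has_missing_sd_and_ci(self):
        s = summarize_D(_records([{"D_onset": -30, "D_peak_acc": -10, "D_peak_vel": 0,
                                   "D_peak_dec": 10}]))
        assert s["sd_D"].isna().all()
        assert s["ci_low"].isna().all()

    def test_sampling_distribution_of_the_mean(self, rng):
        mu, sigma, n = 34.0, 193.0, 130
        d = rng.normal(mu, sigma, size=n)
        rows = [{"event_id": i, "D_onset": x - 300, "D_peak_acc": x - 50, "D_peak_vel": x,
                 "D_peak_dec": x + 100} for i, x in enumerate(d)]
        s = summarize_D(_records(rows))
        vel = s[s["anchor"] == "peak_vel"].iloc[0]
        assert abs(vel["mean_D"] - mu) < 2 * sigma / np.sqrt(n)


class TestMixedModel:
    def _balanced(self, effect=30.0, noise=0.0, rng=None, n_per=4, n_groups=5):
        rows = []
        for g in range(n_groups):
            for cond, base in (("NODAF", 10.0), ("DAF", 10.0 + effect)):
                for _ in range(n_per):
                    e = 0.0 if rng is None else rng.normal(0, noise)
                    rows.append({"participant": f"g{g}", "condition": cond, "y": base + e})
        return pd.DataFrame(rows)

    def test_noiseless_balanced_coefficient_exact(self):
        df = self._balanced(effect=30.0)
        fit = fit_random_intercept_model(df, "y", ["C(condition, Treatment('NODAF'))"], "participant")
        assert fit.degenerate  # zero residual variance handled as exact OLS
        coef = fit.params[[i for i in fit.params.index if "DAF" in i][0]]
        assert coef == pytest.approx(30.0, abs=1e-9)
        assert fit.group_var == 0.0

    def test_single_group_falls_back_to_ols(self, rng):
        df = self._balanced(noise=5.0, rng=rng, n_groups=1)
        fit = fit_random_intercept_model(df, "y", ["C(condition)"], "participant")
        assert fit.degenerate
        assert fit.group_var == 0.0

    def test_singular_design_names_the_term(self):
        df = self._balanced(noise=1.0, rng=np.random.default_rng(0))
        df["dup"] = (df["condition"] == "DAF").astype(float)
        with pytest.raises(SingularModelError, match="dup|condition"):
            fit_random_intercept_model(df, "y", ["C(condition)", "dup"], "participant")

    def test_lrt_of_identical_models_is_zero(self, rng):
        df = self._balanced(noise=5.0, rng=rng)
        fit = fit_random_intercept_model(df, "y", ["C(condition)"], "participant")
        res = likelihood_ratio_test(fit, fit)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_adding_a_parameter_never_increases_deviance(self, rng):
        df = self._balanced(effect=5.0, noise=20.0, rng=rng, n_per=10, n_groups=8)
        f0 = fit_random_intercept_model(df, "y", [], "participant")
        f1 = fit_random_intercept_model(df, "y", ["C(condition)"], "participant")
        assert f1.deviance <= f0.deviance + 1e-6

    def test_type_I_error_rate_nominal(self):
        """Null simulation: the condition LRT rejects at ~alpha."""
        rej = 0
        n_rep = 150
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            df = self._balanced(effect=0.0, noise=20.0, rng=rng, n_per=6, n_groups=8)
            df["y"] += df.groupby("participant")["y"].transform(lambda s: rng.normal(0, 10))
            f0 = fit_random_intercept_model(df, "y", [], "participant")
            f1 = fit_random_intercept_model(df, "y", ["C(condition)"], "participant")
            if likelihood_ratio_test(f0, f1).p < 0.05:
                rej += 1
        assert 0.02 <= rej / n_rep <= 0.09

    def test_strong_effect_always_detected(self):
        """Power simulation: +100 ms shift, residual SD 200, n=500 rows."""
        rng = np.random.default_rng(5)
        detected = 0
        n_seeds = 40
        for _ in range(n_seeds):
            rows = []
            for g in range(10):
                u = rng.normal(0, 50)
                for _ in range(50):
                    cond = "DAF" if rng.random() < 0.5 else "NODAF"
                    y = u + (100.0 if cond == "DAF" else 0.0) + rng.normal(0, 200)
                    rows.append({"participant": f"g{g}", "condition": cond, "y": y})
            df = pd.DataFrame(rows)
            f0 = fit_random_intercept_model(df, "y", [], "participant")
            f1 = fit_random_intercept_model(df, "y", ["C(condition)"], "participant")
            if likelihood_ratio_test(f0, f1).p < 0.001:
                detected += 1
        assert detected >= 0.95 * n_seeds


class TestCSHAnalyses:
    def test_equal_absolute_D_gives_null_condition_effect(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(6):
            for cond in ("DAF", "NODAF"):
                for i in range(20):
                    d = rng.normal(0, 200)
                    rows.append({"participant": f"p{p}", "event_id": i, "condition": cond,
                                 "gesture_type": "beat", "t_peak_pitch": 0.0,
                                 "D_onset": d - 300, "D_peak_acc": d - 50,
                                 "D_peak_vel": d, "D_peak_dec": d + 100})
        res = csh_absolute_D_analysis(pd.DataFrame(rows))
        assert abs(res.condition_coef) < 50.0
        assert res.lrt.df == 1

    def test_missing_condition_stratum_rejected(self, study_records):
        only = study_records[study_records["condition"] == "DAF"]
        with pytest.raises(ValueError):
            csh_absolute_D_analysis(only)

    def test_wider_nodaf_spread_gives_positive_nodaf_absolute_effect(self):
        """E|D| grows with sigma (folded normal), so sigma 230 vs 193 shows up."""
        rng = np.random.default_rng(8)
        rows = []
        for p in range(10):
            for cond, sd in (("NODAF", 230.0), ("DAF", 193.0)):
                for i in range(60):
                    d = rng.normal(20.0, sd)
                    rows.append({"participant": f"p{p}", "event_id": i, "condition": cond,
                                 "gesture_type": "beat", "t_peak_pitch": 0.0,
                                 "D_onset": d, "D_peak_acc": d, "D_peak_vel": d,
                                 "D_peak_dec": d})
        res = csh_absolute_D_analysis(pd.DataFrame(rows))
        # coefficient is the DAF effect: NO DAF has the higher |D|, so negative
        assert res.condition_coef < 0

    def test_sdd_single_anchor_skips_anchor_term(self, study_records):
        beat = study_records[study_records["gesture_type"] == "beat"]
        res = csh_SDD_analysis(beat, anchors=("peak_vel",))
        assert all(l.label != "anchor" for l in res.lrts)

    def test_sdd_needs_two_participants(self, study_records):
        one = study_records[study_records["participant"] == "p01"]
        with pytest.raises(ValueError):
            csh_SDD_analysis(one)


class TestEHAnalysis:
    def test_deterministic_shift_recovered_exactly(self):
        rows = []
        for p in range(4):
            for cond, shift in (("NODAF", 0.0), ("DAF", 33.0)):
                for i in range(5):
                    rows.append({"participant": f"p{p}", "event_id": f"{p}_{cond}_{i}",
                                 "condition": cond, "gesture_type": "beat", "t_peak_pitch": 0.0,
                                 "D_onset": -300 + shift, "D_peak_acc": -40 + shift,
                                 "D_peak_vel": 7 + shift, "D_peak_dec": 105 + shift})
        res = eh_shift_analysis(pd.DataFrame(rows), "beat")
        assert res.condition_coef == pytest.approx(33.0, abs=1e-6)

    def test_interaction_null_on_homogeneous_shift(self, study_records):
        # generator applies the same shift to all anchors: interaction should be null
        res = eh_shift_analysis(study_records, "beat")
        inter = next(l for l in res.lrts if l.label == "interaction")
        assert inter.p > 0.01

    def test_long_format_row_count(self, study_records):
        beat = study_records[study_records["gesture_type"] == "beat"]
        long = records_long(beat)
        assert len(long) == 4 * len(beat)


class TestSDMeanCorrelation:
    def _records_from_pairs(self, means, sds, n_ev=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, (m, s) in enumerate(zip(means, sds)):
            for j in range(n_ev):
                d = rng.normal(m, s)
                rows.append({"participant": f"p{i:02d}", "event_id": j, "condition": "DAF",
                             "gesture_type": "beat", "t_peak_pitch": 0.0, "D_onset": d,
                             "D_peak_acc": d, "D_peak_vel": d, "D_peak_dec": d})
        return pd.DataFrame(rows)

    def test_collinear_points_give_r_one(self):
        df = self._records_from_pairs(means=[50, 100, 150, 200], sds=[50, 100, 150, 200],
                                      n_ev=400, seed=1)
        res = sd_mean_correlation(df, "peak_vel", "DAF")
        assert res.r > 0.95

    def test_independent_mean_and_sd_give_null_r(self):
        # normal theory: the sample mean and SD are independent
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(300):
            df = self._records_from_pairs(means=rng.normal(0, 80, 14),
                                          sds=np.full(14, 200.0), n_ev=8,
                                          seed=int(rng.integers(2**31)))
            rs.append(sd_mean_correlation(df, "peak_vel", "DAF").r)
        assert abs(np.mean(rs)) < 0.05

    def test_positive_dependence_sign_recovered(self):
        rng = np.random.default_rng(4)
        hits = 0
        for k in range(20):
            sds = rng.uniform(100, 400, 14)
            means = sds * 0.5 + rng.normal(0, 20, 14)
            df = self._records_from_pairs(means, sds, n_ev=60, seed=k)
            if sd_mean_correlation(df, "peak_vel", "DAF").r > 0:
                hits += 1
        assert hits >= 19

    def test_too_few_participants_rejected(self):
        df = self._records_from_pairs(means=[0, 10], sds=[100, 100])
        with pytest.raises(ValueError):
            sd_mean_correlation(df, "peak_vel", "DAF")


class TestDescriptiveRates:
    def test_rate_arithmetic(self):
        sched = ConditionSchedule(warmup_s=0.0, block_s=60.0, first_block="DAF")
        ann = pd.DataFrame({
            "participant": ["p"] * 21, "onset_s": np.linspace(1, 59, 21),
            "offset_s": np.linspace(1.2, 59.2, 21),
            "gesture_type": ["beat"] * 21, "condition": ["DAF"] * 21,
        })
        rates = descriptive_rates(ann, sched, 120.0)  # 60 s DAF + 60 s NO DAF
        daf = rates[rates["condition"] == "DAF"].iloc[0]
        assert daf["gestures_per_min"] == pytest.approx(21.0)

    def test_zero_gestures_is_rate_zero_not_missing(self):
        sched = ConditionSchedule()
        ann = pd.DataFrame({"participant": ["p"], "onset_s": [40.0], "offset_s": [40.5],
                            "gesture_type": ["beat"], "condition": ["DAF"]})
        rates = descriptive_rates(ann, sched, 160.0)
        nodaf = rates[rates["condition"] == "NODAF"].iloc[0]
        assert nodaf["gestures_per_min"] == 0.0


class TestLeaveTwoOut:
    @staticmethod
    def _dummy_analysis(records):
        return (float(records["D_peak_vel"].mean()), 0.001)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_dataset_count_is_n_choose_2(self, n):
        rows = [{"participant": f"p{i:02d}", "event_id": j, "condition": c,
                 "gesture_type": "beat", "t_peak_pitch": 0.0, "D_onset": 0.0,
                 "D_peak_acc": 0.0, "D_peak_vel": float(j), "D_peak_dec": 0.0}
                for i in range(n) for j in range(3) for c in ("DAF", "NODAF")]
        rep = leave_two_out_robustness(pd.DataFrame(rows), self._dummy_analysis)
        assert rep.n_datasets == n * (n - 1) // 2

    def test_strong_effect_fully_robust(self, study_records):
        both = study_records[study_records["gesture_type"].isin(["beat", "iconic"])].copy()
        both.loc[both["condition"] == "DAF", list(D_COLUMNS)] += 200.0  # unmissable shift
        rep = leave_two_out_robustness(both, lambda r: eh_shift_analysis(r, None))
        assert rep.fraction_significant == 1.0

    def test_exclusion_losing_a_condition_is_flagged(self, study_records):
        sub = study_records[study_records["participant"].isin(["p01", "p02", "p03"])].copy()
        # confine DAF to participants p01 and p02: excluding that pair kills it
        sub = sub[~((sub["condition"] == "DAF") & (sub["participant"] == "p03"))]
        rep = leave_two_out_robustness(sub, lambda r: eh_shift_analysis(r, None))
        assert rep.n_datasets == 3
        assert rep.n_valid == 2
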