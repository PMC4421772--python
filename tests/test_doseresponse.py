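"""Normalisation, logistic MLE, outlier rule, EC10 and batch aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytovar import doseresponse as dr
from cytovar import synthdata as sd

D8 = np.log10(sd.default_concentrations())


def make_profile(y, d=D8, **kw):
    defaults = dict(chemical_id="c", line_id="l", batch="b", plate="p")
    defaults.update(kw)
    return dr.ResponseProfile(d=d, y=np.asarray(y, float), **defaults)


def plate_df(signals, neg=(40_000.0,), pos=(2_000.0,)):
    rows = []
    for i, s in enumerate(signals):
        rows.append(("c", "l", "b", "p", "treatment", sd.default_concentrations()[i], s))
    for s in neg:
        rows.append(("", "l", "b", "p", "neg_ctrl", np.nan, s))
    for s in pos:
        rows.append(("", "l", "b", "p", "pos_ctrl", np.nan, s))
    return pd.DataFrame(
        rows, columns=["chemical_id", "line_id", "batch", "plate", "role",
                       "concentration_molar", "signal"],
    )


class TestNormalize:
    def test_control_anchors(self):
        df = plate_df([40_000.0] * 4 + [2_000.0] * 3 + [21_000.0])
        profs, issues = dr.normalize_plate(df)
        assert not issues
        y = profs[0].y
        assert y[0] == pytest.approx(1.0)
        assert y[4] == pytest.approx(0.0)
        assert y[7] == pytest.approx(0.5)

    def test_missing_controls_rejects_plate(self):
        df = plate_df([30_000.0] * 8, pos=())
        profs, issues = dr.normalize_plate(df)
        assert profs == []
        assert any("positive" in msg for msg in issues)

    def test_normalization_uses_medians(self):
        # an extreme single control well must not move the anchors
        df = plate_df([40_000.0] * 8, neg=(39_000, 40_000, 41_000, 500_000),
                      pos=(1_900, 2_000, 2_100))
        profs, _ = dr.normalize_plate(df)
        assert profs[0].y[0] == pytest.approx((40_000 - 2_000) / (40_500 - 2_000))


class TestCurve:
    def test_midpoint(self):
        assert dr.curve(0.0, 0.0, -1.0, 0.9) == pytest.approx(0.45)

    def test_flat_when_slope_zero(self):
        vals = dr.curve(np.linspace(-9, -4, 8), 2.0, 0.0, 1.0)
        assert np.allclose(vals, 1.0 / (1.0 + math.exp(-2.0)))

    def test_ninety_percent_point(self):
        assert dr.curve(0.0, math.log(9.0), -1.0, 1.0) == pytest.approx(0.9)

    @settings(max_examples=50, deadline=None)
    @given(
        beta0=st.floats(-30, 30), beta1=st.floats(-8, -0.01),
        tmax=st.floats(0.2, 1.2),
    )
    def test_monotone_decreasing_for_negative_slope(self, beta0, beta1, tmax):
        d = np.linspace(-9.5, -4.0, 40)
        eta = dr.curve(d, beta0, beta1, tmax)
        assert np.all(np.diff(eta) <= 1e-12)


class TestFitLogistic:
    def test_noiseless_parameter_recovery(self):
        y = dr.curve(D8, b0 := 5.0, b1 := -2.0, 1.0)
        f = dr.fit_logistic(make_profile(y), theta_max_rule=None)
        assert f.converged
        assert f.beta0 == pytest.approx(b0, abs=1e-4)
        assert f.beta1 == pytest.approx(b1, abs=1e-4)
        assert f.theta_max == pytest.approx(1.0, abs=1e-4)

    def test_flat_profile_censored(self):
        f = dr.fit_logistic(make_profile([0.97] * 8))
        assert f.censored
        assert f.log_ec10 == pytest.approx(D8[-1])

    def test_theta_max_fix_rule_triggers_above_0p4(self):
        # weakly toxic: response at the top concentration stays at 0.6
        y = np.array([1.0, 1.0, 0.99, 0.95, 0.9, 0.8, 0.7, 0.6])
        f = dr.fit_logistic(make_profile(y), theta_max_rule="plateau")
        assert f.theta_max_fixed
        assert f.theta_max == pytest.approx(1.0)  # mean of two lowest-conc y
        f_top = dr.fit_logistic(make_profile(y), theta_max_rule="top")
        assert f_top.theta_max == pytest.approx(0.6)
        f_free = dr.fit_logistic(make_profile(y), theta_max_rule=None)
        assert not f_free.theta_max_fixed

    def test_too_few_points_refused(self):
        p = make_profile(dr.curve(D8, 5, -2, 1.0))
        p.mask[:5] = False
        with pytest.raises(ValueError, match="refused"):
            dr.fit_logistic(p)


class TestComputeLogEc10:
    def test_censored_when_beta0_ln9(self):
        fit = dr.LogisticFit(beta0=math.log(9), beta1=-1.0, sigma2=1e-4, theta_max=1.0)
        le, cens = dr.compute_log_ec10(fit, d_max=D8[-1])
        # solution d = 0 (EC10 = 1 M) lies above the tested range
        assert cens and le == pytest.approx(D8[-1])

    def test_closed_form(self):
        fit = dr.LogisticFit(beta0=2 * math.log(9), beta1=-math.log(9),
                             sigma2=1e-4, theta_max=1.0)
        le, cens = dr.compute_log_ec10(fit, d_max=2.0)
        assert not cens
        assert le == pytest.approx(1.0)

    def test_positive_slope_censored(self):
        fit = dr.LogisticFit(beta0=0.0, beta1=0.5, sigma2=1e-4, theta_max=1.0)
        le, cens = dr.compute_log_ec10(fit, d_max=D8[-1])
        assert cens


def brute_force_outlier_flags(profile, theta_max_rule="plateau"):
    """Independent drop-one oracle: refit on every 7-point subset and flag by
    the factor-10 likelihood-improvement rule."""
    full = dr.fit_logistic(profile, theta_max_rule=theta_max_rule)
    flags = []
    for j in range(profile.d.size):
        mask = np.ones(profile.d.size, bool)
        mask[j] = False
        sub = dr.ResponseProfile("c", "l", "b", "p", profile.d, profile.y, mask=mask)
        red = dr.fit_logistic(sub, theta_max_rule=theta_max_rule)
        if red.log_likelihood - full.log_likelihood >= math.log(10.0):
            flags.append(j)
    return set(flags)


class TestDetectOutliers:
    def test_clean_noiseless_profile_unflagged(self):
        y = dr.curve(D8, 5.0, -2.0, 1.0)
        f = dr.detect_outliers(make_profile(y))
        assert f.outliers == frozenset()

    def test_single_displaced_well_flagged(self):
        # noiseless curve with EC10 at -5.5, one well displaced by 0.5
        y = dr.curve(D8, np.log(9) - 3.0 * 5.5, -3.0, 1.0)
        y[3] += 0.5
        f = dr.detect_outliers(make_profile(y))
        assert f.outliers == frozenset({3})
        # final parameters come from the refit excluding the flagged well
        assert abs(f.beta1 - (-3.0)) < 1e-3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        truth = rng.uniform(-7.5, -4.5, 30)
        profs, _ = sd.simulate_profiles(truth, seed=18, noise_sd=0.05,
                                        outlier_magnitude=0.4)
        for p in profs:
            f = dr.detect_outliers(p)
            assert set(f.outliers) == brute_force_outlier_flags(p)

    def test_never_leaves_fewer_than_four_points(self):
        # pathological profile: most wells displaced
        y = dr.curve(D8, 5.0, -2.0, 1.0)
        y[[0, 2, 4, 5, 7]] += np.array([0.6, -0.6, 0.7, -0.7, 0.6])
        f = dr.detect_outliers(make_profile(y))
        assert 8 - len(f.outliers) >= 4


class TestFitWellTable:
    def test_pre_normalized_input_skips_controls(self):
        conc = sd.default_concentrations()
        y = dr.curve(np.log10(conc), np.log(9) - 2.0 * 6.0, -2.0, 1.0)
        wells = pd.DataFrame({
            "chemical_id": "c", "line_id": "l", "batch": "b", "plate": "p",
            "role": "treatment", "concentration_molar": conc, "signal": y,
        })
        fits = dr.fit_well_table(wells, pre_normalized=True,
                                 outlier_detection=False)
        assert len(fits) == 1
        assert fits.loc[0, "log_ec10"] == pytest.approx(-6.0, abs=1e-6)


class TestBatchCorrectAndAggregate:
    def _fits(self, rows):
        return pd.DataFrame(
            rows, columns=["chemical_id", "line_id", "batch", "plate",
                           "log_ec10", "censored", "n_outliers"],
        )

    def test_single_batch_identity(self):
        fits = self._fits([
            ("c", "l1", "b1", "p1", -6.0, False, 0),
            ("c", "l2", "b1", "p2", -5.0, False, 0),
        ])
        per_line, _ = dr.batch_correct_and_aggregate(fits)
        assert per_line["log_ec10"].tolist() == [-6.0, -5.0]

    def test_pure_batch_shift_removed(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(-6, 0.3, 20)
        rows = []
        for i, v in enumerate(vals):
            rows.append(("c", f"l{i}", "b1", f"p{i}a", v, False, 0))
            rows.append(("c", f"l{i}", "b2", f"p{i}b", v + 0.3, False, 0))
        per_line, registry = dr.batch_correct_and_aggregate(self._fits(rows))
        corr = registry.groupby("batch")["log_ec10_corrected"].mean()
        assert abs(corr["b1"] - corr["b2"]) < 1e-12

    def test_replicate_registry_counts(self):
        fits = self._fits([
            ("c", "l1", "b1", "p1", -6.0, False, 1),
            ("c", "l1", "b2", "p2", -6.2, False, 0),
            ("c", "l2", "b1", "p3", -5.8, False, 0),
        ])
        per_line, registry = dr.batch_correct_and_aggregate(fits)
        row = per_line.set_index("line_id").loc["l1"]
        assert row["n_prime"] == 2
        assert len(registry) == 3

    def test_all_censored_line_stays_censored(self):
        fits = self._fits([
            ("c", "l1", "b1", "p1", -4.0, True, 0),
            ("c", "l2", "b1", "p2", -6.0, False, 0),
        ])
        per_line, _ = dr.batch_correct_and_aggregate(fits)
        assert per_line.set_index("line_id").loc["l1", "censored"]


class TestPipelineInvariants:
    def test_censoring_conservation(self):
        rng = np.random.default_rng(3)
        # mix of active and inactive chemicals
        truth = np.concatenate([rng.uniform(-7, -5, 30), np.full(10, -2.0)])
        profs, _ = sd.simulate_profiles(truth, seed=4, noise_sd=0.05)
        fits = [dr.fit_logistic(p) for p in profs]
        conv = [f for f in fits if f.converged]
        n_cens = sum(f.censored for f in conv)
        n_fin = sum((not f.censored) and np.isfinite(f.log_ec10) for f in conv)
        assert n_cens + n_fin == len(conv)
        assert n_cens >= 10  # inactive chemicals are reported as no-effect
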