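"""RPPM quantification: spot filtering, 5PL fits, ROUT-FDR, y-intercepts."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from twibio.rppm import (
    LOG10_2,
    FiveParamLogistic,
    RppmError,
    fit_master,
    fit_samples,
    fivepl_eval,
    max_slope_point,
    preprocess_spots,
    quantify,
    remove_outliers_fdr,
    run_rppm_pipeline,
)
from twibio.synthetic import PlateSpec, make_plate

SHAPE = FiveParamLogistic(A=4.7, D=2.2, B=1.0, G=1.5, x_mid=-2.0)


def synthetic_spots(shape=SHAPE, n_samples=8, n_steps=16, noise_sd=0.0, seed=0,
                    abundance=None):
    spec = PlateSpec(
        n_samples=n_samples, n_dilution_steps=n_steps, shape=shape,
        noise_sd=noise_sd, seed=seed,
        true_log10_abundance=abundance,
    )
    plate, truth = make_plate(spec)
    return preprocess_spots(plate), truth


class TestPreprocess:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_low_snr_excluded_despite_bright(self):
        df = preprocess_spots(self._table(
            [{"sample_id": "a", "dilution_step": k, "fg": 550.0, "bg": 50.0,
              "snr": 1.9 if k == 0 else 50.0} for k in range(8)]
        ))
        assert not df.loc[df.dilution_step == 0, "included"].iloc[0]

    def test_low_net_excluded_despite_high_snr(self):
        df = preprocess_spots(self._table(
            [{"sample_id": "a", "dilution_step": k, "fg": 59.0 if k == 0 else 500.0,
              "bg": 50.0, "snr": 50.0} for k in range(8)]
        ))
        assert not df.loc[df.dilution_step == 0, "included"].iloc[0]

    def test_counting(self):
        rows = [{"sample_id": "a", "dilution_step": k, "fg": 500.0, "bg": 50.0, "snr": 10.0}
                for k in range(10)]
        rows[0]["snr"] = 1.0
        rows[1]["fg"] = 55.0
        rows[2]["snr"] = 0.5
        df = preprocess_spots(pd.DataFrame(rows))
        assert int(df["included"].sum()) == 7

    def test_log_coordinates(self):
        df = preprocess_spots(self._table(
            [{"sample_id": "a", "dilution_step": k, "fg": 1050.0, "bg": 50.0, "snr": 9.0}
             for k in range(4)]
        ))
        assert np.allclose(df["x"], -df["dilution_step"] * LOG10_2)
        assert np.allclose(df.loc[df.included, "y"], 3.0)

    def test_replicate_depositions_averaged(self):
        rows = [{"sample_id": "a", "block": 1, "dilution_step": 0, "fg": 100.0,
                 "bg": 50.0, "snr": 9.0},
                {"sample_id": "a", "block": 1, "dilution_step": 0, "fg": 300.0,
                 "bg": 50.0, "snr": 11.0}]
        df = preprocess_spots(pd.DataFrame(rows))
        assert len(df) == 1 and df["net"].iloc[0] == 150.0

    def test_all_filtered_is_error(self):
        with pytest.raises(RppmError, match="empty"):
            preprocess_spots(self._table(
                [{"sample_id": "a", "dilution_step": 0, "fg": 51.0, "bg": 50.0, "snr": 0.1}]
            ))


class TestFivePL:
    def test_symmetric_midpoint_when_g_is_one(self):
        p = FiveParamLogistic(A=4.0, D=1.0, B=2.0, G=1.0, x_mid=-1.0)
        assert fivepl_eval(p, -1.0) == pytest.approx(2.5)

    def test_asymptotes(self):
        p = SHAPE
        assert fivepl_eval(p, 50.0) == pytest.approx(p.A, abs=1e-9)
        assert fivepl_eval(p, -50.0) == pytest.approx(p.D, abs=1e-9)

    def test_hand_evaluated_point(self):
        p = FiveParamLogistic(A=4.0, D=1.0, B=1.0, G=2.0, x_mid=0.0)
        # at x = x_mid: y = D + (A−D)/2^G = 1 + 3/4
        assert fivepl_eval(p, 0.0) == pytest.approx(1.75)

    def test_strictly_increasing(self):
        x = np.linspace(-6, 2, 200)
        y = fivepl_eval(SHAPE, x)
        assert np.all(np.diff(y) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FiveParamLogistic(A=1.0, D=2.0, B=1.0, G=1.0, x_mid=0.0)
        with pytest.raises(ValueError):
            FiveParamLogistic(A=2.0, D=1.0, B=-1.0, G=1.0, x_mid=0.0)

    def test_max_slope_closed_form_against_numeric(self):
        """x* = x_mid + log10(G)/B and the slope there match a dense
        numerical differentiation of the curve."""
        for p in (SHAPE, FiveParamLogistic(A=5.0, D=1.5, B=0.7, G=3.0, x_mid=0.5)):
            x_star, slope = max_slope_point(p)
            xs = np.linspace(p.x_mid - 6, p.x_mid + 6, 400001)
            dy = np.gradient(fivepl_eval(p, xs), xs)
            i = np.argmax(dy)
            assert xs[i] == pytest.approx(x_star, abs=1e-3)
            assert dy[i] == pytest.approx(slope, rel=1e-5)


class TestMasterFit:
    def test_noiseless_recovery(self):
        spots, _ = synthetic_spots(noise_sd=0.0)
        fit = fit_master(spots)
        for name in ("A", "D", "B", "G", "x_mid"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(SHAPE, name), abs=1e-6
            )

    def test_noisy_recovery_within_five_percent(self):
        spots, _ = synthetic_spots(noise_sd=0.02, seed=0)
        fit = fit_master(spots)
        for name in ("A", "D", "B", "G"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(SHAPE, name), rel=0.05
            )

    def test_too_few_dilutions_rejected(self):
        rows = [{"sample_id": f"s{i}", "dilution_step": k, "fg": 500.0 - 100 * k,
                 "bg": 50.0, "snr": 9.0} for i in range(5) for k in range(2)]
        spots = preprocess_spots(pd.DataFrame(rows))
        with pytest.raises(RppmError, match="dilution"):
            fit_master(spots)


class TestOutlierRemoval:
    def test_zero_residuals_zero_flags_and_identical_refit(self):
        spots, _ = synthetic_spots(noise_sd=0.0)
        fit = fit_master(spots)
        spots2, refit = remove_outliers_fdr(spots, fit, q=0.01)
        assert len(refit.excluded_points) == 0
        assert refit.params == fit.params

    def test_clean_false_flag_rate(self):
        """Mean flagged fraction on clean plates stays at or below Q."""
        rates = []
        for seed in range(50):
            spots, _ = synthetic_spots(noise_sd=0.02, seed=400 + seed)
            fit = fit_master(spots)
            spots2, _ = remove_outliers_fdr(spots, fit, q=0.01)
            rates.append(spots2["outlier"].mean())
        assert np.mean(rates) <= 0.01

    def test_gross_outliers_flagged(self):
        """±1 log10 displacements of 5% of spots are flagged with high
        sensitivity across seeds."""
        sens = []
        for seed in range(20):
            spec = PlateSpec(noise_sd=0.02, outlier_fraction=0.05,
                             outlier_magnitude=1.0, seed=800 + seed)
            plate, truth = make_plate(spec)
            spots = preprocess_spots(plate)
            fit = fit_master(spots)
            spots2, _ = remove_outliers_fdr(spots, fit, q=0.01)
            flagged = set(spots2.loc[spots2["outlier"], "row_id"])
            injected = set(int(i) for i in truth["outlier_rows"])
            sens.append(len(flagged & injected) / len(injected))
        assert np.mean(sens) >= 0.8


class TestSampleFitsAndQuantify:
    def _master(self):
        spots, _ = synthetic_spots(noise_sd=0.0)
        return fit_master(spots)

    def test_exact_shift_recovery_noiseless(self):
        """A sample generated from the master curve shifted by Δx = +0.30
        is recovered with x_mid error below 1e-6."""
        master = self._master()
        shifted = replace(master.params, x_mid=master.params.x_mid + 0.30)
        x = -np.arange(16) * LOG10_2
        df = pd.DataFrame({
            "sample_id": "s", "block": 1, "dilution_step": np.arange(16),
            "x": x, "y": fivepl_eval(shifted, x), "included": True,
        })
        fits = fit_samples(df, master)
        assert fits["x_mid"].iloc[0] - master.params.x_mid == pytest.approx(0.30, abs=1e-6)

    def test_identical_samples_identical_xmid(self):
        master = self._master()
        x = -np.arange(16) * LOG10_2
        y = fivepl_eval(master.params, x)
        df = pd.DataFrame({
            "sample_id": ["a"] * 16 + ["b"] * 16, "block": 1,
            "dilution_step": list(range(16)) * 2,
            "x": np.concatenate([x, x]), "y": np.concatenate([y, y]),
            "included": True,
        })
        fits = fit_samples(df, master)
        assert fits["x_mid"].iloc[0] == fits["x_mid"].iloc[1]

    def test_small_samples_skipped_with_warning_row(self):
        master = self._master()
        x = -np.arange(2) * LOG10_2
        df = pd.DataFrame({
            "sample_id": "tiny", "block": 1, "dilution_step": np.arange(2),
            "x": x, "y": fivepl_eval(master.params, x), "included": True,
        })
        fits = fit_samples(df, master)
        assert not fits["fitted"].iloc[0] and math.isnan(fits["x_mid"].iloc[0])

    def test_mean_shift_recovery_under_noise(self):
        """Shift of 0.30 recovered within 0.01 on average (σ = 0.02)."""
        shifts = []
        for seed in range(40):
            abundance = np.array([0.0] * 4 + [0.30] * 4)
            spots, _ = synthetic_spots(noise_sd=0.02, seed=900 + seed,
                                       abundance=abundance)
            master = fit_master(spots)
            fits = fit_samples(spots, master).set_index("sample_id")
            lo = fits.loc[["S01", "S02", "S03", "S04"], "x_mid"].mean()
            hi = fits.loc[["S05", "S06", "S07", "S08"], "x_mid"].mean()
            shifts.append(lo - hi)  # higher abundance shifts x_mid left
        assert np.mean(shifts) == pytest.approx(0.30, abs=0.01)

    def test_tangent_translation_identity(self):
        """Samples differing only in x_mid have y-intercepts differing by
        slope·Δ exactly."""
        master = self._master()
        q1 = quantify({"sample_id": "a", "x_mid": -2.0, "rss": 0.0, "n_points": 16}, master)
        q2 = quantify({"sample_id": "b", "x_mid": -2.4, "rss": 0.0, "n_points": 16}, master)
        assert q1.slope_linear == q2.slope_linear > 0
        assert q2.y_intercept - q1.y_intercept == pytest.approx(
            q1.slope_linear * 0.4, rel=1e-12
        )

    def test_sample_identical_to_master(self):
        master = self._master()
        q = quantify({"sample_id": "m", "x_mid": master.params.x_mid}, master)
        x_star, slope = max_slope_point(master.params)
        expected = fivepl_eval(master.params, x_star) - slope * x_star
        assert q.y_intercept == pytest.approx(expected, rel=1e-12)


class TestPipeline:
    GROUPS = ["low"] * 4 + ["high"] * 4

    def test_noiseless_twofold_exact(self):
        spec = PlateSpec(
            noise_sd=0.0, seed=1, groups=self.GROUPS,
            true_log10_abundance=np.concatenate([np.zeros(4), np.full(4, LOG10_2)]),
        )
        plate, _ = make_plate(spec)
        quants, summary, master = run_rppm_pipeline(plate)
        d = quants.set_index("sample_id")
        slope = d["slope_linear"].iloc[0]
        delta = (d.loc[["S05", "S06", "S07", "S08"], "y_intercept"].mean()
                 - d.loc[["S01", "S02", "S03", "S04"], "y_intercept"].mean())
        assert delta / (slope * LOG10_2) == pytest.approx(1.0, abs=1e-3)
        assert set(summary["group"]) == {"low", "high"}

    def test_monotone_in_abundance_noiseless(self):
        """Raising true abundance never lowers the y-intercept."""
        abundance = np.linspace(-0.3, 0.6, 8)
        spec = PlateSpec(noise_sd=0.0, seed=1, true_log10_abundance=abundance)
        plate, _ = make_plate(spec)
        quants, _, _ = run_rppm_pipeline(plate)
        y0 = quants.sort_values("sample_id")["y_intercept"].to_numpy()
        assert np.all(np.diff(y0) >= -1e-9)

    def test_group_ordering_under_noise(self):
        """1.5-fold group difference is correctly ordered in ≥95% of runs."""
        ok = 0
        n_runs = 40
        for seed in range(n_runs):
            spec = PlateSpec(
                noise_sd=0.02, seed=1300 + seed, groups=self.GROUPS,
                true_log10_abundance=np.concatenate(
                    [np.zeros(4), np.full(4, math.log10(1.5))]
                ),
            )
            plate, _ = make_plate(spec)
            _, summary, _ = run_rppm_pipeline(plate)
            s = summary.set_index("group")
            ok += bool(s.loc["high", "mean"] > s.loc["low", "mean"])
        assert ok / n_runs >= 0.95

    def test_no_group_column_gives_no_summary(self):
        plate, _ = make_plate(PlateSpec(noise_sd=0.0, seed=2))
        quants, summary, _ = run_rppm_pipeline(plate)
        assert summary is None and len(quants) == 8

    def test_all_dim_spots_fail_in_stage_one(self):
        plate, _ = make_plate(PlateSpec(noise_sd=0.0, seed=2))
        plate["snr"] = 0.5
        with pytest.raises(RppmError, match="preprocess"):
            run_rppm_pipeline(plate)
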