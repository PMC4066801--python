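"""Exponential distance model, residual neighbor regression, summaries."""

import numpy as np
import pandas as pd
import pytest

from alueditability.models import (
    ExpFitParams,
    FitError,
    fit_exponential,
    fit_neighbor_regression,
    neighbor_effect,
    predict_exponential,
    residual_editability,
    stratified_exponential_fit,
    summarize_by,
    variance_explained,
)

PAPER = ExpFitParams(2.9, 800.0, 0.25, 1.0, 0.28)


class TestPredict:
    def test_large_distance_asymptote(self):
        assert predict_exponential(PAPER, 1e9) == pytest.approx(0.25)

    def test_zero_distance(self):
        assert predict_exponential(PAPER, 0) == pytest.approx(2.9 + 0.25)

    def test_one_decay_length(self):
        assert predict_exponential(PAPER, 800) == pytest.approx(2.9 / np.e + 0.25)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            predict_exponential(PAPER, -1)


class TestFitExponential:
    def noise_free(self):
        # distances at the centers of the default 100-bp bins, so the
        # binned and per-element modes see identical (d, E) pairs
        d = np.linspace(50, 3950, 40)
        return d, 2.9 * np.exp(-d / 800.0) + 0.25

    @pytest.mark.parametrize("mode", ["binned", "per_element"])
    def test_noise_free_recovery(self, mode):
        d, e = self.noise_free()
        p = fit_exponential(d, e, mode=mode)
        assert p.amplitude == pytest.approx(2.9, rel=1e-5)
        assert p.decay_bp == pytest.approx(800.0, rel=1e-4)
        assert p.baseline == pytest.approx(0.25, rel=1e-4)
        assert p.variance_explained_per_element == pytest.approx(1.0, abs=1e-9)

    def test_flat_data_degenerates_to_baseline(self):
        d = np.linspace(0, 3900, 40)
        p = fit_exponential(d, np.full(40, 1.7))
        assert p.amplitude == pytest.approx(0.0, abs=1e-6)
        assert p.baseline == pytest.approx(1.7, abs=1e-6)

    def test_scale_consistency(self):
        d, e = self.noise_free()
        rng = np.random.default_rng(3)
        e = e + rng.normal(0, 0.05, len(e))
        p1 = fit_exponential(d, e)
        p3 = fit_exponential(d, 3.0 * e)
        assert p3.amplitude == pytest.approx(3 * p1.amplitude, rel=1e-6)
        assert p3.baseline == pytest.approx(3 * p1.baseline, rel=1e-6)
        assert p3.decay_bp == pytest.approx(p1.decay_bp, rel=1e-6)

    def test_too_few_distinct_distances(self):
        with pytest.raises(FitError):
            fit_exponential([100, 100, 200], [1, 1, 2])

    def test_records_beyond_max_d_excluded_from_curve_not_variance(self):
        d = np.concatenate([np.linspace(50, 3950, 40), [20_000.0]])
        e = 2.9 * np.exp(-d / 800.0) + 0.25
        e[-1] = 5.0  # wild outlier far beyond the fit range
        p = fit_exponential(d, e, mode="binned", max_d=4000)
        assert p.amplitude == pytest.approx(2.9, rel=1e-4)
        assert p.variance_explained_per_element < 0.9  # outlier counted here

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1, 2, 3], mode="smoothed")


class TestResiduals:
    def test_exact_prediction_gives_zero(self):
        assert residual_editability(0.25, 1e9, PAPER) == pytest.approx(0.0)

    def test_offset_passes_through(self):
        pred = predict_exponential(PAPER, 500)
        assert residual_editability(pred + 1.0, 500, PAPER) == pytest.approx(1.0)

    def test_mean_residual_near_zero_for_per_element_fit(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 3900, 4000)
        e = 2.9 * np.exp(-d / 800) + 0.25 + rng.normal(0, 0.3, 4000)
        p = fit_exponential(d, e, mode="per_element")
        r = residual_editability(e, d, p)
        assert abs(np.mean(r)) < 1e-6


class TestNeighborRegression:
    def test_exact_recovery_on_noise_free_linear_data(self, rng):
        nss = rng.integers(0, 30, 500).astype(float)
        nrs = rng.integers(0, 30, 500).astype(float)
        resid = -0.022 * nss + 0.015 * nrs + 0.11
        params = fit_neighbor_regression(resid, nss, nrs, exp_baseline=0.25)
        assert params.beta_ss == pytest.approx(-0.022, abs=1e-12)
        assert params.beta_rs == pytest.approx(0.015, abs=1e-12)
        assert params.intercept_combined == pytest.approx(0.36, abs=1e-12)

    def test_zero_residuals_give_zero_coefficients(self, rng):
        nss = rng.integers(0, 30, 100).astype(float)
        nrs = rng.integers(0, 30, 100).astype(float)
        params = fit_neighbor_regression(np.zeros(100), nss, nrs)
        assert params.beta_ss == pytest.approx(0.0, abs=1e-12)
        assert params.beta_rs == pytest.approx(0.0, abs=1e-12)

    def test_collinear_design_rejected(self, rng):
        n = rng.integers(0, 30, 100).astype(float)
        with pytest.raises(FitError):
            fit_neighbor_regression(rng.normal(size=100), n, n)


class TestNeighborEffect:
    PARAMS = fit_neighbor_regression(
        [-0.022 * 1 + 0.015 * 2, -0.022 * 3 + 0.015 * 1, 0.0, -0.022 * 2],
        [1, 3, 0, 2], [2, 1, 0, 0])

    def test_ten_same_strand_elements(self):
        assert neighbor_effect(self.PARAMS, 10, 0) == pytest.approx(-0.22, abs=1e-9)

    def test_ten_reverse_elements(self):
        assert neighbor_effect(self.PARAMS, 0, 10) == pytest.approx(0.15, abs=1e-9)

    def test_no_change(self):
        assert neighbor_effect(self.PARAMS, 0, 0) == 0.0


class TestVarianceExplained:
    def test_perfect_prediction(self):
        e = [1.0, 2.0, 3.0]
        assert variance_explained(e, e) == pytest.approx(1.0)

    def test_mean_prediction(self):
        e = np.array([1.0, 2.0, 3.0])
        assert variance_explained(e, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(FitError):
            variance_explained([1.0, 1.0], [1.0, 1.0])

    def test_clip_keeps_reported_value_in_unit_interval(self):
        e = np.array([1.0, 2.0, 3.0])
        bad = np.array([10.0, -5.0, 7.0])
        assert variance_explained(e, bad) < 0
        assert variance_explained(e, bad, clip=True) == 0.0


def make_merged(groups, editability, d=None, extra=None):
    df = pd.DataFrame({"family": groups, "editability_pct": editability})
    df["d"] = d if d is not None else np.linspace(100, 2000, len(df))
    df["start"] = 0
    df["end"] = 300
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


class TestSummaries:
    def test_group_means_exact(self):
        merged = make_merged(["AluS", "AluS", "AluJ"], [1.0, 3.0, 5.0])
        out = {s.group: s for s in summarize_by(merged, "family")}
        assert out["AluS"].mean_editability == pytest.approx(2.0)
        assert out["AluJ"].n == 1

    def test_single_group_mean_equals_overall(self):
        merged = make_merged(["AluY"] * 4, [1.0, 2.0, 3.0, 4.0])
        (summary,) = summarize_by(merged, "family")
        assert summary.mean_editability == pytest.approx(2.5)

    def test_distance_correction_removes_spurious_group_difference(self, rng):
        # group "near" sits at short distances, "far" at long ones; the
        # residuals from the generating curve carry no group effect, so
        # raw means must differ while distance-corrected means agree
        n = 4000
        d_near = rng.uniform(100, 800, n)
        d_far = rng.uniform(2000, 3900, n)
        d = np.concatenate([d_near, d_far])
        e = 2.9 * np.exp(-d / 800) + 0.25 + rng.normal(0, 0.2, 2 * n)
        merged = make_merged(["near"] * n + ["far"] * n, e, d=d)
        raw = {s.group: s.mean_editability
               for s in summarize_by(merged, "family")}
        corrected = {s.group: s.mean_residual
                     for s in summarize_by(merged, "family", distance_correct=True)}
        assert raw["near"] - raw["far"] > 0.5
        assert abs(corrected["near"] - corrected["far"]) < 0.05

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            summarize_by(make_merged(["a"], [1.0]), "codon_bias")


def test_stratified_fit_identical_strata_agree(rng):
    d = np.tile(np.linspace(0, 3900, 500), 2)
    e = 2.9 * np.exp(-d / 800) + 0.25
    merged = pd.DataFrame({
        "d": d, "editability_pct": e,
        "expressed_strand_class": ["polyA"] * 500 + ["polyU"] * 500,
    })
    pa = stratified_exponential_fit(merged, "polyA")
    pu = stratified_exponential_fit(merged, "polyU")
    assert pa.decay_bp == pytest.approx(pu.decay_bp, rel=1e-9)
    assert pa.amplitude == pytest.approx(pu.amplitude, rel=1e-9)


def test_stratified_fit_unknown_stratum():
    with pytest.raises(ValueError):
        stratified_exponential_fit(pd.DataFrame(), "polyC")
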