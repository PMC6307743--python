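"""Satellite binarization, validation, OR-fusion and the sensitivity
stratifications."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snowcam.metrics import ConfusionCounts, UndefinedMetricError
from snowcam.modis import (
    binarize_modis,
    binarize_modis_table,
    combine_or,
    combine_or_table,
    fit_log_curve,
    seasonal_sensitivity,
    site_sensitivity_summary,
    stratified_metrics,
    validate_binary,
)
from snowcam.types import BinaryOutcome, ModisObservation


def outcome_series(values, ids=None):
    ids = ids or [f"i{k}" for k in range(len(values))]
    return pd.Series([v.value for v in values], index=pd.Index(ids, name="image_id"))


class TestBinarize:
    def test_exhaustive_truth_table(self):
        # oracle over {missing, zero, positive}^2: snow iff any positive,
        # missing iff both missing
        cases = {"missing": None, "zero": 0.0, "positive": 37.5}
        for (na, va), (nb, vb) in itertools.product(cases.items(), repeat=2):
            expected = (
                BinaryOutcome.MISSING
                if na == "missing" and nb == "missing"
                else BinaryOutcome.SNOW
                if "positive" in (na, nb)
                else BinaryOutcome.NO_SNOW
            )
            obs = ModisObservation("x", va, vb)
            assert binarize_modis(obs) is expected, (na, nb)

    def test_one_product_reporting_snow_is_snow(self):
        assert binarize_modis(ModisObservation("x", 10.0, None)) is BinaryOutcome.SNOW

    def test_out_of_range_codes_coerce_to_missing(self):
        assert binarize_modis(ModisObservation("x", -5.0, 250.0)) is BinaryOutcome.MISSING
        assert binarize_modis(ModisObservation("x", 250.0, 0.0)) is BinaryOutcome.NO_SNOW

    def test_table_matches_scalar(self):
        rng = np.random.default_rng(0)
        raw = rng.choice([np.nan, 0.0, 5.0, 110.0, -3.0], size=(200, 2))
        frame = pd.DataFrame(
            {
                "image_id": [f"i{k}" for k in range(200)],
                "terra_fraction": raw[:, 0],
                "aqua_fraction": raw[:, 1],
            }
        )
        table = binarize_modis_table(frame)
        for row in frame.itertuples(index=False):
            t = None if np.isnan(row.terra_fraction) else row.terra_fraction
            a = None if np.isnan(row.aqua_fraction) else row.aqua_fraction
            assert table[row.image_id] == binarize_modis(
                ModisObservation(row.image_id, t, a)
            ).value


class TestValidate:
    def test_perfect_predictions(self):
        outcomes = outcome_series([BinaryOutcome.SNOW] * 5 + [BinaryOutcome.NO_SNOW] * 5)
        ref = pd.Series([True] * 5 + [False] * 5, index=outcomes.index)
        c = validate_binary(outcomes, ref)
        assert c.sensitivity == c.specificity == c.accuracy == 1.0

    def test_constructed_counts_match_reported_rates(self):
        # 766 detected / 234 missed snow, 971 correct / 29 phantom no-snow
        values = (
            [BinaryOutcome.SNOW] * 766
            + [BinaryOutcome.NO_SNOW] * 234
            + [BinaryOutcome.NO_SNOW] * 971
            + [BinaryOutcome.SNOW] * 29
        )
        ref = pd.Series([True] * 1000 + [False] * 1000)
        outcomes = outcome_series(values, ids=list(ref.index))
        c = validate_binary(outcomes, ref)
        assert round(100 * c.sensitivity, 1) == 76.6
        assert round(100 * c.specificity, 1) == 97.1
        assert c.total == 2000

    def test_missing_excluded_before_scoring(self):
        outcomes = outcome_series(
            [BinaryOutcome.SNOW, BinaryOutcome.MISSING, BinaryOutcome.NO_SNOW]
        )
        ref = pd.Series([True, True, False], index=outcomes.index)
        c = validate_binary(outcomes, ref)
        assert c.total == 2 and c.tp == 1 and c.tn == 1

    def test_all_missing_raises(self):
        outcomes = outcome_series([BinaryOutcome.MISSING] * 3)
        ref = pd.Series([True] * 3, index=outcomes.index)
        with pytest.raises(UndefinedMetricError):
            validate_binary(outcomes, ref)

    def test_sensitivity_tracks_miss_probability(self):
        # image-level miss probability m -> sensitivity ~ 1 - m
        from snowcam.synthetic import SimulationConfig, SiteConfig, simulate_modis_table

        from _utils import make_truth_frame

        m = 0.25
        cfg = SimulationConfig(
            modis_missing_prob=0.0,
            modis_miss_base=m,
            modis_miss_canopy_penalty=0.0,
            modis_miss_patchy=0.0,
        )
        n = 50_000
        frame = make_truth_frame(n, snow=True, patchiness=1.0)
        table = simulate_modis_table(frame, [SiteConfig(site_id="s0")], cfg, seed=13)
        outcomes = binarize_modis_table(table)
        ref = pd.Series(True, index=outcomes.index)
        c = validate_binary(outcomes, ref)
        sigma = np.sqrt(m * (1 - m) / n)
        assert abs(c.sensitivity - (1 - m)) <= 3 * sigma


class TestFusion:
    def test_or_rule_examples(self):
        assert combine_or(BinaryOutcome.NO_SNOW, True) is True
        assert combine_or(BinaryOutcome.SNOW, False) is True
        assert combine_or(BinaryOutcome.NO_SNOW, False) is False

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError):
            combine_or(BinaryOutcome.MISSING, True)

    def test_fusion_bounds_fuzz(self):
        # fused sensitivity >= both marginals, fused specificity <= both
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = 400
            truth = rng.random(n) < rng.uniform(0.2, 0.8)
            a = np.where(rng.random(n) < rng.uniform(0.5, 1.0), truth, ~truth)
            b = np.where(rng.random(n) < rng.uniform(0.5, 1.0), truth, ~truth)
            fused = a | b
            if truth.sum() == 0 or truth.sum() == n:
                continue
            ca = ConfusionCounts.from_labels(truth, a)
            cb = ConfusionCounts.from_labels(truth, b)
            cf = ConfusionCounts.from_labels(truth, fused)
            assert cf.tp >= max(ca.tp, cb.tp)  # same denominator: sens bound
            assert cf.tn <= min(ca.tn, cb.tn)  # same denominator: spec bound

    def test_table_fusion_drops_missing(self):
        outcomes = outcome_series(
            [BinaryOutcome.SNOW, BinaryOutcome.MISSING, BinaryOutcome.NO_SNOW]
        )
        pred = pd.Series([False, True, True], index=outcomes.index)
        fused = combine_or_table(outcomes, pred)
        assert list(fused.index) == ["i0", "i2"]
        assert fused.tolist() == [True, True]


class TestStratified:
    def test_single_stratum_equals_validate(self):
        outcomes = outcome_series([BinaryOutcome.SNOW, BinaryOutcome.NO_SNOW] * 10)
        ref = pd.Series([True, False] * 10, index=outcomes.index)
        strata = {i: "all" for i in outcomes.index}
        out = stratified_metrics(outcomes, ref, strata)
        assert out["all"] == validate_binary(outcomes, ref)

    def test_strata_counts_partition_total(self):
        rng = np.random.default_rng(5)
        n = 500
        outcomes = outcome_series(
            [BinaryOutcome.SNOW if v else BinaryOutcome.NO_SNOW for v in rng.random(n) < 0.3]
        )
        ref = pd.Series(rng.random(n) < 0.3, index=outcomes.index)
        strata = {i: ("a" if rng.random() < 0.5 else "b") for i in outcomes.index}
        out = stratified_metrics(outcomes, ref, strata)
        assert sum(c.total for c in out.values()) == n
        pooled = ConfusionCounts()
        for c in out.values():
            pooled = pooled + c
        assert pooled == validate_binary(outcomes, ref)

    def test_missing_stratum_rejected(self):
        outcomes = outcome_series([BinaryOutcome.SNOW, BinaryOutcome.SNOW])
        ref = pd.Series([True, True], index=outcomes.index)
        with pytest.raises(ValueError):
            stratified_metrics(outcomes, ref, {"i0": "a"})

    def test_generative_canopy_ordering_survives_the_chain(self, default_network):
        # ground-only snow under canopy is missed more than snow on foliage
        from snowcam.modis import binarize_modis_table

        net = default_network
        truth = net.truth.set_index("image_id")
        outcomes = binarize_modis_table(net.modis)
        snow_ids = truth.index[truth["snow"].to_numpy(dtype=bool)]
        trees = truth.loc[snow_ids, "snow_on_trees"]
        with_trees = trees[trees.notna()]
        strata = {
            i: ("on_trees" if bool(v) else "ground_only") for i, v in with_trees.items()
        }
        ids = list(strata)
        ref = pd.Series(True, index=pd.Index(ids))
        out = stratified_metrics(outcomes.loc[ids], ref, strata)
        assert out["ground_only"].sensitivity < out["on_trees"].sensitivity


class TestSeasonal:
    def test_day_below_min_images_is_missing(self):
        dates = pd.Series(
            ["2013-01-01"] * 4 + ["2013-02-01"] * 6,
            index=pd.Index([f"i{k}" for k in range(10)], name="image_id"),
        )
        outcomes = outcome_series([BinaryOutcome.SNOW] * 10, ids=list(dates.index))
        ref = pd.Series(True, index=dates.index)
        series = seasonal_sensitivity(outcomes, ref, dates, min_images=5)
        assert np.isnan(series.loc[1])  # only 4 snow images on Jan 1
        assert series.loc[32] == 1.0  # Feb 1 has 6

    def test_perfect_detector_is_one_everywhere_emitted(self, default_network):
        net = default_network
        ref = net.true_binary
        dates = net.records.set_index("image_id")["date"]
        outcomes = pd.Series(
            np.where(ref, BinaryOutcome.SNOW.value, BinaryOutcome.NO_SNOW.value),
            index=ref.index,
        )
        series = seasonal_sensitivity(outcomes, ref, dates)
        emitted = series.dropna()
        assert len(emitted) > 0 and (emitted == 1.0).all()

    def test_spring_decline_in_sensitivity(self, default_network):
        # patchy transition snow drives a spring drop relative to winter
        net = default_network
        outcomes = binarize_modis_table(net.modis)
        ref = net.true_binary
        dates = net.records.set_index("image_id")["date"]
        series = seasonal_sensitivity(outcomes, ref, dates)
        spring = series.loc[60:150].dropna()
        winter = pd.concat([series.loc[330:366], series.loc[1:59]]).dropna()
        assert len(spring) and len(winter)
        assert spring.mean() < winter.mean()


class TestSiteSummary:
    def test_perfect_site(self):
        ids = [f"i{k}" for k in range(10)]
        outcomes = outcome_series([BinaryOutcome.SNOW] * 10, ids=ids)
        ref = pd.Series(True, index=outcomes.index)
        records = pd.DataFrame({"image_id": ids, "site_id": "s1"})
        summary = site_sensitivity_summary(outcomes, ref, records)
        row = summary.iloc[0]
        assert row.fraction_snow_days == 1.0
        assert row.sensitivity == 1.0
        assert row.missed_snow_count == 0

    def test_missed_counts_sum_to_global_fn(self, default_network):
        net = default_network
        outcomes = binarize_modis_table(net.modis)
        ref = net.true_binary
        summary = site_sensitivity_summary(outcomes, ref, net.records)
        global_counts = validate_binary(outcomes, ref)
        assert summary["missed_snow_count"].sum() == global_counts.fn

    def test_zero_snow_site_has_missing_sensitivity(self):
        ids = ["a", "b"]
        outcomes = outcome_series([BinaryOutcome.NO_SNOW] * 2, ids=ids)
        ref = pd.Series(False, index=outcomes.index)
        records = pd.DataFrame({"image_id": ids, "site_id": "s"})
        summary = site_sensitivity_summary(outcomes, ref, records)
        assert np.isnan(summary.iloc[0].sensitivity)


class TestLogCurveFit:
    def test_noiseless_recovery_is_exact(self):
        x = np.linspace(0.05, 0.9, 40)
        y = 0.5 + 0.1 * np.log(x)
        a, b, r2 = fit_log_curve(x, y)
        assert a == pytest.approx(0.5, abs=1e-10)
        assert b == pytest.approx(0.1, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.02, 0.9, size=133)
        y = 0.5 + 0.12 * np.log(x) + rng.normal(0, 0.05, size=133)
        _, b, _ = fit_log_curve(x, y)
        assert abs(b - 0.12) <= 0.03

    def test_pure_noise_has_low_r_squared(self):
        rng = np.random.default_rng(4)
        low = 0
        for trial in range(20):
            x = rng.uniform(0.02, 0.9, size=133)
            y = 0.5 + rng.normal(0, 0.05, size=133)
            *_, r2 = fit_log_curve(x, y)
            low += r2 < 0.1
        assert low >= 19  # >= 95% of seeds

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_log_curve([0.5, 0.5, 0.5], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_log_curve([0.0, 0.5, 0.7], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_log_curve([0.5, 0.6], [1, 2])
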