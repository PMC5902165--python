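"""LOESS, curve features, seeding, self-training, model assignment."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess

from circamyo import curves as cv
from circamyo import simulate as sim

TIMES = np.arange(0.0, 49.0, 2.0)
DENSE = np.arange(0.0, 48.0 + 1e-9, 0.5)


def _features(y, span=0.3):
    sm_s = cv.loess_smooth(TIMES, y, span)
    sm_d = cv.loess_smooth(TIMES, y, span, xout=DENSE)
    return cv.extract_features(TIMES, y, sm_s, sm_d, DENSE), sm_d


class TestLoess:
    def test_reproduces_lines_and_constants(self):
        line = 0.1 * TIMES + 2
        assert np.allclose(cv.loess_smooth(TIMES, line, 0.3), line, atol=1e-9)
        const = np.full_like(TIMES, 3.0)
        assert np.allclose(cv.loess_smooth(TIMES, const, 0.3), const, atol=1e-12)

    def test_matches_statsmodels_lowess_at_sample_points(self, rng):
        y = np.cos(2 * np.pi * TIMES / 24) + rng.normal(0, 0.2, TIMES.size)
        for span in (0.3, 0.5):
            mine = cv.loess_smooth(TIMES, y, span)
            ref = lowess(y, TIMES, frac=span, it=0, return_sorted=False)
            assert np.allclose(mine, ref, atol=1e-10)

    def test_denoises_cosine(self, rng):
        truth = np.cos(2 * np.pi * TIMES / 24)
        S = cv.loess_matrix(TIMES, TIMES, 0.3)
        wins = 0
        for _ in range(200):
            y = truth + rng.normal(0, 0.2, TIMES.size)
            sm = S @ y
            wins += np.sqrt(np.mean((sm - truth) ** 2)) < np.sqrt(np.mean((y - truth) ** 2))
        assert wins >= 190

    def test_too_small_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            cv.loess_matrix(TIMES, TIMES, 0.05)


class TestExtractFeatures:
    def test_line_features(self):
        f, _ = _features(0.1 * TIMES + 1)
        assert f["resid_linear"] == pytest.approx(0.0, abs=1e-9)
        assert f["max_slope"] == pytest.approx(0.1, abs=1e-6)
        assert f["extremum1_t"] == 48.0 and f["extremum2_t"] == 48.0  # sentinels

    def test_cosine_features(self):
        f, _ = _features(np.cos(2 * np.pi * TIMES / 24))
        assert abs(f["period_est"] - 24.0) <= 0.5
        assert f["autocorr24"] > 0.95
        assert f["extremum1_t"] == pytest.approx(12.0, abs=1.0)
        assert f["extremum2_t"] == pytest.approx(24.0, abs=1.0)

    def test_noise_scatters_more_than_cosine(self, rng):
        # win rate of white noise over the pure cosine is ~0.87 under the
        # median-|difference|/range definition (5000-trial simulation); assert
        # three binomial SDs below that at n=200
        f_cos, _ = _features(np.cos(2 * np.pi * TIMES / 24))
        wins = 0
        for _ in range(200):
            f_noise, _ = _features(rng.normal(0, 1, TIMES.size))
            wins += f_noise["scattering"] > f_cos["scattering"]
        assert wins >= 160

    def test_zero_variance_curve_is_well_defined(self):
        f, _ = _features(np.full_like(TIMES, 5.0))
        assert f["scattering"] == 0.0 and f["autocorr24"] == 0.0
        assert f["resid_loess"] == 0.0 and f["resid_linear"] == 0.0

    def test_constant_shift_invariance(self, rng):
        """All ten measures are invariant to a constant log2 offset (the
        min/max ratio divides two values scaled by the same 2**c), while the
        linear-scale amplitude is not."""
        y = np.cos(2 * np.pi * TIMES / 24) + rng.normal(0, 0.1, TIMES.size)
        f0, sd0 = _features(y)
        f1, sd1 = _features(y + 3.0)
        for name in cv.FEATURE_NAMES:
            assert f1[name] == pytest.approx(f0[name], abs=1e-9), name
        assert cv.curve_amplitude(sd1) == pytest.approx(8 * cv.curve_amplitude(sd0))


class TestSeedsAndSelfTraining:
    def test_seed_classes_match_planted_archetypes(self, invitro_small, curveset_small):
        seeds = cv.seed_training_set(curveset_small)
        truth = invitro_small.truth["truth_archetype"]
        for cls in cv.CLASSES:
            genes = seeds.index[seeds == cls].get_level_values("gene_id")
            hits = (truth.loc[genes] == cls).sum()
            assert hits >= 10, f"{cls}: {hits}/11 seeds match truth"

    def test_duplicate_clock_gene_rejected(self, curveset_small):
        with pytest.raises(ValueError, match="duplicate"):
            cv.seed_training_set(curveset_small, ("ARNTL",) * 11)

    def test_missing_clock_gene_reported(self, curveset_small):
        bad = ("NOT_A_GENE",) + cv.CLOCK_GENES[1:]
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            cv.seed_training_set(curveset_small, bad)

    def test_self_training_is_deterministic(self, curveset_small):
        seeds = cv.seed_training_set(curveset_small)
        rf1, lab1, hist1 = cv.self_train(
            curveset_small.features, seeds, target_per_class=60, rng_seed=5
        )
        rf2, lab2, hist2 = cv.self_train(
            curveset_small.features, seeds, target_per_class=60, rng_seed=5
        )
        pd.testing.assert_series_equal(lab1, lab2)
        c1 = cv.classify_curves(rf1, curveset_small.features)
        c2 = cv.classify_curves(rf2, curveset_small.features)
        pd.testing.assert_frame_equal(c1, c2)

    def test_seed_only_set_returns_after_one_pass(self, curveset_small):
        seeds = cv.seed_training_set(curveset_small)
        feats = curveset_small.features.loc[seeds.index]
        rf, labels, hist = cv.self_train(feats, seeds, target_per_class=500)
        assert len(labels) == len(seeds)
        assert len(hist) == 1


class TestCalls:
    def test_call_thresholds(self):
        classes = list(cv.CLASSES)
        assert cv.call_category([0.6, 0.2, 0.1, 0.1], classes) == "circadian"
        assert cv.call_category([0.4, 0.3, 0.2, 0.1], classes) == cv.UNCLASSIFIED
        assert cv.call_category([0.5, 0.5, 0.0, 0.0], classes) == cv.UNCLASSIFIED

    def test_model_mask_mapping(self):
        assert cv.MODEL_FOR_MASK[(1, 1, 1, 1)] == 1
        assert cv.MODEL_FOR_MASK[(1, 1, 1, 0)] == 2
        assert cv.MODEL_FOR_MASK[(1, 1, 0, 1)] == 3
        assert cv.MODEL_FOR_MASK[(1, 1, 0, 0)] == 4
        assert cv.MODEL_FOR_MASK[(0, 0, 0, 0)] == 16
        assert sorted(cv.MODEL_FOR_MASK.values()) == list(range(1, 17))

    def test_assign_models_partition(self):
        idx = pd.MultiIndex.from_product(
            [["gA", "gB", "gC"], ["d1", "d2"], ["siControl", "siCLOCK"]],
            names=["gene_id", "donor_id", "condition"],
        )
        cat = pd.Series("cloud", index=idx)
        cat.loc[("gA",)] = "circadian"
        cat.loc[("gB", slice(None), "siControl")] = "circadian"
        calls = pd.DataFrame({"category": cat})
        models = cv.assign_models(calls)
        assert models.loc["gA", "model"] == 1
        assert models.loc["gB", "model"] == 4
        assert models.loc["gC", "model"] == 16
        assert models["model"].between(1, 16).all()

    def test_missing_condition_curve_rejected(self):
        idx = pd.MultiIndex.from_tuples(
            [("g", "d1", "siControl"), ("g", "d2", "siControl"), ("g", "d1", "siCLOCK")],
            names=["gene_id", "donor_id", "condition"],
        )
        with pytest.raises(ValueError, match="missing condition-curve"):
            cv.assign_models(pd.DataFrame({"category": pd.Series("cloud", index=idx)}))


class TestAmplitudes:
    def test_constant_curve_has_zero_amplitude(self):
        assert cv.curve_amplitude(np.full(97, 2.5)) == 0.0

    def test_log2_range_one_to_three(self):
        y = np.where(np.arange(97) % 2 == 0, 3.0, 1.0)
        assert cv.curve_amplitude(y) == pytest.approx(6.0)

    def test_damped_cosine_matches_envelope(self):
        t = DENSE
        log2c = 4 + 0.75 * np.exp(-t / 36) * np.cos(2 * np.pi * t / 24)
        # analytic peak-to-trough from the envelope at the first peak/trough
        peak = 2 ** (4 + 0.75 * np.exp(-0 / 36.0))
        trough = 2 ** (4 - 0.75 * np.exp(-12 / 36.0))
        assert cv.curve_amplitude(log2c) == pytest.approx(peak - trough, rel=0.10)

    def test_compare_amplitudes_identical(self):
        amp = pd.Series([1.0, 2.0, 3.0, 4.0])
        res = cv.compare_amplitudes(amp, amp.copy())
        assert res.t_stat == 0.0 and res.p == 1.0 and res.mean_log10_diff == 0.0

    def test_compare_amplitudes_constant_ratio(self, rng):
        ctrl = pd.Series(rng.uniform(1, 10, 50))
        res = cv.compare_amplitudes(ctrl, 0.5 * ctrl)
        assert res.mean_log10_diff == pytest.approx(np.log10(0.5), abs=1e-12)
        assert res.p < 1e-12

    def test_compare_amplitudes_matches_textbook_formula(self, rng):
        ctrl = pd.Series(rng.uniform(0.5, 8, 30))
        kd = pd.Series(ctrl.to_numpy() * rng.uniform(0.2, 1.5, 30))
        res = cv.compare_amplitudes(ctrl, kd)
        d = np.log10(kd.to_numpy()) - np.log10(ctrl.to_numpy())
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t_stat == pytest.approx(t, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cv.compare_amplitudes(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))
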