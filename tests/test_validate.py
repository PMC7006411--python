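"""Performance measures against brute-force oracles; validation schemes."""

import numpy as np
import pandas as pd
import pytest

from dmtrank import glm, simulate, validate
from dmtrank.validate import (
    c_index,
    calibration,
    compute_measures,
    match_pairs,
    mse,
    predict_observed_therapy,
    run_kfold,
    run_leave_one_site_out,
    window_stratified_eval,
)


def brute_force_pairs(durations):
    out = []
    for i in range(len(durations)):
        for j in range(i + 1, len(durations)):
            a, b = durations[i], durations[j]
            tol = 0.5 if min(a, b) < 0.5 else 1.0
            if abs(a - b) <= tol:
                out.append((i, j))
    return out


def brute_force_c_index(pairs, scores, events):
    num = den = 0.0
    for i, j in pairs:
        if events[i] == events[j]:
            continue
        hi, lo = (i, j) if events[i] else (j, i)
        den += 1
        if scores[hi] > scores[lo]:
            num += 1
        elif scores[hi] == scores[lo]:
            num += 0.5
    return num / den


class TestCalibration:
    def test_equal_bins(self):
        rng = np.random.default_rng(0)
        table = calibration(rng.random(40), rng.random(40), n_bins=20)
        assert (table["n"] == 2).all()
        assert table["n"].sum() == 40

    def test_remainder_goes_to_leading_bins(self):
        rng = np.random.default_rng(0)
        table = calibration(rng.random(45), rng.random(45), n_bins=20)
        assert list(table["n"][:5]) == [3] * 5
        assert list(table["n"][5:]) == [2] * 15

    def test_bins_partition_sorted_predictions(self):
        rng = np.random.default_rng(1)
        preds = rng.random(200)
        table = calibration(preds, preds, n_bins=20)
        assert (table["pred_max"].iloc[:-1].to_numpy() <= table["pred_min"].iloc[1:].to_numpy()).all()

    def test_constant_predictions_tie_rule(self):
        # ties keep input order (stable sort); bins still partition
        obs = np.arange(40.0)
        table = calibration(np.ones(40), obs, n_bins=20)
        assert table["obs_mean"].iloc[0] == 0.5 and table["obs_mean"].iloc[-1] == 38.5

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            calibration(np.ones(5), np.ones(5), n_bins=20)

    def test_true_model_is_calibrated(self):
        cfg = simulate.SimConfig(n_patients=4000, n_sites=5, seed=8)
        cycles, _, truth = simulate.generate_registry(cfg)
        fit = truth.true_fit("relapse")
        frame = predict_observed_therapy(fit, cycles)
        # score with the realized site effects for in-sample calibration
        lppd, _ = glm.pointwise_log_lik(fit, cycles, zero_site=False)
        eta_fit = glm._linear_predictor(fit, cycles, None, None, zero_site=False)
        preds = np.exp(eta_fit).mean(axis=0)
        table = calibration(preds, cycles["n_relapses"].to_numpy(float))
        low = table[table["pred_mean"] < 1.0]
        assert (np.abs(low["pred_mean"] - low["obs_mean"]) < 0.25).all()


class TestMatchPairs:
    def test_rule_examples(self):
        pairs = match_pairs(np.array([0.3, 0.6]))
        assert pairs.tolist() == [[0, 1]]  # min < 0.5 y, diff 0.3 <= 0.5
        assert match_pairs(np.array([1.0, 2.5])).size == 0  # diff 1.5 > 1.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = rng.uniform(0.05, 6.0, 80)
            ours = set(map(tuple, match_pairs(t)))
            assert ours == set(brute_force_pairs(t))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            match_pairs(np.array([1.0, 0.0]))


class TestCIndex:
    def test_perfect_separation(self):
        pairs = np.array([[0, 1]])
        ci, n = c_index(pairs, np.array([0.9, 0.1]), np.array([True, False]))
        assert ci == 1.0 and n == 1

    def test_all_ties_give_half(self):
        pairs = np.array([[0, 1], [0, 2], [1, 2]])
        ci, _ = c_index(pairs, np.ones(3), np.array([True, False, True]))
        assert ci == 0.5

    def test_concordant_pairs_only_among_discordant_outcomes(self):
        pairs = np.array([[0, 1]])
        with pytest.raises(ValueError):
            c_index(pairs, np.array([0.1, 0.9]), np.array([True, True]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 50
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            events = rng.random(n) < 0.4
            durations = rng.uniform(0.1, 4.0, n)
            pairs = match_pairs(durations)
            if not (events[pairs[:, 0]] != events[pairs[:, 1]]).any():
                continue
            ours, _ = c_index(pairs, scores, events)
            ref = brute_force_c_index(pairs.tolist(), scores, events)
            assert ours == pytest.approx(ref, abs=1e-12)


class TestMse:
    def test_identity_and_constant(self):
        assert mse(np.ones(5), np.ones(5)) == 0.0
        assert mse(np.full(4, 0.5), np.array([0, 1, 0, 1.0])) == 0.25

    def test_matches_reference(self):
        rng = np.random.default_rng(5)
        p, o = rng.random(100), rng.random(100)
        assert mse(p, o) == pytest.approx(float(np.mean((p - o) ** 2)), abs=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.ones(3), np.ones(4))


class TestOrderInvariance:
    def test_measures_invariant_to_cycle_order(self):
        rng = np.random.default_rng(6)
        n = 60
        frame = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "duration": rng.uniform(0.2, 4.0, n),
                "pred": rng.random(n),
                "score": rng.random(n),
                "observed": rng.integers(0, 3, n).astype(float),
                "event": rng.random(n) < 0.5,
                "log_lik": -rng.random(n),
            }
        )
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, b = compute_measures(frame), compute_measures(shuffled)
        for k in ("mse", "nll", "c_index", "n_pairs"):
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestWindowStratification:
    def _frame(self, durations):
        n = len(durations)
        rng = np.random.default_rng(7)
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "duration": durations,
                "pred": rng.random(n),
                "score": rng.random(n),
                "observed": rng.integers(0, 2, n).astype(float),
                "event": rng.random(n) < 0.5,
                "log_lik": -rng.random(n),
            }
        )

    def test_right_closed_assignment(self):
        frame = self._frame(np.array([1.5, 1.6]))
        table = window_stratified_eval(frame)
        row = table[(table["window_lo"] == 0.5)].iloc[0]
        assert row["n_obs"] == 1  # duration 1.5 falls in (0.5, 1.5]

    def test_all_short_cycles_populate_first_window_only(self):
        frame = self._frame(np.full(10, 0.4))
        table = window_stratified_eval(frame)
        assert table["n_obs"].iloc[0] == 10
        assert (table["n_obs"].iloc[1:] == 0).all()

    def test_stratified_mse_aggregates_to_pooled(self):
        frame = self._frame(np.random.default_rng(8).uniform(0.1, 5.5, 120))
        table = window_stratified_eval(frame)
        pooled = (table["mse"] * table["n_obs"]).sum() / table["n_obs"].sum()
        assert pooled == pytest.approx(mse(frame["pred"], frame["observed"]), abs=1e-12)


def true_model_fitter(truth, response):
    """A 'fitter' returning the generator's true model, for scheme tests."""

    def fitter(spec, train):
        return truth.true_fit(response)

    return fitter


@pytest.fixture(scope="module")
def cohort_and_truth():
    cfg = simulate.SimConfig(n_patients=300, n_sites=6, site_sd=0.0, seed=9)
    cycles, _, truth = simulate.generate_registry(cfg)
    return cycles, truth


class TestKfold:
    def test_every_cycle_scored_once_per_repeat(self, cohort_and_truth):
        cycles, truth = cohort_and_truth
        spec = glm.ModelSpec("relapse", "predictive")
        report = run_kfold(
            spec, cycles, k=2, repeats=1, seed=0,
            fitter=true_model_fitter(truth, "relapse"),
        )
        assert report.out_of_sample["n_obs"] == len(cycles)
        assert report.in_sample["n_obs"] == len(cycles)

    def test_repeats_reproducible(self, cohort_and_truth):
        cycles, truth = cohort_and_truth
        spec = glm.ModelSpec("relapse", "predictive")
        kw = dict(k=3, repeats=3, seed=5, fitter=true_model_fitter(truth, "relapse"))
        r1 = run_kfold(spec, cycles, **kw)
        r2 = run_kfold(spec, cycles, **kw)
        pd.testing.assert_frame_equal(r1.per_repeat, r2.per_repeat)
        assert r1.se == r2.se

    def test_cohort_smaller_than_k(self, cohort_and_truth):
        cycles, truth = cohort_and_truth
        with pytest.raises(ValueError):
            run_kfold(glm.ModelSpec("relapse"), cycles.head(5), k=10)


class TestLeaveOneSiteOut:
    def test_site_counts_and_coverage(self):
        cfg = simulate.SimConfig(n_patients=200, n_sites=4, seed=10)
        cycles, _, truth = simulate.generate_registry(cfg)
        report = run_leave_one_site_out(
            glm.ModelSpec("relapse", "predictive"), cycles,
            fitter=true_model_fitter(truth, "relapse"),
        )
        assert len(report.per_site) == cycles["site_id"].nunique()
        assert report.out_of_sample["n_obs"] == len(cycles)

    def test_needs_three_sites(self):
        cfg = simulate.SimConfig(n_patients=50, n_sites=2, seed=10)
        cycles, _, _ = simulate.generate_registry(cfg)
        with pytest.raises(ValueError):
            run_leave_one_site_out(glm.ModelSpec("relapse"), cycles)


class TestSensitivityScan:
    def test_identity_variant_agrees_fully(self, small_registry):
        cycles, _, _ = small_registry
        spec = glm.ModelSpec("relapse", "non_personalized")
        table = validate.sensitivity_scan(
            cycles.head(300), spec, prior_scales=(1.0,), seed=0,
            mcmc=glm.MCMCConfig(chains=2, warmup=300, post=150, draws=300, seed=1),
        )
        assert table.loc[0, "variant"] == "prior_scale_x1"
        assert table.loc[0, "agreement"] == 1.0


class TestCalibrationByGroup:
    def test_per_dmt_stratification(self):
        rng = np.random.default_rng(12)
        preds = rng.random(120)
        obs = rng.random(120)
        groups = rng.choice(["DMF", "NA"], 120)
        table = validate.calibration(preds, obs, n_bins=10, groups=groups)
        assert set(table["group"]) == {"DMF", "NA"}
        for g in ("DMF", "NA"):
            sub = table[table["group"] == g]
            assert sub["n"].sum() == (groups == g).sum()
            assert sub["n"].max() - sub["n"].min() <= 1


class TestCompareNested:
    def test_table_covers_all_complexities(self, cohort_and_truth):
        cycles, truth = cohort_and_truth
        table = validate.compare_nested(
            cycles, responses=("relapse",), k=3, repeats=1, seed=0,
            fitter=true_model_fitter(truth, "relapse"),
        )
        assert set(table["complexity"]) == {
            "non_personalized", "prognostic", "predictive"
        }
        assert set(table["split"]) == {"out_of_sample", "in_sample"}
        assert (table["response"] == "relapse").all()


class TestSensitivitySubsample:
    def test_subsample_variant_reported(self, small_registry):
        cycles, _, _ = small_registry
        spec = glm.ModelSpec("relapse", "non_personalized")
        table = validate.sensitivity_scan(
            cycles, spec, prior_scales=(), subsample_fractions=(0.8,), seed=3,
            mcmc=glm.MCMCConfig(chains=2, warmup=300, post=150, draws=300, seed=4),
        )
        row = table.iloc[0]
        assert row["variant"] == "subsample_0.8"
        assert 0.0 <= row["agreement"] <= 1.0
        assert row["n"] == len(cycles)
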