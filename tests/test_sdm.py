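import numpy as np
import pandas as pd
import pytest

import diadrom as dd
from diadrom.sdm import QuadraticBasis, stratified_split, _apply_log, _fit_glm


class TestExplainedDeviance:
    @pytest.mark.parametrize("null, final, expected", [
        (100.0, 100.0, 0.0),
        (100.0, 0.0, 100.0),
        (100.0, 46.0, 54.0),
    ])
    def test_values(self, null, final, expected):
        assert dd.explained_deviance(null, final) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dd.explained_deviance(0.0, 0.0)
        with pytest.raises(ValueError):
            dd.explained_deviance(10.0, 11.0)


class TestKappa:
    def test_perfect_agreement(self):
        obs = np.array([True, True, False, False])
        assert dd.kappa(obs, obs) == pytest.approx(1.0)

    def test_hand_computed_confusion_table(self):
        # TP=40, TN=40, FP=10, FN=10 -> p_o=0.8, p_e=0.5, kappa=0.6
        obs = np.array([True] * 50 + [False] * 50)
        pred = np.array([True] * 40 + [False] * 10 + [True] * 10 + [False] * 40)
        assert dd.kappa(obs, pred) == pytest.approx(0.6)

    def test_chance_level_predictions(self):
        rng = np.random.default_rng(5)
        ks = []
        for _ in range(300):
            obs = rng.random(60) < 0.5
            pred = rng.random(60) < 0.5
            k = dd.kappa(obs, pred)
            if not np.isnan(k):
                ks.append(k)
        assert np.mean(ks) == pytest.approx(0.0, abs=0.02)

    def test_degenerate_margins_return_nan(self):
        obs = np.array([True, True])
        assert np.isnan(dd.kappa(obs, obs))  # p_e == 1

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        checked = 0
        while checked < 200:
            n = rng.integers(8, 40)
            obs = rng.random(n) < rng.uniform(0.2, 0.8)
            pred = rng.random(n) < rng.uniform(0.2, 0.8)
            if obs.all() or (~obs).all():
                continue
            ours = dd.kappa(obs, pred)
            theirs = cohen_kappa_score(obs, pred)
            if np.isnan(ours):
                continue
            assert ours == pytest.approx(theirs, abs=1e-12)
            checked += 1


def auc_pair_counting_oracle(obs, scores):
    """Exhaustive concordant-pair counting with ties counted half."""
    pos = scores[obs]
    neg = scores[~obs]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        obs = np.array([True, True, False, False])
        assert dd.auc(obs, np.array([0.9, 0.8, 0.3, 0.1])) == 1.0

    def test_all_scores_equal_is_half(self):
        obs = np.array([True, False, True, False])
        assert dd.auc(obs, np.full(4, 0.5)) == pytest.approx(0.5)

    def test_worked_example(self):
        # presences {0.9, 0.8}, absences {0.85, 0.1}: 3 of 4 pairs concordant
        obs = np.array([True, True, False, False])
        assert dd.auc(obs, np.array([0.9, 0.8, 0.85, 0.1])) == pytest.approx(
            auc_pair_counting_oracle(obs, np.array([0.9, 0.8, 0.85, 0.1]))
        )
        assert dd.auc(obs, np.array([0.9, 0.8, 0.85, 0.1])) == pytest.approx(0.75)

    def test_tie_counted_half(self):
        obs = np.array([True, False, False])
        assert dd.auc(obs, np.array([0.8, 0.8, 0.1])) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(6, 30))
            obs = np.zeros(n, dtype=bool)
            obs[: int(rng.integers(1, n))] = True
            rng.shuffle(obs)
            if obs.all() or (~obs).all():
                obs[0] = ~obs[0]
            scores = np.round(rng.random(n), 1)  # coarse grid provokes ties
            assert dd.auc(obs, scores) == pytest.approx(
                auc_pair_counting_oracle(obs, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dd.auc(np.array([True, True]), np.array([0.5, 0.6]))


class TestBestThreshold:
    def test_midpoint_between_classes(self):
        obs = np.array([True, False])
        assert dd.best_threshold(obs, np.array([0.9, 0.1])) == pytest.approx(0.5)

    def test_separated_scores_deterministic_tie_break(self):
        obs = np.array([True, True, False, False])
        t = dd.best_threshold(obs, np.array([0.9, 0.7, 0.3, 0.1]))
        # smallest kappa-maximizing candidate: midpoint of the gap
        assert t == pytest.approx(0.5)
        assert dd.kappa(obs, np.array([0.9, 0.7, 0.3, 0.1]) >= t) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dd.best_threshold(np.array([True, True]), np.array([0.4, 0.6]))


def dome_dataset(n=200, t_opt=18.0, seed=0, contamination=0.05):
    """Presence/absence generated from a symmetric dome in temperature,
    plus two pure-noise candidate predictors."""
    net = dd.make_network(n, seed=seed)
    clim = dd.make_climate(net, years=10, seed=seed)
    rule = dd.ThermalResponse(t_opt - 6.0, t_opt, t_opt + 6.0)
    pa = dd.make_virtual_distribution(
        net, clim, thermal_rule=rule, threshold=0.5,
        false_presence_rate=contamination, false_absence_rate=contamination,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    predictors = pd.DataFrame(
        {
            "summer_temperature": [clim.reference_mean(b, "summer") for b in net.ids],
            "noise_1": rng.normal(size=n),
            "noise_2": rng.normal(size=n),
        },
        index=pa.index,
    )
    return pa, predictors


class TestFitSDM:
    def test_dome_recovery_selects_temperature(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        assert "summer_temperature" in fit.predictors
        grid = np.arange(8.0, 26.0, 0.25)
        opt = fit.response_optimum("summer_temperature", grid)
        assert opt == pytest.approx(18.0, abs=1.0)

    def test_single_candidate_returned_regardless_of_aic(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors[["noise_1"]], seed=4,
                         log_transform=())
        assert fit.predictors == ["noise_1"]

    def test_perfectly_separable_validation_kappa(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.uniform(0, 1, 40), rng.uniform(3, 4, 40)])
        y = x > 2.0
        predictors = pd.DataFrame({"x": x})
        fit = dd.fit_sdm(y, predictors, seed=1, log_transform=())
        assert fit.validation_kappa == pytest.approx(1.0)
        assert fit.calibration_kappa == pytest.approx(1.0)

    def test_selected_model_minimizes_aic_over_all_subsets(self):
        """Exhaustiveness: no subset of up to three candidates beats the
        returned model's AIC (recomputed independently per subset)."""
        from itertools import combinations

        pa, predictors = dome_dataset(n=120, seed=3)
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=7, log_transform=())
        y = pa.to_numpy().astype(float)
        cal = stratified_split(y, 0.75, np.random.default_rng(7))
        x_all = _apply_log(predictors, ())
        for size in (1, 2, 3):
            for subset in combinations(predictors.columns, size):
                bases = {n: QuadraticBasis.fit(x_all.loc[cal, n].to_numpy()) for n in subset}
                design = np.column_stack(
                    [np.ones(int(cal.sum()))]
                    + [bases[n].transform(x_all.loc[cal, n].to_numpy()) for n in subset]
                )
                res = _fit_glm(y[cal], design)
                assert fit.aic <= res.aic + 1e-6

    def test_explained_deviance_consistency(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        assert 0.0 <= fit.explained_deviance <= 100.0
        assert fit.final_deviance <= fit.null_deviance

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            dd.fit_sdm(np.array([True, False]), pd.DataFrame({"x": [1.0, 2.0]}),
                       log_transform=())


class TestProjection:
    def test_identity_projection_reproduces_fit(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        proj = dd.project_sdm(fit, predictors)
        assert np.allclose(proj["p_suit"].to_numpy(), fit.predict(predictors))
        assert ((proj["p_suit"] >= 0) & (proj["p_suit"] <= 1)).all()

    def test_probability_drops_past_the_dome_optimum(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        base = predictors.median().to_frame().T
        at_opt = base.copy()
        at_opt["summer_temperature"] = 18.0
        shifted = base.copy()
        shifted["summer_temperature"] = 26.0
        p_opt = dd.project_sdm(fit, at_opt)["p_suit"].iloc[0]
        p_shift = dd.project_sdm(fit, shifted)["p_suit"].iloc[0]
        assert p_shift < p_opt

    def test_extrapolation_flagged(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        wild = predictors.head(1).copy()
        wild["summer_temperature"] = 99.0
        proj = dd.project_sdm(fit, wild)
        assert proj["extrapolated"].iloc[0]

    def test_empty_input(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        proj = dd.project_sdm(fit, predictors.head(0))
        assert len(proj) == 0

    def test_missing_fitted_term_rejected(self):
        pa, predictors = dome_dataset()
        fit = dd.fit_sdm(pa.to_numpy(), predictors, seed=4)
        with pytest.raises(KeyError):
            dd.project_sdm(fit, pd.DataFrame({"unrelated": [1.0]}))
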