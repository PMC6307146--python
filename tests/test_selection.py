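"""Elastic-net cascade, medication filter, logistic fingerprint, ROC/AUC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epifinger import (FingerprintModel, auc_mann_whitney, cascade_select,
                       elastic_net_select, evaluate_fingerprint,
                       fit_fingerprint, medication_filter)
from epifinger.selection import _path_fit


def _toy_logistic_data(rng, n=500, p=200, n_signal=1, shift=3.0,
                       event_rate=0.1):
    y = (rng.random(n) < event_rate).astype(float)
    x = rng.normal(size=(n, p))
    x[y == 1, :n_signal] += shift
    cols = [f"cg{i:04d}" for i in range(p)]
    return pd.DataFrame(x, columns=cols), pd.Series(y)


class TestElasticNet:
    def test_lambda_above_path_maximum_selects_nothing(self, rng):
        wide, y = _toy_logistic_data(rng, n=200, p=20)
        res = elastic_net_select(wide, y, lambda_strategy=10.0)
        assert res.selected == []

    def test_alpha_zero_rejected(self, rng):
        wide, y = _toy_logistic_data(rng, n=100, p=5)
        with pytest.raises(ValueError, match="ridge"):
            elastic_net_select(wide, y, alpha=0.0)

    def test_missing_predictors_rejected(self, rng):
        wide, y = _toy_logistic_data(rng, n=50, p=4)
        wide.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            elastic_net_select(wide, y)

    def test_strongly_separating_cpg_is_selected(self, rng):
        wide, y = _toy_logistic_data(rng, n=500, p=200, n_signal=1,
                                     shift=3.0)
        res = elastic_net_select(wide, y, seed=1)
        assert "cg0000" in res.selected

    def test_tiny_lambda_matches_unpenalized_logistic(self, rng):
        import statsmodels.api as sm

        wide, y = _toy_logistic_data(rng, n=500, p=3, n_signal=1, shift=1.0,
                                     event_rate=0.3)
        res = elastic_net_select(wide, y, lambda_strategy=1e-7)
        fit = sm.Logit(y.to_numpy(),
                       sm.add_constant(wide.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(
            [res.coefficients[c] for c in wide.columns],
            fit.params[1:], atol=1e-4)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-4)

    def test_path_solver_matches_sklearn_saga(self, rng):
        """Dual route: coordinate descent vs an independent solver."""
        import warnings

        from sklearn.linear_model import LogisticRegression

        n, p = 300, 40
        x = rng.normal(size=(n, p))
        y = (rng.random(n) < 1 / (1 + np.exp(-(x[:, 0] - 1)))).astype(float)
        x_std = (x - x.mean(0)) / x.std(0)
        for lam in (0.05, 0.01):
            for _, coef, b0 in _path_fit(x_std, y,
                                         np.geomspace(0.3, lam, 10), 0.5):
                pass
            clf = LogisticRegression(solver="saga", l1_ratio=0.5,
                                     C=1.0 / (n * lam), max_iter=100_000,
                                     tol=1e-10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(x_std, y)
            np.testing.assert_allclose(coef, clf.coef_[0], atol=1e-6)
            assert b0 == pytest.approx(clf.intercept_[0], abs=1e-6)

    def test_fewer_events_than_folds_reduces_folds(self, rng, caplog):
        wide, y = _toy_logistic_data(rng, n=200, p=5, event_rate=0.02)
        assert 2 <= y.sum() < 10
        res = elastic_net_select(wide, y, folds=10)
        assert res.folds == int(y.sum())


class TestCascade:
    def test_refinement_equal_discovery_is_a_subset(self, rng):
        wide, y = _toy_logistic_data(rng, n=300, p=30, n_signal=3,
                                     shift=2.0)
        final, s1, s2 = cascade_select(wide, y, wide, y,
                                       list(wide.columns), seed=3)
        assert set(s2.selected) <= set(s1.selected)
        assert final == s2.selected

    def test_all_noise_selects_nothing_or_aborts(self, rng):
        sizes = []
        for sb in range(5):
            r = np.random.default_rng(sb)
            wide, y = _toy_logistic_data(r, n=300, p=50, n_signal=0)
            wide2, y2 = _toy_logistic_data(r, n=300, p=50, n_signal=0)
            try:
                final, _, _ = cascade_select(wide, y, wide2, y2,
                                             list(wide.columns), seed=sb)
                sizes.append(len(final))
            except RuntimeError:
                sizes.append(0)
        assert np.median(sizes) == 0

    def test_invariant_to_cpg_column_order(self, rng):
        wide, y = _toy_logistic_data(rng, n=300, p=30, n_signal=3,
                                     shift=2.0)
        perm = list(reversed(wide.columns))
        a, *_ = cascade_select(wide, y, wide, y, list(wide.columns), seed=7)
        b, *_ = cascade_select(wide[perm], y, wide[perm], y,
                               list(wide.columns), seed=7)
        assert sorted(a) == sorted(b)

    def test_survivor_absent_from_a_cohort_rejected(self, rng):
        wide, y = _toy_logistic_data(rng, n=100, p=5)
        with pytest.raises(ValueError, match="absent"):
            cascade_select(wide, y, wide.iloc[:, :3], y,
                           list(wide.columns), seed=0)


def _med_usage(index, baseline, followup, classes):
    b = pd.DataFrame(0, index=index, columns=list(classes))
    f = pd.DataFrame(0, index=index, columns=list(classes))
    for cls, rows in baseline.items():
        b.loc[rows, cls] = 1
    for cls, rows in followup.items():
        f.loc[rows, cls] = 1
    return b, f


class TestMedicationFilter:
    def test_no_medication_change_is_a_vacuous_filter(self, rng):
        from epifinger.simulate import MEDICATION_CLASSES

        inds = [f"i{k}" for k in range(30)]
        wide = pd.DataFrame(rng.normal(size=(30, 4)), index=inds,
                            columns=list("abcd"))
        same = {cls: inds[:5] for cls in MEDICATION_CLASSES}
        b, f = _med_usage(inds, same, same, MEDICATION_CLASSES)
        retained, records = medication_filter(wide, b, f, list("abcd"))
        assert retained == list("abcd")
        assert records == []

    def test_absent_stop_level_tests_start_contrast_only(self, rng):
        from epifinger.simulate import MEDICATION_CLASSES

        inds = [f"i{k}" for k in range(60)]
        wide = pd.DataFrame(rng.normal(size=(60, 2)), index=inds,
                            columns=["a", "b"])
        b, f = _med_usage(inds, {}, {MEDICATION_CLASSES[0]: inds[:20]},
                          MEDICATION_CLASSES)
        retained, records = medication_filter(wide, b, f, ["a", "b"])
        assert all(r.contrasts_tested == ("started",) for r in records)
        assert len(records) == 2  # one varying class x two CpGs

    def test_flags_are_marginal_per_cpg(self, rng):
        """Removing one flagged CpG cannot change any other CpG's flag."""
        from epifinger.simulate import MEDICATION_CLASSES

        inds = [f"i{k}" for k in range(200)]
        starters = inds[:50]
        wide = pd.DataFrame(rng.normal(size=(200, 3)), index=inds,
                            columns=["a", "b", "c"])
        wide.loc[starters, "a"] += 5.0  # strongly medication-associated
        b, f = _med_usage(inds, {}, {MEDICATION_CLASSES[2]: starters},
                          MEDICATION_CLASSES)
        _, rec_all = medication_filter(wide, b, f, ["a", "b", "c"])
        _, rec_sub = medication_filter(wide, b, f, ["b", "c"])
        stats_all = {(r.cpg, r.medication_class): r.statistic
                     for r in rec_all if r.cpg != "a"}
        stats_sub = {(r.cpg, r.medication_class): r.statistic
                     for r in rec_sub}
        assert stats_all == pytest.approx(stats_sub)


class TestFingerprint:
    def test_perfectly_separating_cpg_gives_auc_one(self):
        inds = [f"i{k}" for k in range(20)]
        y = pd.Series([1] * 5 + [0] * 15, index=inds)
        wide = pd.DataFrame({"cg1": np.r_[np.ones(5), -np.ones(15)]},
                            index=inds)
        model = fit_fingerprint(wide, y, ["cg1"])
        roc = evaluate_fingerprint(model, wide, y)
        assert roc.auc == 1.0

    def test_weights_match_hand_rolled_irls(self, rng):
        """Newton/IRLS oracle on a 50 x 2 problem, 1e-6 agreement."""
        n = 50
        x = rng.normal(size=(n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + x[:, 0])))).astype(float)
        wide = pd.DataFrame(x, columns=["cg1", "cg2"])
        model = fit_fingerprint(wide, y, ["cg1", "cg2"])

        xd = np.column_stack([np.ones(n), x])
        beta = np.zeros(3)
        for _ in range(100):
            eta = xd @ beta
            mu = 1 / (1 + np.exp(-eta))
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            beta_new = np.linalg.solve(xd.T @ (w[:, None] * xd),
                                       xd.T @ (w * z))
            if np.abs(beta_new - beta).max() < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)
        assert model.weights["cg1"] == pytest.approx(beta[1], abs=1e-6)
        assert model.weights["cg2"] == pytest.approx(beta[2], abs=1e-6)

    def test_null_in_sample_auc_stays_modest(self):
        """Three noise CpGs on 1,000 individuals cannot overfit far."""
        aucs = []
        for sb in range(20):
            r = np.random.default_rng(100 + sb)
            y = (r.random(1000) < 0.05).astype(float)
            wide = pd.DataFrame(r.normal(size=(1000, 3)),
                                columns=["a", "b", "c"])
            model = fit_fingerprint(wide, y, ["a", "b", "c"])
            aucs.append(evaluate_fingerprint(model, wide, y).auc)
        assert np.median(aucs) < 0.65

    def test_empty_panel_rejected(self, rng):
        wide = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            fit_fingerprint(wide, pd.Series(np.ones(10)), [])


class TestRoc:
    def test_complete_separation(self):
        auc, _ = auc_mann_whitney([3, 4], [1, 2])
        assert auc == 1.0

    def test_half_concordant_pairs(self):
        # cases {2,1} vs controls {3,0}: 2 of 4 pairs concordant
        auc, _ = auc_mann_whitney([2, 1], [3, 0])
        assert auc == 0.5

    def test_auc_equals_exhaustive_pair_count(self, rng):
        scores = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(bool)
        auc, _ = auc_mann_whitney(scores[y], scores[~y])
        pairs = [(1.0 if c > d else 0.5 if c == d else 0.0)
                 for c in scores[y] for d in scores[~y]]
        assert auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_normal_approximation_p_close_to_permutation_p(self, rng):
        n, n1 = 500, 50
        scores = rng.normal(size=n)
        y = np.zeros(n, dtype=bool)
        y[rng.choice(n, n1, replace=False)] = True
        auc, p = auc_mann_whitney(scores[y], scores[~y])
        ranks = stats.rankdata(scores)
        n0 = n - n1
        obs = (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        perm_auc = np.empty(10_000)
        for b in range(10_000):
            idx = rng.choice(n, n1, replace=False)
            perm_auc[b] = (ranks[idx].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        perm_p = (perm_auc >= obs).mean()
        assert p == pytest.approx(perm_p, abs=0.02)

    def test_auc_invariant_to_monotone_transform(self, small_delta, rng):
        y = small_delta.outcome
        wide = small_delta.wide
        model = fit_fingerprint(wide, y, small_delta.cpgs[:3])
        base = evaluate_fingerprint(model, wide, y).auc
        warped = FingerprintModel(
            cpgs=model.cpgs, intercept=model.intercept * 3 + 1,
            weights={c: w * 3 for c, w in model.weights.items()})
        assert evaluate_fingerprint(warped, wide, y).auc == \
            pytest.approx(base, abs=1e-12)

    def test_single_class_cohort_rejected(self, rng):
        wide = pd.DataFrame({"a": rng.normal(size=10)})
        model = FingerprintModel(cpgs=["a"], intercept=0.0,
                                 weights={"a": 1.0})
        with pytest.raises(ValueError):
            evaluate_fingerprint(model, wide, pd.Series(np.zeros(10)))
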