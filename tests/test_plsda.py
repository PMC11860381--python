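"""PLS-DA core: NIPALS vs least-squares oracles, metrics, CV, nesting."""

import itertools

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

import nirseed as ns
from nirseed.plsda import (NestedSequence, _nipals, decision_threshold,
                           evaluate_counts, model_from_json, model_to_json)
from nirseed.preprocess import PreprocessPipeline
from nirseed.selection import venetian_blinds


def _two_class_data(rng, n1=15, n2=15, p=8, sep=3.0):
    X1 = rng.normal(0.0, 1.0, size=(n1, p))
    X1[:, 0] += sep
    X2 = rng.normal(0.0, 1.0, size=(n2, p))
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(n1), -np.ones(n2)])
    perm = rng.permutation(n1 + n2)
    return X[perm], y[perm]


class TestNipals:
    def test_full_rank_equals_least_squares(self, rng):
        # n > p full rank with all p latent variables: PLS == OLS
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        fit = _nipals(X, y, n_lv=10)
        design = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(fit.predict(X), design @ beta, atol=1e-8)

    def test_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        for k in (1, 3, 5):
            fit = _nipals(X, y, n_lv=k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(
                X, y.reshape(-1, 1))
            np.testing.assert_allclose(
                fit.predict(X), ref.predict(X).ravel(), atol=1e-6)

    def test_rank_one_with_proportional_response(self, rng):
        t = rng.normal(size=12)
        direction = rng.normal(size=6)
        X = np.outer(t, direction)
        y = 2.0 * t
        fit = _nipals(X, y, n_lv=1)
        np.testing.assert_allclose(fit.predict(X), y, atol=1e-10)

    def test_scores_pairwise_orthogonal(self, rng):
        X = rng.normal(size=(25, 15))
        y = rng.normal(size=25)
        fit = _nipals(X, y, n_lv=6)
        # reconstruct scores by sequential deflation
        Xd = X - fit.x_mean
        scores = []
        for k in range(6):
            t = Xd @ fit.x_weights[:, k]
            scores.append(t)
            Xd = Xd - np.outer(t, fit.x_loadings[:, k])
        G = np.array(scores) @ np.array(scores).T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_exceeding_rank_rejected_with_attained_count(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=5))
        with pytest.raises(ValueError, match="after 1"):
            _nipals(X, t, n_lv=3)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="both classes"):
            ns.fit_pls(X, np.ones(10), n_lv=2)


class TestDecisionThreshold:
    def test_symmetric_separated_classes_cross_at_zero(self, rng):
        p1 = rng.normal(1.0, 0.2, 200)
        p2 = rng.normal(-1.0, 0.2, 200)
        preds = np.concatenate([p1, p2])
        is1 = np.arange(400) < 200
        thr = decision_threshold(preds, is1)
        assert thr == pytest.approx(0.0, abs=0.05)

    def test_equal_sd_closed_form_is_mean_midpoint(self):
        # construct two samples with exactly equal sample sds
        base = np.array([-1.0, 0.0, 1.0])
        p1 = 0.3 + 0.1 * base
        p2 = -0.5 + 0.1 * base
        preds = np.concatenate([p1, p2])
        thr = decision_threshold(preds, np.arange(6) < 3)
        assert thr == pytest.approx((0.3 - 0.5) / 2, abs=1e-10)

    def test_unequal_sds_match_root_finding_oracle(self):
        rng = np.random.default_rng(0)
        p1 = rng.normal(-1.0, 0.1, 500)
        p2 = rng.normal(1.0, 0.4, 500)
        preds = np.concatenate([p1, p2])
        thr = decision_threshold(preds, np.arange(1000) < 500)
        m1, s1 = p1.mean(), p1.std(ddof=1)
        m2, s2 = p2.mean(), p2.std(ddof=1)
        f = lambda x: norm.pdf(x, m1, s1) - norm.pdf(x, m2, s2)  # noqa: E731
        oracle = brentq(f, m1, m2)
        assert thr == pytest.approx(oracle, abs=1e-9)

    def test_tiny_class_falls_back_to_midpoint(self):
        thr = decision_threshold(np.array([1.0, -1.0, -0.8]),
                                 np.array([True, False, False]))
        assert thr == pytest.approx((1.0 + (-0.9)) / 2)

    def test_fixed_zero_method(self, rng):
        preds, is1 = rng.normal(size=10), rng.normal(size=10) > 0
        is1[0], is1[1] = True, False
        assert decision_threshold(preds, is1, method="zero") == 0.0


class TestClassify:
    def test_separable_calibration_has_zero_errors(self, rng):
        X, y = _two_class_data(rng, sep=6.0)
        model = ns.fit_pls(X, y, n_lv=2, class1_name="A", class2_name="B")
        pred = ns.classify(model, X)
        np.testing.assert_array_equal(pred == "A", y > 0)

    def test_threshold_tie_goes_to_class1(self, rng):
        X, y = _two_class_data(rng, sep=6.0)
        model = ns.fit_pls(X, y, n_lv=2, class1_name="A", class2_name="B")
        # craft an exact tie: move the threshold onto a prediction
        x = X[:1]
        model.threshold = float(model.predict_response(x)[0])
        assert ns.classify(model, x)[0] == "A"

    def test_random_labels_near_chance(self, rng):
        errs = []
        for _ in range(20):
            X = rng.normal(size=(40, 10))
            y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
            if np.unique(y).size < 2:
                continue
            model = ns.fit_pls(X, y, n_lv=1)
            pred = ns.classify(model, rng.normal(size=(40, 10)))
            errs.append(np.mean((pred == "class1") != (rng.random(40) < 0.5)))
        assert 0.35 < np.mean(errs) < 0.65


class TestEvaluate:
    def test_printed_consistency_example(self):
        # sensitivity 1.00 and specificity 0.962 give a 1.9% class error
        rep = evaluate_counts(tp=50, fn=0, fp=19, tn=481)
        assert rep.sensitivity == pytest.approx(1.0)
        assert rep.specificity == pytest.approx(0.962)
        assert rep.class_error == pytest.approx(0.019)
        assert rep.overall_accuracy == pytest.approx(0.981)

    def test_perfect_confusion(self):
        rep = evaluate_counts(tp=10, fn=0, fp=0, tn=10)
        assert rep.class_error == 0.0 and rep.overall_accuracy == 1.0

    def test_all_class1_on_balanced_truth(self):
        truth = np.array([True] * 10 + [False] * 10)
        pred = np.ones(20, dtype=bool)
        rep = ns.evaluate(truth, pred)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0
        assert rep.class_error == pytest.approx(0.5)

    def test_identity_against_rate_enumeration(self):
        # brute force over all confusion matrices with margins <= 20
        for n1, n2 in itertools.product(range(1, 21), range(1, 21)):
            for tp in range(0, n1 + 1, max(1, n1 // 3)):
                for tn in range(0, n2 + 1, max(1, n2 // 3)):
                    rep = evaluate_counts(tp, n1 - tp, n2 - tn, tn)
                    fnr = (n1 - tp) / n1
                    fpr = (n2 - tn) / n2
                    assert rep.class_error == pytest.approx((fnr + fpr) / 2)
                    assert rep.overall_accuracy == pytest.approx(
                        1.0 - rep.class_error)

    def test_symmetry_under_class_swap(self):
        rep = evaluate_counts(tp=7, fn=3, fp=2, tn=8)
        swapped = evaluate_counts(tp=8, fn=2, fp=3, tn=7)
        assert rep.class_error == pytest.approx(swapped.class_error)
        assert rep.sensitivity == pytest.approx(swapped.specificity)

    def test_label_input_with_positive_set(self):
        truth = np.array(["A", "A", "B", "C"])
        pred = np.array(["A", "B", "B", "C"])
        rep = ns.evaluate(truth, pred, positive=("A",))
        assert rep.confusion.tolist() == [[1, 1], [0, 2]]


class TestCrossValidation:
    def test_separable_data_gives_zero_cv_error(self, rng):
        X, y = _two_class_data(rng, n1=20, n2=20, sep=8.0)
        folds = venetian_blinds(40, 10, 1)
        rep = ns.cross_validate(X, y, folds, PreprocessPipeline(), n_lv=2)
        assert rep.class_error == 0.0
        assert rep.context == "cross-validation"

    def test_every_scan_predicted_once(self, rng):
        X, y = _two_class_data(rng, n1=17, n2=14, sep=2.0)
        folds = venetian_blinds(31, 10, 1)
        rep = ns.cross_validate(X, y, folds, PreprocessPipeline(), n_lv=2)
        assert int(rep.confusion.sum()) == 31

    def test_cv_error_not_below_calibration_on_average(self, rng):
        diffs = []
        for _ in range(20):
            X, y = _two_class_data(rng, n1=15, n2=15, p=10, sep=1.0)
            folds = venetian_blinds(30, 10, 1)
            cv = ns.cross_validate(X, y, folds, PreprocessPipeline(), 3)
            model = ns.fit_pls(X, y, 3)
            cal = ns.evaluate(y > 0, ns.classify(model, X) == "class1",
                              context="calibration")
            diffs.append(cv.class_error - cal.class_error)
        assert np.mean(diffs) >= 0.0


class TestSelectLV:
    def test_max_lv_one_returns_one(self, rng):
        X, y = _two_class_data(rng)
        folds = venetian_blinds(30, 10, 1)
        n_lv, errors = ns.select_lv(X, y, folds, PreprocessPipeline(),
                                    max_lv=1)
        assert n_lv == 1 and errors.shape == (1,)

    def test_low_dimensional_signal_needs_few_lvs(self, rng):
        # class signal spans 3 orthogonal directions
        n = 60
        basis = np.linalg.qr(rng.normal(size=(12, 3)))[0].T  # 3 x 12
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        coords = np.column_stack([y, y * 0.5, y * 0.25])
        X = coords @ basis * 3.0 + rng.normal(0, 0.3, size=(n, 12))
        folds = venetian_blinds(n, 10, 1)
        n_lv, errors = ns.select_lv(X, y, folds, PreprocessPipeline(),
                                    max_lv=8)
        assert n_lv <= 4
        assert errors[n_lv - 1] <= errors[-1]

    def test_chosen_error_never_above_max_lv_error(self, rng):
        X, y = _two_class_data(rng, sep=1.0)
        folds = venetian_blinds(30, 10, 1)
        n_lv, errors = ns.select_lv(X, y, folds, PreprocessPipeline(),
                                    max_lv=6)
        assert errors[n_lv - 1] <= errors[-1]
        assert errors[n_lv - 1] == errors.min()


def _three_class_data(rng, n_per=30, p=10):
    means = {"A": np.zeros(p), "B": np.zeros(p), "C": np.zeros(p)}
    means["A"][0] = 4.0
    means["B"][1] = 3.0
    means["C"][2] = 1.0
    X, labels = [], []
    for cls, mu in means.items():
        X.append(rng.normal(0, 1.0, size=(n_per, p)) + mu)
        labels += [cls] * n_per
    X = np.vstack(X)
    labels = np.array(labels)
    perm = rng.permutation(len(labels))
    return X[perm], labels[perm]


class TestNested:
    def test_two_classes_degenerate_to_single_binary(self, rng):
        X, y = _two_class_data(rng)
        labels = np.where(y > 0, "A", "B")
        folds = venetian_blinds(30, 10, 1)
        seq = ns.fit_nested(X, labels, ["A", "B"], folds,
                            PreprocessPipeline(), max_lv=3)
        assert len(seq.steps) == 1
        assert seq.steps[0].target == "A"
        assert seq.steps[0].pool == ("B",)

    def test_four_class_pools_shrink(self, benchmark):
        spectra, _, _ = benchmark
        s = ns.trim(spectra, 9000, 3952)
        sub = s.subset(np.arange(0, s.n_scans, 3))
        folds = venetian_blinds(sub.n_scans, 10, 1)
        seq = ns.fit_nested(sub.absorbance, sub.cultivars(),
                            ["Maxsyn", "Alto", "Bronsyn", "Trojan"], folds,
                            ns.cultivar_chain(), max_lv=4)
        assert [st.target for st in seq.steps] == ["Maxsyn", "Alto",
                                                   "Bronsyn"]
        assert [len(st.pool) for st in seq.steps] == [3, 2, 1]
        assert seq.elimination_order == ("Maxsyn", "Alto", "Bronsyn",
                                         "Trojan")

    def test_order_must_be_permutation(self, rng):
        X, labels = _three_class_data(rng, n_per=12)
        folds = venetian_blinds(len(labels), 10, 1)
        with pytest.raises(ValueError, match="permutation"):
            ns.fit_nested(X, labels, ["A", "B"], folds, PreprocessPipeline())

    def test_greedy_auto_order_matches_enumeration(self, rng):
        X, labels = _three_class_data(rng, n_per=20)
        folds = venetian_blinds(len(labels), 10, 1)
        auto = ns.fit_nested(X, labels, None, folds, PreprocessPipeline(),
                             max_lv=3)
        # enumeration oracle: CV error of each candidate first target
        best = None
        for cand in ["A", "B", "C"]:
            y = np.where(labels == cand, 1.0, -1.0)
            _, errors = ns.select_lv(X, y, folds, PreprocessPipeline(),
                                     max_lv=3)
            score = errors.min()
            if best is None or score < best[0]:
                best = (score, cand)
        assert auto.elimination_order[0] == best[1]

    def test_target_absent_from_later_pools_enforced(self, rng):
        X, labels = _three_class_data(rng, n_per=15)
        folds = venetian_blinds(len(labels), 10, 1)
        seq = ns.fit_nested(X, labels, ["A", "B", "C"], folds,
                            PreprocessPipeline(), max_lv=2)
        with pytest.raises(ValueError, match="reappears"):
            NestedSequence(steps=[seq.steps[0], seq.steps[0]],
                           elimination_order=("A", "A"))


class TestSerialization:
    def test_model_json_round_trip(self, rng):
        X, y = _two_class_data(rng, p=30)
        pipe = ns.endophyte_chain()
        Xp = pipe.fit_transform(np.abs(X) + 0.5)
        model = ns.fit_pls(Xp, y, n_lv=2, class1_name="E+",
                           class2_name="E-", pipeline=pipe)
        back = model_from_json(model_to_json(model))
        Xnew = np.abs(rng.normal(size=(4, X.shape[1]))) + 0.5
        np.testing.assert_allclose(
            back.predict_response(Xnew, preprocessed=False),
            model.predict_response(Xnew, preprocessed=False), atol=1e-10)
        assert back.threshold == model.threshold
        assert back.class_map == model.class_map
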