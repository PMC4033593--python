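import numpy as np
import pytest
from scipy.stats import norm
from sklearn.svm import SVC

import oracles
from cprrhythm import synthetic as syn
from cprrhythm.classifier import (
    NSH,
    SH,
    Diagnosis,
    LEAThresholds,
    SVMModel,
    Standardizer,
    TrainConfig,
    classify_segment,
    classify_window,
    lea_detect,
    svm_decide,
    svm_train,
)
from cprrhythm.features import WindowFeatures


def feats(p_lea=1.0, l_min=1.0, bS=0.1, nP=5, p_fib=0.5, p_h=0.1):
    return WindowFeatures(p_lea=p_lea, l_min=l_min, bS=bS, nP=nP, p_fib=p_fib, p_h=p_h)


class TestLEADetector:
    @pytest.mark.parametrize(
        "p_lea, l_min, expected",
        [
            (0.30, 1.00, True),  # energy below threshold
            (0.50, 0.62, True),  # curve length below threshold
            (0.50, 0.70, False),  # neither condition holds
            (0.44, 0.63, False),  # inequalities are strict at the boundary
        ],
    )
    def test_threshold_logic(self, p_lea, l_min, expected):
        th = LEAThresholds()
        assert lea_detect(feats(p_lea=p_lea, l_min=l_min), th) is expected

    def test_monotonicity(self, rng):
        th = LEAThresholds()
        for _ in range(200):
            p, l = rng.uniform(0, 1), rng.uniform(0.5, 1.5)
            if lea_detect(feats(p_lea=p, l_min=l), th):
                # decreasing either feature can never undo a detection
                assert lea_detect(feats(p_lea=p * 0.5, l_min=l), th)
                assert lea_detect(feats(p_lea=p, l_min=l * 0.9), th)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            LEAThresholds(p_lea_max=-1.0)


class TestStandardizer:
    def test_two_point_contract(self):
        st = Standardizer.fit(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(st.transform(np.array([[1.0], [3.0]])), [[-1.0], [1.0]])

    def test_training_mean_maps_to_zero(self, rng):
        X = rng.standard_normal((50, 4))
        st = Standardizer.fit(X)
        np.testing.assert_allclose(st.transform(X.mean(axis=0)[None, :]), 0.0, atol=1e-12)

    def test_round_trip(self, rng):
        X = rng.standard_normal((30, 4)) * 5 + 2
        st = Standardizer.fit(X)
        np.testing.assert_allclose(st.inverse_transform(st.transform(X)), X, atol=1e-10)

    def test_zero_variance_names_feature(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="nP"):
            Standardizer.fit(X, feature_names=("bS", "nP"))


def toy_model(svs, weights, bias=0.0, gamma=1.0):
    return SVMModel(
        support_vectors=np.asarray(svs, dtype=float),
        dual_weights=np.asarray(weights, dtype=float),
        bias=bias,
        gamma=gamma,
        C=1.0,
        standardizer=Standardizer(mean=np.zeros(len(svs[0])), sd=np.ones(len(svs[0]))),
    )


class TestSVMDecide:
    def test_single_support_vector_at_query(self):
        m = toy_model([[0.1, 0.2, 0.3, 0.4]], [1.0])
        d = svm_decide(m, np.array([0.1, 0.2, 0.3, 0.4]))
        assert d.decision == SH and d.stage == "SVM"
        assert d.discriminant == pytest.approx(1.0)

    def test_boundary_is_no_shock(self):
        # two symmetric SVs with opposite weights cancel at the midpoint
        m = toy_model([[1.0, 0, 0, 0], [-1.0, 0, 0, 0]], [0.7, -0.7])
        d = svm_decide(m, np.zeros(4))
        assert d.discriminant == pytest.approx(0.0, abs=1e-15)
        assert d.decision == NSH

    def test_dimension_mismatch(self):
        m = toy_model([[0.0, 0.0, 0.0, 0.0]], [1.0])
        with pytest.raises(ValueError):
            svm_decide(m, np.zeros(3))

    def test_agrees_with_naive_double_loop(self, rng):
        for _ in range(20):
            ns = rng.integers(1, 30)
            svs = rng.standard_normal((ns, 4))
            w = rng.standard_normal(ns)
            b = float(rng.standard_normal())
            gamma = float(10 ** rng.uniform(-2, 1))
            m = toy_model(svs, w, bias=b, gamma=gamma)
            x = rng.standard_normal(4)
            expected = oracles.svm_discriminant_loop(svs, w, b, gamma, x)
            assert m.decision_value(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_decision_function(self, rng):
        """Dual route: the frozen-model evaluation must reproduce sklearn."""
        X = rng.standard_normal((80, 4))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(80) > 0, 1, -1)
        clf = SVC(kernel="rbf", C=2.0, gamma=0.3).fit(X, y)
        m = toy_model(clf.support_vectors_, clf.dual_coef_.ravel(),
                      bias=float(clf.intercept_[0]), gamma=0.3)
        for x in rng.standard_normal((10, 4)):
            assert m.decision_value(x) == pytest.approx(
                float(clf.decision_function(x[None, :])[0]), abs=1e-10
            )


SMALL_GRID = TrainConfig(c_grid=(0.5, 2.0, 8.0), gamma_grid=(0.05, 0.2, 0.8), seed=1)


class TestSVMTrain:
    def test_separable_blobs(self, rng):
        X = np.vstack([rng.standard_normal((100, 4)) + 10, rng.standard_normal((100, 4)) - 10])
        y = np.array([1] * 100 + [-1] * 100)
        model, report = svm_train(X, y, SMALL_GRID)
        assert report.best_ber < 0.01
        assert report.best_c in SMALL_GRID.c_grid
        assert report.best_gamma in SMALL_GRID.gamma_grid

    def test_single_class_error(self, rng):
        X = rng.standard_normal((20, 4))
        with pytest.raises(ValueError):
            svm_train(X, np.ones(20, dtype=int), SMALL_GRID)

    def test_recovers_known_bayes_error(self):
        """Two spherical Gaussians whose analytic Bayes error is 10%."""
        rng = np.random.default_rng(2024)
        delta = 2 * norm.ppf(0.90)  # mean separation for 0.10 Bayes error
        n = 1000
        X = np.vstack(
            [rng.standard_normal((n, 4)),
             rng.standard_normal((n, 4)) + np.array([delta, 0, 0, 0])]
        )
        y = np.array([-1] * n + [1] * n)
        cfg = TrainConfig(c_grid=(1.0, 8.0), gamma_grid=(0.05, 0.25), seed=3)
        _, report = svm_train(X, y, cfg)
        assert abs(report.best_ber - 0.10) <= 0.03


@pytest.fixture(scope="module")
def dummy_model():
    # any valid SVM; the LEA-stage tests never reach it
    return toy_model([[0.0, 0.0, 0.0, 0.0]], [1.0], bias=0.5)


class TestWindowAndSegmentDecisions:

    def test_asystole_window_caught_by_lea(self, dummy_model):
        asy = syn.gen_rhythm(syn.RhythmSpec(kind="ASY", amplitude=0.05, duration=3.0, seed=1))
        d = classify_window(asy.samples, LEAThresholds(), dummy_model)
        assert d.decision == NSH and d.stage == "LEA"

    def test_coarse_vf_reaches_svm(self, dummy_model):
        vf = syn.gen_rhythm(syn.RhythmSpec(kind="VF", amplitude=1.0, rate=5.0,
                                           duration=3.0, seed=2))
        d = classify_window(vf.samples, LEAThresholds(), dummy_model)
        assert d.stage == "SVM"

    def test_zero_window_is_lea(self, dummy_model):
        d = classify_window(np.zeros(750), LEAThresholds(), dummy_model)
        assert d.decision == NSH and d.stage == "LEA"

    def test_svm_never_called_for_lea_windows(self, dummy_model, monkeypatch):
        calls = []
        orig = SVMModel.decision_value

        def spy(self, x):
            calls.append(1)
            return orig(self, x)

        monkeypatch.setattr(SVMModel, "decision_value", spy)
        asy = syn.gen_rhythm(syn.RhythmSpec(kind="ASY", amplitude=0.05, duration=3.0, seed=1))
        classify_window(asy.samples, LEAThresholds(), dummy_model)
        assert calls == []
        vf = syn.gen_rhythm(syn.RhythmSpec(kind="VF", amplitude=1.0, rate=5.0,
                                           duration=3.0, seed=2))
        classify_window(vf.samples, LEAThresholds(), dummy_model)
        assert calls == [1]

    @pytest.mark.parametrize(
        "votes, expected",
        [
            ((SH, SH, SH), SH),
            ((SH, SH, NSH), SH),
            ((SH, NSH, SH), SH),
            ((NSH, SH, SH), SH),
            ((SH, NSH, NSH), NSH),
            ((NSH, SH, NSH), NSH),
            ((NSH, NSH, SH), NSH),
            ((NSH, NSH, NSH), NSH),
        ],
    )
    def test_majority_truth_table(self, votes, expected):
        diags = [Diagnosis(decision=v, stage="SVM" if v == SH else "LEA") for v in votes]
        assert classify_segment(diags) == expected

    def test_segment_requires_three_windows(self):
        with pytest.raises(ValueError):
            classify_segment([Diagnosis(decision=NSH, stage="LEA")] * 2)

    def test_lea_stage_cannot_advise_shock(self):
        with pytest.raises(ValueError):
            Diagnosis(decision=SH, stage="LEA")


class TestEndToEndRecovery:
    """Trained on half of a balanced synthetic corpus, the algorithm must
    recover high segment-level sensitivity and specificity on the other half
    while the LEA calibration keeps shockable losses within its constraint."""

    def test_lea_constraint_on_training_input(self, corpus_tables, trained_saa):
        train, _ = corpus_tables
        saa, _ = trained_saa
        sh = train[train.shockable]
        lost = ((sh.p_lea < saa.lea.p_lea_max) | (sh.l_min < saa.lea.l_min_max)).mean()
        assert lost <= 0.05

    def test_holdout_sensitivity_specificity(self, corpus_tables, trained_saa):
        from cprrhythm.evaluation import evaluate_table

        _, test = corpus_tables
        saa, _ = trained_saa
        report = evaluate_table(test, saa)
        assert report.segment_se >= 0.90
        assert report.segment_sp >= 0.90

    def test_grid_membership_of_selected_point(self, trained_saa):
        saa, report = trained_saa
        assert report.best_c in report.c_grid
        assert report.best_gamma in report.gamma_grid
        assert saa.svm.n_support >= 1


class TestSerialization:
    def test_model_round_trip(self, tmp_path, trained_saa, rng):
        from cprrhythm.classifier import ShockAdviceModel

        saa, _ = trained_saa
        path = tmp_path / "model.json"
        saa.save(path)
        back = ShockAdviceModel.load(path)
        assert back.lea.p_lea_max == saa.lea.p_lea_max
        assert back.lea.l_min_max == saa.lea.l_min_max
        x = rng.standard_normal(4)
        assert back.svm.decision_value(x) == pytest.approx(saa.svm.decision_value(x), abs=1e-12)
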