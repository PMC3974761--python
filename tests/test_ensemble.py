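"""Incremental-ensemble training core: base learner contract, hyperparameter
search, cleaning/balancing, the boosting-style invariants, voting and Platt
calibration."""

import numpy as np
import pytest

from pzmap.ensemble import (
    EnsembleConfig,
    EnsembleModel,
    PlattCalibration,
    TrainingSet,
    WeakHypothesis,
    bootstrap_balance,
    clean_training_set,
    fit_platt,
    learnpp_increment,
    optimize_hyperparams,
    predict_probability,
    random_subspace_increment,
    remove_outliers_oneclass,
    split_batches,
    train_base_svm,
    vote,
)
from pzmap.evaluate import roc_auc_score_ranked
from pzmap.phantom import GaussianSetSpec, generate_gaussian_set

FAST = EnsembleConfig(
    T=3,
    inner_cv_folds=3,
    optimize_every="never",
    fixed_C=2.0,
    fixed_gamma=0.3,
    seed=0,
)


def _two_gaussians(n=200, seed=0, dim=2):
    return generate_gaussian_set(
        GaussianSetSpec(n_per_class=(n, n), dim=dim, seed=seed)
    )


class _StubModel:
    """Constant-decision stand-in obeying the decision_function contract."""

    def __init__(self, value):
        self.value = value

    def decision_function(self, X):
        return np.full(len(X), self.value, dtype=float)


def _stub_hyp(decision, beta, platt=None):
    h = WeakHypothesis(
        model=_StubModel(decision),
        C=1.0,
        gamma=1.0,
        subspace=np.array([0]),
        epsilon=beta / (1 + beta),
        beta=beta,
    )
    h.calibration = platt
    return h


class TestBaseSVM:
    def test_separable_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        h = train_base_svm(X, y, C=10.0, gamma=1.0)
        assert np.all(h.predict(X) == y)

    def test_label_flip_negates_decision(self):
        # symmetry of the soft-margin objective, up to solver tolerance
        ts = _two_gaussians(seed=1)
        h1 = train_base_svm(ts.X, ts.y, C=2.0, gamma=0.5)
        h2 = train_base_svm(ts.X, -ts.y, C=2.0, gamma=0.5)
        np.testing.assert_allclose(
            h1.decision(ts.X), -h2.decision(ts.X), atol=1e-2
        )

    def test_xor_with_oversmooth_kernel_underfits(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([-1, -1, 1, 1])
        h = train_base_svm(X, y, C=1.0, gamma=1e-4)
        # the RBF is too smooth to attain the unit functional margin on the
        # XOR pattern: every training point stays inside the margin
        assert np.all(np.abs(h.decision(X)) < 0.1)
        good = train_base_svm(X, y, C=10.0, gamma=1.0)
        assert np.all(np.abs(good.decision(X)) >= 0.9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_base_svm(np.zeros((3, 2)), np.ones(3), C=1.0, gamma=1.0)
        with pytest.raises(ValueError):
            train_base_svm(np.zeros((2, 2)), np.array([-1, 1]), C=-1.0, gamma=1.0)


class TestHyperparamSearch:
    def test_quadratic_surrogate_converges(self):
        # substitute an analytic objective with a unique maximum at
        # (log2 C, log2 gamma) = (2, -3)
        def bowl(C, gamma):
            return -((np.log2(C) - 2.0) ** 2 + (np.log2(gamma) + 3.0) ** 2)

        cfg = EnsembleConfig(nm_maxiter=300)
        C, g = optimize_hyperparams(
            _two_gaussians(), config=cfg, objective=bowl
        )
        assert abs(np.log2(C) - 2.0) < 1e-3
        assert abs(np.log2(g) + 3.0) < 1e-3

    def test_plateau_returns_grid_point(self):
        with pytest.warns(UserWarning):
            C, g = optimize_hyperparams(
                _two_gaussians(), objective=lambda C, g: 0.7
            )
        assert C > 0 and g > 0

    def test_deterministic_under_seed(self):
        ts = _two_gaussians(n=60, seed=2)
        cfg = EnsembleConfig(
            inner_cv_folds=3,
            grid_log2C=(-1, 3, 2),
            grid_log2gamma=(-4, 0, 2),
            nm_maxiter=10,
        )
        a = optimize_hyperparams(ts, config=cfg, seed=5)
        b = optimize_hyperparams(ts, config=cfg, seed=5)
        assert a == b


class TestCleaningAndBalancing:
    def test_outlier_removal_recovers_injected_points(self):
        rng = np.random.default_rng(0)
        core = rng.normal(size=(380, 2))
        outliers = rng.uniform(-12, 12, size=(20, 2))
        pts = np.vstack([core, outliers])
        kept = remove_outliers_oneclass(pts, nu=0.05, gamma=0.05)
        removed = set(range(400)) - set(kept)
        injected_removed = len([i for i in removed if i >= 380])
        # distance-to-centroid oracle: the injected box points are the
        # farthest; at matched nu most of them must go
        far = np.argsort(np.linalg.norm(pts, axis=1))[-20:]
        assert len(set(far) & set(range(380, 400))) >= 16
        assert injected_removed >= 16

    def test_small_nu_removes_almost_nothing(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 2))
        kept = remove_outliers_oneclass(pts, nu=0.01, gamma=0.1)
        assert len(kept) >= 195

    def test_nu_property_on_clean_gaussian(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(500, 2))
        kept = remove_outliers_oneclass(pts, nu=0.1)
        removed_frac = 1 - len(kept) / 500
        assert abs(removed_frac - 0.1) < 0.06

    def test_small_class_noop_with_warning(self):
        with pytest.warns(UserWarning):
            kept = remove_outliers_oneclass(np.zeros((5, 2)), nu=0.5)
        assert len(kept) == 5

    def test_clean_training_set_per_patient(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        y = np.where(rng.random(200) < 0.5, 1, -1)
        pid = np.repeat([0, 1], 100)
        out = clean_training_set(TrainingSet(X=X, y=y, patient_id=pid), nu=0.05)
        assert out.n <= 200
        assert set(np.unique(out.patient_id)) == {0, 1}

    def test_balance_fixed_point(self):
        ts = _two_gaussians(n=50, seed=4)
        out = bootstrap_balance(ts, seed=0)
        assert out.n == ts.n
        assert (out.y == 1).sum() == (out.y == -1).sum() == 50

    def test_balance_geometric_mean_rule(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(125, 2))
        y = np.concatenate([np.full(100, -1), np.full(25, 1)])
        out = bootstrap_balance(TrainingSet(X=X, y=y), seed=1)
        # sqrt(100 * 25) = 50 per class
        assert (out.y == 1).sum() == (out.y == -1).sum() == 50

    def test_balance_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(90, 2))
        y = np.concatenate([np.full(60, -1), np.full(30, 1)])
        a = bootstrap_balance(TrainingSet(X=X, y=y), seed=3)
        b = bootstrap_balance(TrainingSet(X=X, y=y), seed=3)
        assert a.X.tobytes() == b.X.tobytes()


class TestVoting:
    def test_single_hypothesis(self):
        h = _stub_hyp(+1.5, beta=0.2)
        labels, margin = vote([h], np.zeros((4, 1)))
        assert np.all(labels == 1)
        assert np.all(margin == 1.0)

    def test_equal_weights_tie_goes_negative(self):
        hs = [_stub_hyp(+1.0, beta=0.3), _stub_hyp(-1.0, beta=0.3)]
        labels, margin = vote(hs, np.zeros((3, 1)))
        assert np.all(labels == -1)
        assert np.allclose(margin, 0.0)

    def test_three_hypothesis_log_arithmetic(self):
        # weights: log(1/0.1) = 2.303 vs 2 * log(1/0.4) = 1.833 -> the
        # single strong hypothesis outvotes the agreeing pair
        hs = [
            _stub_hyp(+1.0, beta=0.1),
            _stub_hyp(-1.0, beta=0.4),
            _stub_hyp(-1.0, beta=0.4),
        ]
        assert 2 * np.log(1 / 0.4) < np.log(1 / 0.1)
        labels, _ = vote(hs, np.zeros((2, 1)))
        assert np.all(labels == 1)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            vote(EnsembleModel(), np.zeros((1, 1)))


class TestPlatt:
    def test_symmetric_data_zero_intercept(self):
        rng = np.random.default_rng(0)
        f = np.concatenate([rng.normal(1, 0.5, 500), rng.normal(-1, 0.5, 500)])
        y = np.concatenate([np.ones(500, int), -np.ones(500, int)])
        cal = fit_platt(f, y)
        assert cal.A < 0
        # the crossover point -B/A of the sigmoid sits at score ~ 0
        assert abs(cal.B / cal.A) < 0.05

    def test_confident_scores_give_confident_probs(self):
        f = np.concatenate([np.full(50, 5.0), np.full(50, -5.0)])
        y = np.concatenate([np.ones(50, int), -np.ones(50, int)])
        cal = fit_platt(f, y)
        assert np.all(cal.predict(np.array([5.0])) >= 0.9)

    def test_independent_labels_constant_base_rate(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=1000)
        y = np.where(rng.random(1000) < 0.3, 1, -1)
        cal = fit_platt(f, y)
        probs = cal.predict(f)
        base = (y == 1).mean()
        assert np.all(np.abs(probs - base) < 0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_platt(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_parameter_recovery_from_known_sigmoid(self):
        # scores through a known sigmoid (A, B) = (-2, 0.5); n = 2000
        rng = np.random.default_rng(42)
        f = rng.normal(0.0, 1.5, size=2000)
        p = 1.0 / (1.0 + np.exp(-2.0 * f + 0.5))
        y = np.where(rng.random(2000) < p, 1, -1)
        cal = fit_platt(f, y)
        assert abs(cal.A - (-2.0)) / 2.0 < 0.05
        assert abs(cal.B - 0.5) / 0.5 < 0.05


class TestPredictProbability:
    def test_equal_weight_average(self):
        # calibrations returning 0.8 and 0.6 with equal vote weights -> 0.7
        class FixedCal:
            def __init__(self, p):
                self.p = p

            def predict(self, f):
                return np.full(len(np.atleast_1d(f)), self.p)

        hs = [
            _stub_hyp(1.0, beta=0.1, platt=FixedCal(0.8)),
            _stub_hyp(1.0, beta=0.1, platt=FixedCal(0.6)),
        ]
        m = EnsembleModel(increments=[hs])
        np.testing.assert_allclose(
            predict_probability(m, np.zeros((3, 1))), 0.7
        )

    def test_consensus_probability_one(self):
        class FixedCal:
            def predict(self, f):
                return np.ones(len(np.atleast_1d(f)))

        hs = [_stub_hyp(1.0, beta=0.2, platt=FixedCal()) for _ in range(3)]
        m = EnsembleModel(increments=[hs])
        np.testing.assert_allclose(predict_probability(m, np.zeros((2, 1))), 1.0)

    def test_singleton_equals_platt_curve(self):
        ts = _two_gaussians(n=100, seed=7)
        h = train_base_svm(ts.X, ts.y, C=2.0, gamma=0.3)
        h.epsilon, h.beta = 0.1, 0.1 / 0.9
        h.calibration = fit_platt(h.decision(ts.X), ts.y)
        m = EnsembleModel(increments=[[h]])
        np.testing.assert_allclose(
            predict_probability(m, ts.X),
            h.calibration.predict(h.decision(ts.X)),
        )


class TestLearnppIncrement:
    @pytest.fixture(scope="class")
    def trained(self):
        ts = _two_gaussians(n=200, seed=10, dim=2)
        model = EnsembleModel()
        learnpp_increment(model, ts, config=FAST, seed=3)
        return model, ts

    def test_accepted_errors_below_half(self, trained):
        model, _ = trained
        assert model.history
        for rec in model.history:
            assert 0.0 <= rec["epsilon"] < 0.5
            assert 0.0 <= rec["E"] < 0.5

    def test_normalized_error_relations_exact(self, trained):
        model, _ = trained
        for rec in model.history:
            assert rec["beta"] == rec["epsilon"] / (1.0 - rec["epsilon"])
            assert rec["B"] == rec["E"] / (1.0 - rec["E"])
            assert 0.0 <= rec["beta"] < 1.0
            assert 0.0 <= rec["B"] < 1.0

    def test_ensemble_not_worse_than_first_weak(self, trained):
        model, _ = trained
        held = _two_gaussians(n=300, seed=11, dim=2)
        h0 = model.hypotheses[0]
        auc_first = roc_auc_score_ranked(h0.decision(held.X), held.y)
        auc_ens = roc_auc_score_ranked(
            predict_probability(model, held.X), held.y
        )
        assert auc_ens >= auc_first - 0.02

    def test_substitution_beta_for_quarter_error(self):
        # epsilon = 0.25 -> beta = 1/3 by the normalization rule
        assert np.isclose(0.25 / (1 - 0.25), 1 / 3)

    def test_single_class_batch_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            learnpp_increment(
                EnsembleModel(),
                TrainingSet(X=X, y=np.ones(10, int)),
                config=FAST,
            )

    def test_deterministic_under_seed(self):
        ts = _two_gaussians(n=120, seed=12)
        m1 = EnsembleModel()
        learnpp_increment(m1, ts, config=FAST, seed=9)
        m2 = EnsembleModel()
        learnpp_increment(m2, ts, config=FAST, seed=9)
        assert [r["epsilon"] for r in m1.history] == [
            r["epsilon"] for r in m2.history
        ]


class TestIncrementalLearning:
    def _clusters(self, seed, centers, labels, n=120, sd=0.7):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(c, sd, size=(n, 2)) for c in centers]
        )
        y = np.concatenate([np.full(n, l) for l in labels])
        return TrainingSet(X=X, y=y)

    def test_new_batch_learned_without_unlearning(self):
        """Two increments (clusters A,B then A,C) with no access to the
        first batch: accuracy on B must survive, accuracy on C must rise."""
        A, B, C = (0.0, 0.0), (5.0, -1.0), (6.0, 2.0)
        cfg = EnsembleConfig(T=3, inner_cv_folds=5, seed=0)
        s1 = self._clusters(10, [A, B], [-1, 1])
        s2 = self._clusters(20, [A, C], [-1, 1])
        testB = self._clusters(90, [B], [1], n=300)
        testC = self._clusters(91, [C], [1], n=300)
        m = EnsembleModel()
        learnpp_increment(m, s1, config=cfg, seed=100)
        accB1 = (vote(m, testB.X)[0] == 1).mean()
        learnpp_increment(m, s2, config=cfg, seed=200)
        accB2 = (vote(m, testB.X)[0] == 1).mean()
        accC2 = (vote(m, testC.X)[0] == 1).mean()
        assert accB2 >= accB1 - 0.10
        assert accC2 > 0.8


class TestRandomSubspace:
    def test_r_larger_than_f_rejected(self):
        ts = _two_gaussians(n=40, seed=13)
        with pytest.raises(ValueError):
            random_subspace_increment(
                EnsembleModel(), ts, r=10, config=FAST
            )

    def test_full_subspace_single_learner_matches_learnpp_draw(self):
        ts = _two_gaussians(n=100, seed=14)
        cfg = EnsembleConfig(
            T=1, optimize_every="never", fixed_C=2.0, fixed_gamma=0.3, seed=0
        )
        m_rs = EnsembleModel()
        random_subspace_increment(m_rs, ts, T=1, L=1, r=2, config=cfg, seed=21)
        m_lp = EnsembleModel()
        learnpp_increment(m_lp, ts, T=1, config=cfg, seed=21)
        # same seed stream -> same TR_t draw -> identical base predictions
        np.testing.assert_array_equal(
            m_rs.hypotheses[0].predict(ts.X), m_lp.hypotheses[0].predict(ts.X)
        )

    def test_mse_errors_recorded_below_half(self):
        ts = _two_gaussians(n=150, seed=15)
        m = EnsembleModel()
        random_subspace_increment(m, ts, T=2, L=3, r=1, config=FAST, seed=5)
        for rec in m.history:
            assert 0.0 <= rec["epsilon"] < 0.5

    def test_mse_closed_forms(self):
        # scores equal to {0,1} labels -> mse 0; constant 0.5 -> mse 0.25
        y01 = np.array([0.0, 1.0, 1.0, 0.0])
        assert np.mean((y01 - y01) ** 2) == 0.0
        assert np.mean((np.full(4, 0.5) - y01) ** 2) == 0.25


def test_split_batches_partition_and_determinism():
    ts = _two_gaussians(n=60, seed=16)
    parts = split_batches(ts, K=4, seed=2)
    assert sum(p.n for p in parts) == ts.n
    assert {p.n for p in parts} == {30}
    parts2 = split_batches(ts, K=4, seed=2)
    assert parts[0].X.tobytes() == parts2[0].X.tobytes()
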