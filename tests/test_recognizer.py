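"""Split protocol, centroids, one-class SVM and open-set metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gaitproto.gait_signal import StepDataset
from gaitproto.recognizer import (Centroid, Embedding, MetricsReport,
                                  OSVMModel, SplitSpec, compute_centroid,
                                  decision_value, evaluate, fit_osvm,
                                  rbf_kernel, recognize, recognize_batch,
                                  split_dataset)


@pytest.fixture(scope="module")
def study_dataset():
    """40 subjects x 158 short steps — split arithmetic only needs counts."""
    rng = np.random.default_rng(0)
    return StepDataset({a: rng.normal(size=(158, 4, 28)) for a in range(40)})


class TestSplit:
    def test_study_scale_counts(self, study_dataset):
        split = split_dataset(study_dataset, SplitSpec(seed=1), 0)
        assert sum(v.shape[0] for v in split.known_test.values()) == 1480
        assert sum(v.shape[0] for v in split.unknown_test.values()) == 1580
        assert sum(v.shape[0] for v in split.train.values()) == 3160
        assert sum(v.shape[0] for v in split.shots.values()) == 100

    def test_groups_disjoint_and_seeded(self, study_dataset):
        spec = SplitSpec(seed=1)
        s0 = split_dataset(study_dataset, spec, 0)
        s0b = split_dataset(study_dataset, spec, 0)
        s1 = split_dataset(study_dataset, spec, 1)
        groups = [set(s0.train), set(s0.shots), set(s0.unknown_test)]
        assert not (groups[0] & groups[1]) and not (groups[0] & groups[2])
        assert sorted(s0.train) == sorted(s0b.train)
        assert sorted(s0.train) != sorted(s1.train)  # re-partitioned

    def test_insufficient_subjects(self):
        tiny = StepDataset({a: np.zeros((20, 4, 28)) for a in range(5)})
        with pytest.raises(ValueError):
            split_dataset(tiny, SplitSpec(), 0)


class TestCentroid:
    def test_identical_embeddings(self, rng):
        v = rng.normal(size=128)
        c = compute_centroid(np.tile(v, (5, 1)), subject=3)
        np.testing.assert_allclose(c.vector, v, rtol=1e-14)
        assert c.subject == 3

    def test_antipodal_pair_gives_zero(self):
        v = np.zeros(128); v[0] = 1.0
        c = compute_centroid(np.stack([v, -v]))
        np.testing.assert_array_equal(c.vector, np.zeros(128))

    def test_matches_loop_mean(self, rng):
        V = rng.normal(size=(10, 128))
        oracle = sum(V[i] for i in range(10)) / 10
        np.testing.assert_allclose(compute_centroid(V).vector, oracle, atol=1e-12)

    def test_mixed_subjects_rejected(self, rng):
        embs = [Embedding(rng.normal(size=128), subject=0),
                Embedding(rng.normal(size=128), subject=1)]
        with pytest.raises(ValueError):
            compute_centroid(embs)


def unit_rows(rng, n, d=128):
    V = rng.normal(size=(n, d))
    return V / np.linalg.norm(V, axis=1, keepdims=True)


class TestOSVM:
    def test_single_shot_is_fully_constrained(self, rng):
        V = unit_rows(rng, 1)
        m = fit_osvm(V, gamma=2.2, nu=0.06)
        assert m.alphas.tolist() == [1.0]
        assert m.delta == pytest.approx(1.0)
        assert decision_value(m, V[0]) == pytest.approx(0.0, abs=1e-12)

    def test_constraints_satisfied(self, rng):
        for n, nu in [(10, 0.06), (10, 0.5), (5, 0.9)]:
            m = fit_osvm(unit_rows(rng, n), gamma=2.2, nu=nu)
            assert abs(m.alphas.sum() - 1.0) < 1e-8
            assert m.alphas.min() > -1e-8
            assert m.alphas.max() < m.box + 1e-8

    def test_objective_matches_dense_qp(self, rng):
        """Independent QP oracle at n=5 (scipy SLSQP on the dual)."""
        V = unit_rows(rng, 5)
        gamma, nu, n = 2.2, 0.06, 5
        m = fit_osvm(V, gamma, nu)
        K = rbf_kernel(V, V, gamma)
        box = 1.0 / (nu * n)
        res = minimize(
            lambda a: 0.5 * a @ K @ a, np.full(n, 1.0 / n),
            jac=lambda a: K @ a, bounds=[(0.0, box)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                          "jac": lambda a: np.ones(n)}],
            method="SLSQP", tol=1e-14,
        )
        assert abs(0.5 * m.alphas @ K @ m.alphas - res.fun) < 1e-6

    def test_margin_support_vectors_lie_on_boundary(self, rng):
        m = fit_osvm(unit_rows(rng, 10), gamma=2.2, nu=0.06)
        idx = m.margin_support_indices()
        assert len(idx) > 0
        for h in idx:
            assert abs(decision_value(m, m.support[h])) < 1e-6

    @pytest.mark.parametrize("gamma,nu", [(0.0, 0.06), (2.2, 0.0), (2.2, 1.5)])
    def test_invalid_hyperparameters(self, gamma, nu, rng):
        with pytest.raises(ValueError):
            fit_osvm(unit_rows(rng, 5), gamma, nu)

    def test_decision_matches_kernel_expansion(self, rng):
        m = fit_osvm(unit_rows(rng, 8), gamma=1.3, nu=0.2)
        v = unit_rows(rng, 1)[0]
        oracle = sum(
            m.alphas[i] * np.exp(-1.3 * np.sum((m.support[i] - v) ** 2))
            for i in range(8)
        ) - m.delta
        assert decision_value(m, v) == pytest.approx(oracle, abs=1e-12)

    def test_single_shot_closed_form(self):
        v = np.zeros(128); v[0] = 1.0
        m = fit_osvm(v[None], gamma=2.0, nu=0.1)
        far = np.zeros(128); far[1] = 1.0  # distance^2 = 2
        assert decision_value(m, far) == pytest.approx(np.exp(-2.0 * 2.0) - 1.0)


def one_shot_pipeline(shots: dict[int, np.ndarray], gamma=2.2, nu=0.06):
    centroids = [compute_centroid(v[None], a) for a, v in shots.items()]
    models = {a: fit_osvm(v[None], gamma, nu, subject=a) for a, v in shots.items()}
    return centroids, models


class TestRecognize:
    def test_exact_shot_is_accepted(self):
        e0 = np.zeros(128); e0[0] = 1.0
        e1 = np.zeros(128); e1[1] = 1.0
        centroids, models = one_shot_pipeline({0: e0, 1: e1})
        r = recognize(e0, centroids, models, tau=-0.1)
        assert r.provisional == 0 and r.accepted
        assert r.decision == pytest.approx(0.0, abs=1e-12)

    def test_far_query_is_rejected(self):
        e0 = np.zeros(128); e0[0] = 1.0
        centroids, models = one_shot_pipeline({0: e0})
        far = np.zeros(128); far[1] = -1.0
        r = recognize(far, centroids, models, tau=-0.1)
        assert not r.accepted  # kernel ~ exp(-2.2*2) << 1, h ~ -delta ~ -1

    def test_equidistant_tie_breaks_to_smaller_id(self):
        e0 = np.zeros(128); e0[0] = 1.0
        e1 = np.zeros(128); e1[1] = 1.0
        centroids, models = one_shot_pipeline({7: e0, 3: e1})
        q = (e0 + e1) / np.linalg.norm(e0 + e1)
        r = recognize(q, centroids, models, tau=-10.0)
        assert r.provisional == 3

    def test_empty_known_set(self):
        with pytest.raises(ValueError):
            recognize(np.zeros(128), [], {}, 0.0)


class TestEvaluate:
    def test_counting_semantics(self):
        """Accepted-but-misassigned known steps are false negatives."""
        e0 = np.zeros(128); e0[0] = 1.0
        e1 = np.zeros(128); e1[1] = 1.0
        centroids, models = one_shot_pipeline({0: e0, 1: e1})
        far = np.zeros(128); far[2] = -1.0
        known = {0: np.stack([e0, e1, far])}   # TP, FN (misassigned), FN (rejected)
        unknown = np.stack([e1, far])          # FP (accepted as 1), TN
        rep = evaluate(known, unknown, centroids, models, tau=-0.1)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (1, 2, 1, 1)

    def test_metric_formulas(self):
        rep = MetricsReport(tp=8, fn=2, tn=9, fp=1)
        assert rep.tpr == pytest.approx(0.8)
        assert rep.tnr == pytest.approx(0.9)
        assert rep.acc == pytest.approx(0.85)

    def test_reject_everything_extreme(self, rng):
        e0 = np.zeros(128); e0[0] = 1.0
        centroids, models = one_shot_pipeline({0: e0})
        known = {0: unit_rows(rng, 20)}
        unknown = unit_rows(rng, 20)
        rep = evaluate(known, unknown, centroids, models, tau=1.1)
        assert rep.tpr == 0.0 and rep.tnr == 1.0

    def test_empty_unknown_is_nan_with_warning(self):
        e0 = np.zeros(128); e0[0] = 1.0
        centroids, models = one_shot_pipeline({0: e0})
        rep = evaluate({0: e0[None]}, np.empty((0, 128)), centroids, models, -0.1)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rep.tnr)

    def test_tau_monotonicity(self, rng):
        """Raising tau never increases TPR and never decreases TNR."""
        centers = unit_rows(rng, 3)
        shots = {a: unit_rows(rng, 10) * 0.05 + centers[a] for a in range(3)}
        shots = {a: v / np.linalg.norm(v, axis=1, keepdims=True)
                 for a, v in shots.items()}
        centroids = [compute_centroid(v, a) for a, v in shots.items()]
        models = {a: fit_osvm(v, 2.2, 0.06, subject=a) for a, v in shots.items()}
        known = {a: v + rng.normal(0, 0.05, v.shape) for a, v in shots.items()}
        unknown = unit_rows(rng, 30)
        prev_tpr, prev_tnr = 1.1, -0.1
        for tau in np.linspace(-1.0, 1.0, 9):
            rep = evaluate(known, unknown, centroids, models, tau)
            assert rep.tpr <= prev_tpr + 1e-12
            assert rep.tnr >= prev_tnr - 1e-12
            prev_tpr, prev_tnr = rep.tpr, rep.tnr
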