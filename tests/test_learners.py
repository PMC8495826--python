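"""The nine classifiers: contracts, oracles, and recovery properties."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from beetlecast import learners
from beetlecast.bayesnet import ChowLiuTree, DiscreteNaiveBayes, IambModel
from beetlecast.evaluation import auc
from beetlecast.features import FeatureMatrix
from beetlecast.learners import LearnerSpec, SingleClassError
from beetlecast.mrmr import mutual_information

from conftest import logistic_sample

CHEAP = dict(
    GBM={"n_estimators": 100},
    NN={"max_iter": 100},
    MM={"GBM": {"n_estimators": 100}, "NN": {"max_iter": 100}},
)


def make_fm(X, y, r=1, h=1):
    """Wrap arrays as a FeatureMatrix with synthetic keys."""
    X = pd.DataFrame(np.asarray(X, dtype=float))
    X.columns = [f"f{j}_lag0" for j in range(X.shape[1])]
    df = X.copy()
    n = len(df)
    df.insert(0, "pixel_id", np.arange(n))
    df.insert(1, "row", 0)
    df.insert(2, "col", np.arange(n))
    df.insert(3, "year", 2010 + (np.arange(n) % 5))
    df["target"] = np.asarray(y, dtype=int)
    df["target_year"] = df["year"] + r
    return FeatureMatrix(
        df=df, r=r, h=h, c=X.shape[1], ranking=[f"f{j}" for j in range(X.shape[1])],
        feature_cols=list(X.columns),
    )


class TestContracts:
    @pytest.mark.parametrize("name", learners.BASE_LEARNERS)
    def test_probabilities_in_unit_interval(self, name, train_setup):
        fm, plan, folds = train_setup
        spec = LearnerSpec(name, CHEAP.get(name, {}))
        model = learners.train(spec, fm, seed=0, rows=plan.train_idx)
        p = learners.predict(model, fm, plan.test_idx)
        assert np.all((p >= 0) & (p <= 1))

    @pytest.mark.parametrize("name", ["GLM", "KNN", "NB", "CL", "IAMB"])
    def test_row_order_invariance(self, name):
        rng = np.random.default_rng(0)
        X, y = logistic_sample(300, [1.5, -1.0], -0.5, seed=3)
        fm = make_fm(X, y)
        perm = rng.permutation(300)
        fm_perm = make_fm(X[perm], y[perm])
        spec = LearnerSpec(name)
        m1 = learners.train(spec, fm, seed=0)
        m2 = learners.train(spec, fm_perm, seed=0)
        Xtest = pd.DataFrame(
            rng.normal(size=(40, 2)), columns=fm.feature_cols
        )
        np.testing.assert_allclose(m1.predict(Xtest), m2.predict(Xtest), atol=1e-8)

    @pytest.mark.parametrize("name", ["SVM", "GLM", "GBM", "NN"])
    def test_single_class_raises_for_discriminative(self, name):
        X = np.random.default_rng(0).normal(size=(50, 3))
        fm = make_fm(X, np.zeros(50))
        with pytest.raises(SingleClassError):
            learners.train(LearnerSpec(name, CHEAP.get(name, {})), fm, seed=0)

    @pytest.mark.parametrize("name", ["NB", "CL", "IAMB", "KNN"])
    def test_single_class_tolerated_with_constant_output(self, name):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        fm = make_fm(X, np.zeros(300))
        model = learners.train(LearnerSpec(name), fm, seed=0)
        p = model.predict(pd.DataFrame(rng.normal(size=(10, 3)), columns=fm.feature_cols))
        assert np.all(p <= 0.15)  # near the zero base rate, up to smoothing

    def test_empty_training_data_raises(self):
        fm = make_fm(np.zeros((5, 2)), np.zeros(5))
        with pytest.raises(ValueError):
            learners.train(LearnerSpec("GLM"), fm, seed=0, rows=np.array([], dtype=int))

    def test_schema_mismatch_raises(self):
        X, y = logistic_sample(100, [1.0], 0.0, seed=0)
        model = learners.train(LearnerSpec("GLM"), make_fm(X, y), seed=0)
        with pytest.raises(ValueError):
            model.predict(pd.DataFrame({"wrong": [1.0]}))

    @pytest.mark.parametrize("name", ["GLM", "NB", "KNN"])
    def test_model_round_trip(self, name, tmp_path):
        X, y = logistic_sample(200, [1.0, -0.5], 0.0, seed=2)
        fm = make_fm(X, y)
        model = learners.train(LearnerSpec(name), fm, seed=0)
        path = tmp_path / "model.joblib"
        learners.save_model(model, path)
        again = learners.load_model(path)
        assert again.name == model.name
        np.testing.assert_array_equal(
            again.predict(fm.features()), model.predict(fm.features())
        )

    def test_seed_determinism(self, train_setup):
        fm, plan, _ = train_setup
        for name in ("GBM", "NN", "SVM"):
            spec = LearnerSpec(name, CHEAP.get(name, {}))
            m1 = learners.train(spec, fm, seed=5, rows=plan.train_idx)
            m2 = learners.train(spec, fm, seed=5, rows=plan.train_idx)
            np.testing.assert_array_equal(
                learners.predict(m1, fm, plan.test_idx),
                learners.predict(m2, fm, plan.test_idx),
            )


class TestSvm:
    def test_platt_calibration_preserves_ranking(self):
        """The sigmoid probability map is monotone in the decision value, so
        probability AUC equals raw-margin AUC."""
        X, y = logistic_sample(500, [1.0, -0.8, 0.3], -0.2, seed=6)
        fm = make_fm(X, y)
        model = learners.train(LearnerSpec("SVM"), fm, seed=0)
        Xte = pd.DataFrame(
            np.random.default_rng(7).normal(size=(200, 3)), columns=fm.feature_cols
        )
        d = model.decision_values(Xte)
        p = model.predict(Xte)
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= -1e-12)
        yte = (Xte.to_numpy() @ [1.0, -0.8, 0.3] - 0.2 > 0).astype(int)
        assert auc(p, yte) == pytest.approx(auc(d, yte))


class TestGlm:
    def test_recovers_known_logistic_coefficients(self):
        """MLE within 3 standard errors of the generating coefficients."""
        coefs = np.array([0.8, -1.2, 0.5])
        intercept = -0.7
        X, y = logistic_sample(20_000, coefs, intercept, seed=42)
        model = learners.train(LearnerSpec("GLM"), make_fm(X, y), seed=0)
        est = model.estimator
        theta = np.concatenate([est.intercept_, est.coef_.ravel()])
        # observed-information standard errors
        Xd = np.column_stack([np.ones(len(X)), X])
        p = 1 / (1 + np.exp(-(Xd @ theta)))
        fisher = Xd.T @ (Xd * (p * (1 - p))[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(fisher)))
        truth = np.concatenate([[intercept], coefs])
        assert np.all(np.abs(theta - truth) <= 3 * se)


class TestKnn:
    def test_nearest_self_with_k1(self):
        X, y = logistic_sample(50, [1.0, 1.0], 0.0, seed=1)
        fm = make_fm(X, y)
        model = learners.train(LearnerSpec("KNN", {"k": 1}), fm, seed=0)
        p = model.predict(fm.features())
        np.testing.assert_array_equal(p, y)

    def test_prediction_is_neighbor_fraction(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        y = np.array([1, 0, 1, 0])
        model = learners.train(LearnerSpec("KNN", {"k": 3}), make_fm(X, y), seed=0)
        p = model.predict(pd.DataFrame({"f0_lag0": [0.9]}))
        assert p[0] == pytest.approx(2 / 3)  # neighbors at 0,1,2

    def test_equidistant_tie_breaks_by_row_index(self):
        # four training rows all at distance 1 from the query; k=2 takes
        # the first two by training-row order
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.array([1, 1, 0, 0])
        model = learners.train(LearnerSpec("KNN", {"k": 2}), make_fm(X, y), seed=0)
        p = model.predict(pd.DataFrame({"f0_lag0": [0.0], "f1_lag0": [0.0]}))
        assert p[0] == pytest.approx(1.0)


class TestNaiveBayes:
    def test_posterior_matches_exact_bayes_oracle(self):
        """Two binary covariates: posterior equals hand enumeration of the
        smoothed joint table."""
        rng = np.random.default_rng(4)
        n = 400
        y = rng.integers(0, 2, n)
        x1 = np.where(rng.random(n) < 0.8, y, 1 - y)
        x2 = np.where(rng.random(n) < 0.6, y, rng.integers(0, 2, n))
        X = pd.DataFrame({"x1": x1.astype(float), "x2": x2.astype(float)})
        nb = DiscreteNaiveBayes(alpha=1.0).fit(
            X, y, {"x1": [0.0, 1.0], "x2": [0.0, 1.0]}
        )

        def oracle(v1, v2):
            post = []
            for cls in (0, 1):
                n_cls = np.sum(y == cls)
                prior = (n_cls + 1) / (n + 2)
                like = 1.0
                for col, v in (("x1", v1), ("x2", v2)):
                    cnt = np.sum((y == cls) & (X[col] == v))
                    like *= (cnt + 1) / (n_cls + 2)
                post.append(prior * like)
            return post[1] / (post[0] + post[1])

        for v1, v2 in itertools.product((0.0, 1.0), repeat=2):
            got = nb.predict_proba(pd.DataFrame({"x1": [v1], "x2": [v2]}))[0]
            assert got == pytest.approx(oracle(v1, v2))

    def test_all_missing_returns_prior(self):
        rng = np.random.default_rng(5)
        y = (rng.random(200) < 0.3).astype(int)
        X = pd.DataFrame({"x": rng.integers(1, 6, 200).astype(float)})
        nb = DiscreteNaiveBayes().fit(X, y, {"x": np.arange(1.0, 6.0)})
        p = nb.predict_proba(pd.DataFrame({"x": [np.nan]}))[0]
        prior = (y.sum() + 1) / (len(y) + 2)
        assert p == pytest.approx(prior)


def exhaustive_chow_liu_oracle(frame):
    """Best labeled spanning tree by total pairwise MI, exhaustively."""
    cols = list(frame.columns)
    mi = {
        frozenset((a, b)): mutual_information(frame[a], frame[b])
        for a, b in itertools.combinations(cols, 2)
    }
    best_edges, best_w = None, -np.inf
    for edges in itertools.combinations(itertools.combinations(cols, 2), len(cols) - 1):
        g = nx.Graph(edges)
        if g.number_of_nodes() == len(cols) and nx.is_tree(g):
            w = sum(mi[frozenset(e)] for e in edges)
            if w > best_w:
                best_edges, best_w = {frozenset(e) for e in edges}, w
    return best_edges, best_w


class TestChowLiu:
    def test_two_variables_single_edge(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = pd.DataFrame({"x": rng.integers(1, 3, 100).astype(float)})
        cl = ChowLiuTree().fit(X, y, {"x": [1.0, 2.0]})
        assert cl.edges() == {frozenset(("x", "target"))}

    def test_recovers_chain_against_exhaustive_oracle(self):
        """Data from the chain A->B->C->target: the fitted tree equals the
        exhaustive max-MI spanning tree (16 labeled trees on 4 nodes),
        which is the chain."""
        rng = np.random.default_rng(6)
        n = 6000
        a = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.85, a, 1 - a)
        c = np.where(rng.random(n) < 0.85, b, 1 - b)
        y = np.where(rng.random(n) < 0.85, c, 1 - c)
        X = pd.DataFrame({"A": a.astype(float), "B": b.astype(float), "C": c.astype(float)})
        cl = ChowLiuTree().fit(X, y, {k: [0.0, 1.0] for k in "ABC"})
        frame = X.copy()
        frame["target"] = y
        oracle_edges, oracle_w = exhaustive_chow_liu_oracle(frame)
        assert cl.edges() == oracle_edges
        assert cl.edges() == {
            frozenset(("A", "B")), frozenset(("B", "C")), frozenset(("C", "target"))
        }
        assert cl.tree_weight() == pytest.approx(oracle_w)

    def test_tree_weight_beats_random_spanning_trees(self):
        rng = np.random.default_rng(7)
        n = 800
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            {f"x{j}": np.where(rng.random(n) < 0.6 + 0.05 * j, y, rng.integers(0, 2, n)).astype(float)
             for j in range(4)}
        )
        cl = ChowLiuTree().fit(X, y, {f"x{j}": [0.0, 1.0] for j in range(4)})
        nodes = list(X.columns) + ["target"]
        w_fit = cl.tree_weight()
        frame = X.copy()
        frame["target"] = y
        for _ in range(100):
            # random spanning tree via random Prufer-like attachment
            order = list(rng.permutation(nodes))
            w = 0.0
            for i, node in enumerate(order[1:], start=1):
                other = order[rng.integers(0, i)]
                w += mutual_information(frame[node], frame[other])
            assert w_fit >= w - 1e-9

    def test_partial_evidence_marginalizes(self):
        rng = np.random.default_rng(8)
        n = 2000
        y = rng.integers(0, 2, n)
        x1 = np.where(rng.random(n) < 0.9, y, 1 - y)
        x2 = rng.integers(0, 2, n)
        X = pd.DataFrame({"x1": x1.astype(float), "x2": x2.astype(float)})
        cl = ChowLiuTree().fit(X, y, {"x1": [0.0, 1.0], "x2": [0.0, 1.0]})
        p_full = cl.predict_proba(pd.DataFrame({"x1": [1.0], "x2": [np.nan]}))[0]
        # manual: evidence only on x1
        assert p_full == pytest.approx(cl.posterior_target({"x1": 1.0}))
        assert p_full > 0.7

    def test_star_structure_posterior_equals_naive_bayes(self):
        """When the generating structure is a star centered on the target,
        Chow-Liu recovers it and its posterior equals naive Bayes."""
        rng = np.random.default_rng(9)
        n = 5000
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(
            {f"x{j}": np.where(rng.random(n) < 0.8, y, rng.integers(0, 2, n)).astype(float)
             for j in range(3)}
        )
        lv = {f"x{j}": [0.0, 1.0] for j in range(3)}
        cl = ChowLiuTree().fit(X, y, lv)
        assert cl.edges() == {frozenset((c, "target")) for c in X.columns}
        nb = DiscreteNaiveBayes().fit(X, y, lv)
        test = pd.DataFrame(
            [dict(zip(X.columns, vals)) for vals in itertools.product((0.0, 1.0), repeat=3)]
        )
        np.testing.assert_allclose(
            cl.predict_proba(test), nb.predict_proba(test), atol=1e-9
        )

    def test_fewer_than_two_variables_rejected(self):
        with pytest.raises(ValueError):
            ChowLiuTree().fit(pd.DataFrame(index=range(10)), np.zeros(10), {})


def exhaustive_blanket_oracle(frame, y, alpha=0.01):
    """Markov blanket by exhaustive conditional-independence testing: X is in
    the blanket iff no conditioning set renders it independent of the target."""
    from beetlecast.bayesnet import g_squared_test

    cols = list(frame.columns)
    blanket = []
    for x in cols:
        others = [c for c in cols if c != x]
        independent_somewhere = False
        for k in range(len(others) + 1):
            for cond in itertools.combinations(others, k):
                z = frame[list(cond)].to_numpy() if cond else None
                _, p = g_squared_test(frame[x], y, z)
                if p >= alpha:
                    independent_somewhere = True
                    break
            if independent_somewhere:
                break
        if not independent_somewhere:
            blanket.append(x)
    return set(blanket)


class TestIamb:
    def test_independent_target_empty_blanket(self):
        rng = np.random.default_rng(10)
        n = 500
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({f"x{j}": rng.integers(0, 2, n).astype(float) for j in range(4)})
        # the grow step takes the max over candidates, so the effective
        # false-positive level is ~4x alpha; test at a stricter level
        model = IambModel(alpha=0.002).fit(X, y, {f"x{j}": [0.0, 1.0] for j in range(4)})
        assert model.blanket == []
        p = model.predict_proba(X.head(5))
        np.testing.assert_allclose(p, (y.sum() + 1) / (n + 2))

    def test_recovers_two_variable_blanket(self):
        """target driven by x1 and x2 with independent x3: blanket {x1,x2},
        agreeing with the exhaustive conditional-independence oracle."""
        rng = np.random.default_rng(11)
        n = 4000
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        x3 = rng.integers(0, 2, n)
        p = 0.1 + 0.5 * x1 + 0.3 * x2
        y = (rng.random(n) < p).astype(int)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}, dtype=float)
        model = IambModel(alpha=0.01).fit(X, y, {c: [0.0, 1.0] for c in X.columns})
        assert set(model.blanket) == {"x1", "x2"}
        assert exhaustive_blanket_oracle(X, y) == {"x1", "x2"}

    @pytest.mark.parametrize("seed", range(10))
    def test_alpha_monotonicity(self, seed):
        """Stricter significance levels never grow the blanket."""
        rng = np.random.default_rng(seed)
        n = 600
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        x3 = np.where(rng.random(n) < 0.7, x1, rng.integers(0, 2, n))
        y = (rng.random(n) < 0.15 + 0.5 * x1 + 0.2 * x2).astype(int)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}, dtype=float)
        lv = {c: [0.0, 1.0] for c in X.columns}
        strict = IambModel(alpha=1e-6).fit(X, y, lv)
        loose = IambModel(alpha=0.05).fit(X, y, lv)
        assert len(strict.blanket) <= len(loose.blanket)

    def test_unseen_configuration_backs_off_to_nb(self):
        rng = np.random.default_rng(12)
        n = 1000
        x1 = rng.integers(0, 2, n)
        x2 = np.zeros(n)  # configuration (x1=., x2=1) never seen
        x2[:2] = 1.0  # keep column non-constant but (1,1) unseen
        x1[:2] = 0
        y = np.where(rng.random(n) < 0.9, x1, 1 - x1).astype(int)
        X = pd.DataFrame({"x1": x1.astype(float), "x2": x2})
        model = IambModel(alpha=0.05).fit(X, y, {c: [0.0, 1.0] for c in X.columns})
        if "x1" in model.blanket and "x2" in model.blanket:
            p = model.predict_proba(pd.DataFrame({"x1": [1.0], "x2": [1.0]}))[0]
            assert 0.0 <= p <= 1.0


class TestMixedModel:
    def _probs_fm(self, seed=0):
        rng = np.random.default_rng(seed)
        X, y = logistic_sample(400, [1.2, -0.8], -0.5, seed=seed)
        return make_fm(X, y), y

    def test_perfect_base_dominates_stack(self):
        """A base whose out-of-fold probabilities equal the target gets the
        stacker's weight and training AUC 1."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        n = 500
        y = rng.integers(0, 2, n)
        probs = pd.DataFrame(
            {
                "perfect": y.astype(float),
                "noise1": rng.random(n),
                "noise2": rng.random(n),
            }
        )
        stk = LogisticRegression(max_iter=2000).fit(probs.to_numpy(), y)
        p = stk.predict_proba(probs.to_numpy())[:, 1]
        assert auc(p, y) == pytest.approx(1.0)
        w = dict(zip(probs.columns, stk.coef_.ravel()))
        assert w["perfect"] > 3 * max(abs(w["noise1"]), abs(w["noise2"]))

    def test_constant_bases_predict_base_rate(self):
        rng = np.random.default_rng(3)
        n = 200
        y = (rng.random(n) < 0.3).astype(int)
        X = rng.normal(size=(n, 2))
        fm = make_fm(X, y)
        oof = pd.DataFrame(
            {name: np.full(n, 0.5) for name in learners.BASE_LEARNERS},
            index=fm.df.index,
        )
        mm = learners.fit_mixed_model(
            [LearnerSpec(n_, CHEAP.get(n_, {})) for n_ in learners.BASE_LEARNERS],
            fm, seed=0, oof_probs=oof,
        )
        p = mm.predict(fm.features())
        np.testing.assert_allclose(p, y.mean(), atol=1e-9)

    def test_stacking_sanity_on_synthetic_runs(self, train_setup):
        """MM's cross-validated AUC keeps up with the best base learner."""
        from beetlecast.evaluation import cross_val_aucs

        fm, plan, folds = train_setup
        best_base = -np.inf
        for name in ("GLM", "NB", "KNN"):
            vals = [a for _, a in cross_val_aucs(LearnerSpec(name), fm, folds, seed=0) if a is not None]
            best_base = max(best_base, float(np.mean(vals)))
        mm_spec = LearnerSpec("MM", CHEAP["MM"])
        vals = [a for _, a in cross_val_aucs(mm_spec, fm, folds, seed=0) if a is not None]
        assert float(np.mean(vals)) >= best_base - 0.05
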