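"""Shapley attribution: axioms, estimators, rankings, force-plot records."""

import numpy as np
import pytest

from kelptrace import (Background, ShapleyExplainer, global_importance,
                       local_explanation, shapley_exact, shapley_permutation,
                       value_function)
from kelptrace.shapley import exhaustive_permutation_reference


def _linear(w, b=None):
    w = np.atleast_2d(w)
    b = np.zeros(w.shape[1]) if b is None else b
    return lambda X: np.atleast_2d(X) @ w + b


def _sigmoid_model(w):
    return lambda X: 1.0 / (1.0 + np.exp(-(np.atleast_2d(X) @ w)))


class TestValueFunction:
    def test_full_coalition_is_model_output(self, rng):
        w = rng.normal(size=(5, 2))
        f = _linear(w)
        x = rng.normal(size=5)
        bg = Background(rng.normal(size=(4, 5)))
        v = value_function(f, x, range(5), bg)
        assert np.allclose(v, f(x)[0])

    def test_empty_coalition_mean_vector(self, rng):
        w = rng.normal(size=(5, 2))
        f = _sigmoid_model(w)
        x = rng.normal(size=5)
        samples = rng.normal(size=(6, 5))
        bg = Background(samples, summary_mode="mean-vector")
        v = value_function(f, x, [], bg)
        assert np.allclose(v, f(samples.mean(axis=0))[0])

    def test_sample_average_two_rows_hand_expansion(self, rng):
        w = rng.normal(size=(3, 2))
        f = _sigmoid_model(w)
        x = rng.normal(size=3)
        rows = rng.normal(size=(2, 3))
        bg = Background(rows)
        v = value_function(f, x, [1], bg)
        m0 = np.array([rows[0, 0], x[1], rows[0, 2]])
        m1 = np.array([rows[1, 0], x[1], rows[1, 2]])
        assert np.allclose(v, (f(m0)[0] + f(m1)[0]) / 2)

    def test_index_out_of_range(self, rng):
        bg = Background(rng.normal(size=(2, 3)))
        with pytest.raises(IndexError):
            value_function(_linear(np.ones((3, 1))), np.zeros(3), [3], bg)


class TestExactAxioms:
    def test_linear_closed_form(self, rng):
        w = rng.normal(size=(6, 3))
        b = rng.normal(size=3)
        x = rng.normal(size=6)
        bgr = rng.normal(size=(8, 6))
        expl = shapley_exact(_linear(w, b), x,
                            Background(bgr, summary_mode="mean-vector"))
        closed = (x - bgr.mean(axis=0))[:, None] * w
        assert np.abs(expl.phi[0] - closed).max() < 1e-9

    def test_efficiency(self, rng):
        for trial in range(20):
            w = rng.normal(size=(5, 3))
            expl = shapley_exact(_sigmoid_model(w), rng.normal(size=5),
                                 Background(rng.normal(size=(4, 5))))
            assert expl.additivity_residual.max() < 1e-9

    def test_dummy_axiom(self, rng):
        w = rng.normal(size=(5, 2))
        w[2] = 0.0  # model ignores feature 2
        expl = shapley_exact(_sigmoid_model(w), rng.normal(size=5),
                             Background(rng.normal(size=(6, 5))))
        assert np.abs(expl.phi[0, 2]).max() < 1e-12

    def test_symmetry_axiom(self, rng):
        w_row = rng.normal(size=2)
        w = np.vstack([w_row, w_row, rng.normal(size=(2, 2))])  # feats 0,1 equal
        x = rng.normal(size=4)
        x[1] = x[0]
        bgr = rng.normal(size=(5, 4))
        bgr[:, 1] = bgr[:, 0]
        expl = shapley_exact(_sigmoid_model(w), x, Background(bgr))
        assert np.abs(expl.phi[0, 0] - expl.phi[0, 1]).max() < 1e-9

    def test_linearity_of_games(self, rng):
        w1 = rng.normal(size=(4, 2))
        w2 = rng.normal(size=(4, 2))
        x = rng.normal(size=4)
        bgr = rng.normal(size=(5, 4))
        f1, f2 = _linear(w1), _linear(w2)
        fsum = lambda X: f1(X) + f2(X)
        p1 = shapley_exact(f1, x, Background(bgr)).phi
        p2 = shapley_exact(f2, x, Background(bgr)).phi
        ps = shapley_exact(fsum, x, Background(bgr)).phi
        assert np.abs(ps - (p1 + p2)).max() < 1e-9

    def test_refuses_wide_games(self, rng):
        with pytest.raises(ValueError, match="15"):
            shapley_exact(_linear(np.ones((20, 1))), np.zeros(20),
                          Background(np.zeros((2, 20))))


class TestPermutationEstimator:
    def test_matches_exact_within_monte_carlo_error(self, rng):
        w = rng.normal(size=(7, 3))
        f = _sigmoid_model(w)
        x = rng.normal(size=7)
        bg = Background(rng.normal(size=(5, 7)))
        exact = shapley_exact(f, x, bg).phi[0]
        estimates = [shapley_permutation(f, x, bg, n_perm=200, seed=s).phi[0]
                     for s in range(5)]
        mean_est = np.mean(estimates, axis=0)
        se = np.std(estimates, axis=0, ddof=1) / np.sqrt(5)
        assert np.all(np.abs(mean_est - exact) < 3 * np.maximum(se, 1e-4))

    def test_full_enumeration_reference_equals_exact(self, rng):
        w = rng.normal(size=(4, 3))
        f = _sigmoid_model(w)
        x = rng.normal(size=4)
        bg = Background(rng.normal(size=(6, 4)))
        ref = exhaustive_permutation_reference(f, x, bg)
        exact = shapley_exact(f, x, bg).phi[0]
        assert np.abs(ref - exact).max() < 1e-12

    def test_seed_determinism(self, rng):
        w = rng.normal(size=(6, 2))
        f = _sigmoid_model(w)
        x = rng.normal(size=6)
        bg = Background(rng.normal(size=(4, 6)))
        a = shapley_permutation(f, x, bg, n_perm=20, seed=5).phi
        b = shapley_permutation(f, x, bg, n_perm=20, seed=5).phi
        c = shapley_permutation(f, x, bg, n_perm=20, seed=6).phi
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_additivity_after_correction(self, rng):
        w = rng.normal(size=(9, 3))
        f = _sigmoid_model(w)
        x = rng.normal(size=9)
        bg = Background(rng.normal(size=(4, 9)))
        expl = shapley_permutation(f, x, bg, n_perm=5, seed=0)
        total = expl.base_values + expl.phi[0].sum(axis=0)
        assert np.allclose(total, expl.outputs[0], atol=1e-9)

    def test_error_decays_like_root_n(self, rng):
        """Empirical consistency: log-log error slope near -1/2."""
        w = rng.normal(size=(8, 2))
        f = _sigmoid_model(w)
        x = rng.normal(size=8)
        bg = Background(rng.normal(size=(3, 8)))
        exact = shapley_exact(f, x, bg).phi[0]
        sizes = [100, 400, 1600, 6400]
        errs = []
        for n_perm in sizes:
            err = np.mean([
                np.abs(shapley_permutation(f, x, bg, n_perm=n_perm,
                                           seed=s).phi[0] - exact).mean()
                for s in range(3)
            ])
            errs.append(err)
        slope = np.polyfit(np.log(sizes), np.log(errs), 1)[0]
        assert -0.65 < slope < -0.35


class TestReporting:
    def test_global_importance_hand_built(self):
        phi = np.zeros((2, 3, 2))
        phi[0, 0, 0], phi[1, 0, 0] = 1.0, -3.0   # feature 0, class 0
        phi[:, 2, 1] = 0.5
        expl = _dummy_expl(phi)
        df = global_importance(expl)
        assert df.iloc[0]["feature_id"] == "f0"
        assert df.iloc[0]["stacked_importance"] == pytest.approx(2.0)
        assert df.iloc[1]["feature_id"] == "f2"
        assert df.iloc[1]["stacked_importance"] == pytest.approx(0.5)

    def test_zero_phi_ranking_stable(self):
        expl = _dummy_expl(np.zeros((3, 4, 2)))
        df = global_importance(expl)
        assert list(df["feature_id"]) == ["f0", "f1", "f2", "f3"]
        assert (df["stacked_importance"] == 0).all()

    def test_local_explanation_identity(self, rng):
        w = rng.normal(size=(5, 3))
        f = _sigmoid_model(w)
        x = rng.normal(size=5)
        bg = Background(rng.normal(size=(6, 5)))
        expl = shapley_exact(f, x, bg)
        rec = local_explanation(expl, 0, 1)
        contrib = sum(c["phi"] for c in rec["contributions"])
        assert rec["base_value"] + contrib == pytest.approx(rec["output"])
        mags = [abs(c["phi"]) for c in rec["contributions"]]
        assert mags == sorted(mags, reverse=True)

    def test_balanced_symmetric_base_value_is_third(self, seed1_run):
        clf = seed1_run["clf"]
        zero = {k: np.zeros_like(v) for k, v in clf.weights_.items()}
        saved = clf.weights_
        try:
            clf.weights_ = zero
            expl = ShapleyExplainer(clf.predict_proba,
                                    Background(seed1_run["Xtr"]))
            assert np.allclose(expl.base_values(), 1 / 3)
        finally:
            clf.weights_ = saved


def _dummy_expl(phi):
    from kelptrace.shapley import Explanation
    n, d, C = phi.shape
    return Explanation(
        phi=phi, base_values=np.zeros(C), outputs=phi.sum(axis=1),
        additivity_residual=np.zeros((n, C)),
        feature_ids=[f"f{j}" for j in range(d)],
    )


def test_seed1_base_value_near_class_prior(seed1_run):
    """Mean training-set probability per class ~ 1/3 on the balanced split."""
    expl = ShapleyExplainer(seed1_run["clf"].predict_proba,
                            Background(seed1_run["Xtr"]))
    base = expl.base_values()
    assert np.allclose(base.sum(), 1.0, atol=1e-9)
    assert np.abs(base - 1 / 3).max() < 0.01
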