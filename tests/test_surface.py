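"""Quadratic surface fitting, prediction, and exhaustive ranking."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

import qpop
from qpop.design import generate_oacd
from qpop.surface import (
    QuadraticSurfaceRegressor,
    all_level_vectors,
    enumerate_and_rank,
    model_from_json,
    model_to_json,
    pairwise_interaction_matrix,
    predict_ncv,
    predict_regimen_ncv,
    second_order_terms,
    surface_from_coefficients,
    top_combinations,
)


def brute_force_scores(model, k):
    """Independent oracle: evaluate the polynomial term by term for every
    coded vector, without the model's feature-expansion machinery."""
    out = []
    for codes in itertools.product((0, 1, 2), repeat=k):
        x = [c / 2.0 for c in codes]
        y = model.intercept_
        for i in range(k):
            y += model.coef_linear_[i] * x[i] + model.coef_quadratic_[i] * x[i] ** 2
        for idx, (i, j) in enumerate(model.pair_index_):
            y += model.coef_interaction_[idx] * x[i] * x[j]
        out.append((tuple(codes), y))
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_noiseless_fit_recovers_truth_exactly(k2_truth, full_3x3_design):
    y = k2_truth.predict(full_3x3_design)
    model = QuadraticSurfaceRegressor().fit(full_3x3_design, y)
    assert model.intercept_ == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(model.coef_linear_, [-0.3, -0.2], atol=1e-10)
    np.testing.assert_allclose(model.coef_quadratic_, [0.05, 0.0], atol=1e-10)
    np.testing.assert_allclose(model.coef_interaction_, [-0.15], atol=1e-10)
    assert model.adj_r2_ == pytest.approx(1.0, abs=1e-12)


def test_noisy_fit_is_unbiased(k2_truth, full_3x3_design):
    """Parameter recovery: mean coefficient bias over 500 seeds stays
    below half the noise sd."""
    y0 = k2_truth.predict(full_3x3_design)
    truth = np.concatenate(
        [[1.0], k2_truth.coef_linear_, k2_truth.coef_quadratic_, k2_truth.coef_interaction_]
    )
    biases = []
    for seed in range(500):
        rng = np.random.default_rng(seed)
        m = QuadraticSurfaceRegressor().fit(full_3x3_design, y0 + rng.normal(0, 0.01, len(y0)))
        fitted = np.concatenate(
            [[m.intercept_], m.coef_linear_, m.coef_quadratic_, m.coef_interaction_]
        )
        biases.append(fitted - truth)
    assert np.abs(np.mean(biases, axis=0)).max() < 0.005


def test_k12_model_has_91_coefficients(oacd12):
    rng = np.random.default_rng(3)
    y = rng.uniform(0, 1, oacd12.n_rows)
    model = qpop.fit_quadratic_surface(oacd12, y)
    n_coefs = 1 + len(model.coef_linear_) + len(model.coef_quadratic_) + len(model.coef_interaction_)
    assert n_coefs == 91
    assert model.n_obs_ == 155


def test_underdetermined_fit_rejected(full_3x3_design):
    with pytest.raises(ValueError, match="observations"):
        QuadraticSurfaceRegressor().fit(full_3x3_design[:5], np.zeros(5))


def test_rank_deficient_design_rejected():
    X = np.tile([[0, 0], [2, 2]], (5, 1))  # only 2 distinct points
    with pytest.raises(ValueError):
        QuadraticSurfaceRegressor().fit(X, np.zeros(10))


def test_fit_matches_statsmodels_ols(oacd12):
    """Dual-route check of the estimator against an independent OLS."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    y = rng.uniform(0.1, 1.1, oacd12.n_rows)
    model = qpop.fit_quadratic_surface(oacd12, y)
    M = np.hstack([np.ones((155, 1)), second_order_terms(oacd12.numeric)])
    ref = sm.OLS(y, M).fit()
    np.testing.assert_allclose(
        np.concatenate([[model.intercept_], model.coef_linear_,
                        model.coef_quadratic_, model.coef_interaction_]),
        ref.params, rtol=1e-8,
    )
    assert model.adj_r2_ == pytest.approx(ref.rsquared_adj, abs=1e-10)


def test_adj_r2_decreases_with_noise(k2_truth, full_3x3_design):
    y0 = k2_truth.predict(full_3x3_design)
    means = []
    for sd in (0.0, 0.05, 0.2):
        vals = []
        for seed in range(200):
            rng = np.random.default_rng((seed, int(sd * 1000)))
            m = QuadraticSurfaceRegressor().fit(
                full_3x3_design, y0 + rng.normal(0, sd, len(y0))
            )
            vals.append(m.adj_r2_)
        means.append(np.mean(vals))
    assert means[0] == pytest.approx(1.0, abs=1e-12)
    assert means[0] > means[1] > means[2]


def test_sklearn_estimator_protocol(full_3x3_design, k2_truth):
    est = QuadraticSurfaceRegressor(alpha=0.1)
    assert est.get_params() == {"alpha": 0.1}
    cloned = clone(est)
    assert cloned.get_params() == {"alpha": 0.1}
    y = k2_truth.predict(full_3x3_design)
    fitted = QuadraticSurfaceRegressor().fit(full_3x3_design, y)
    assert fitted.score(full_3x3_design, y) == pytest.approx(1.0)  # R^2 via mixin


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "levels, expected",
    [((0, 0), 1.0), ((2, 2), 0.40), ((2, 0), 0.75)],
)
def test_predict_reference_values(k2_truth, levels, expected):
    assert predict_ncv(k2_truth, levels) == pytest.approx(expected, abs=1e-12)


def test_predict_rejects_invalid_codes(k2_truth):
    with pytest.raises(ValueError):
        k2_truth.predict(np.array([[3, 0]]))


# ---------------------------------------------------------------------------
# enumeration and ranking
# ---------------------------------------------------------------------------


def test_enumerate_k2(k2_truth):
    ranking = enumerate_and_rank(k2_truth)
    assert ranking.n == 9
    assert ranking.scores[0] == pytest.approx(0.40)  # (2,2) is the best killer
    assert tuple(ranking.codes[0]) == (2, 2)
    assert np.all(np.diff(ranking.scores) >= 0)


@pytest.mark.parametrize("k", [2, 3, 4])
def test_ranking_matches_brute_force_oracle(k):
    rng = np.random.default_rng(k)
    model = surface_from_coefficients(
        1.0,
        rng.normal(-0.2, 0.1, k),
        rng.normal(0, 0.05, k),
        rng.normal(0, 0.1, k * (k - 1) // 2),
    )
    ranking = enumerate_and_rank(model)
    oracle = sorted(brute_force_scores(model, k), key=lambda t: (t[1], t[0]))
    assert ranking.n == 3**k
    for rank_codes, rank_score, (o_codes, o_score) in zip(
        ranking.codes, ranking.scores, oracle
    ):
        assert tuple(rank_codes) == o_codes
        assert rank_score == pytest.approx(o_score, abs=1e-12)


def test_ranking_tie_break_is_lexicographic():
    # purely flat surface: all 27 scores tie; order must be lexicographic
    model = surface_from_coefficients(1.0, [0, 0, 0], [0, 0, 0], [0, 0, 0])
    ranking = enumerate_and_rank(model)
    assert np.array_equal(ranking.codes, all_level_vectors(3))


def test_ranking_invariant_to_response_shift(full_3x3_design, k2_truth):
    y = k2_truth.predict(full_3x3_design)
    a = enumerate_and_rank(QuadraticSurfaceRegressor().fit(full_3x3_design, y))
    b = enumerate_and_rank(QuadraticSurfaceRegressor().fit(full_3x3_design, y + 0.37))
    assert np.array_equal(a.codes, b.codes)
    np.testing.assert_allclose(b.scores - a.scores, 0.37, atol=1e-9)


def test_enumeration_refused_beyond_bound():
    k = 14
    model = surface_from_coefficients(
        1.0, np.zeros(k), np.zeros(k), np.zeros(k * (k - 1) // 2)
    )
    with pytest.raises(ValueError, match="refused"):
        enumerate_and_rank(model)


def test_top_combinations_filters_by_order(k2_truth):
    ranking = enumerate_and_rank(k2_truth)
    top1 = top_combinations(ranking, order=1, n=10)
    assert len(top1) == 4  # (1,0),(2,0),(0,1),(0,2) — fewer than n is fine
    assert ((top1[["A", "B"]] != 0).sum(axis=1) == 1).all()
    top2 = top_combinations(ranking, order=2, n=2)
    assert len(top2) == 2
    assert ((top2[["A", "B"]] != 0).sum(axis=1) == 2).all()
    assert top2["predicted_ncv"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# interaction matrix and regimen scores
# ---------------------------------------------------------------------------


def test_interaction_matrix_k2(k2_truth):
    mat = pairwise_interaction_matrix(k2_truth)
    assert mat.loc["A", "B"] == pytest.approx(0.40)  # attained at (2,2)
    assert mat.loc["B", "A"] == mat.loc["A", "B"]
    assert mat.loc["A", "A"] == pytest.approx(0.75)  # best single-drug A
    assert mat.loc["B", "B"] == pytest.approx(0.80)


def test_interaction_matrix_additive_closed_form():
    """With all pairwise terms zero the pair score decomposes into
    intercept + best single-drug contributions."""
    rng = np.random.default_rng(9)
    k = 4
    lin, quad = rng.normal(-0.3, 0.1, k), rng.normal(0, 0.05, k)
    model = surface_from_coefficients(1.0, lin, quad, np.zeros(6))
    mat = pairwise_interaction_matrix(model)
    best = [min(lin[m] * x + quad[m] * x * x for x in (0.5, 1.0)) for m in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            assert mat.iloc[i, j] == pytest.approx(1.0 + best[i] + best[j], abs=1e-12)


def test_interaction_matrix_symmetric_random():
    rng = np.random.default_rng(5)
    model = surface_from_coefficients(
        1.0, rng.normal(-0.2, 0.1, 5), rng.normal(0, 0.02, 5), rng.normal(0, 0.1, 10)
    )
    mat = pairwise_interaction_matrix(model).to_numpy()
    np.testing.assert_allclose(mat, mat.T)


def test_predict_regimen_ncv(k2_truth):
    assert predict_regimen_ncv(k2_truth, {"A"}) == pytest.approx(0.75)
    assert predict_regimen_ncv(k2_truth, {"A", "B"}) == pytest.approx(0.40)
    with pytest.raises(KeyError, match="unknown"):
        predict_regimen_ncv(k2_truth, {"unknown"})
    with pytest.raises(ValueError):
        predict_regimen_ncv(k2_truth, set())


def test_model_json_round_trip(k2_truth, tmp_path):
    path = tmp_path / "model.json"
    model_to_json(k2_truth, path)
    back = model_from_json(path)
    assert back.drug_names() == ["A", "B"]
    codes = all_level_vectors(2)
    np.testing.assert_allclose(back.predict(codes), k2_truth.predict(codes), atol=1e-12)
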