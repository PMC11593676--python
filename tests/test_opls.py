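"""OPLS discriminant model: recovery, VIP, homogeneity, CV, LLR link."""

import numpy as np
import pandas as pd
import pytest

from steroidomics import (
    classification_report,
    cross_validated_explained,
    fit_opls,
    hotelling_screen,
    predict_llr,
    select_predictors,
    vip_scores,
    wald_ci,
)
from steroidomics.opls import model_summary


def _nipals_pls_weight(X, y, n_iter=500, tol=1e-12):
    """Independent oracle: first-component PLS weight via NIPALS iteration."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    u = y - y.mean()
    Xc = X - X.mean(axis=0)
    w = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    for _ in range(n_iter):
        w_new = Xc.T @ u
        w_new /= np.linalg.norm(w_new)
        t = Xc @ w_new
        c = (u @ t) / (t @ t)
        u_new = u  # single y: u stays the centered response
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w, u = w_new, u_new
    return w


def _planted(rng, n=40, p=20, n_inf=6, effect=1.0, ortho_scale=0.0):
    """Case-control data: unit-variance noise plus a +/- ``effect``-sd class
    shift on the first ``n_inf`` variables, optionally confounded by a
    response-orthogonal latent factor."""
    y = np.r_[np.ones(n // 2), -np.ones(n - n // 2)]
    direction = np.zeros(p)
    direction[:n_inf] = 1.0 / np.sqrt(n_inf)
    X = rng.normal(0, 1.0, (n, p))
    X[:, :n_inf] += np.outer(y, np.full(n_inf, effect))
    if ortho_scale > 0:
        v = np.zeros(p)
        v[n_inf:] = 1.0 / np.sqrt(p - n_inf)  # orthogonal to the class direction
        t_conf = rng.normal(0, ortho_scale, n)  # chance correlation with y remains
        X = X + np.outer(t_conf, v)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return X, y, direction


def test_predictive_weight_recovery(rng):
    """X = y p' + modest noise, no structured orthogonal variation: the
    predictive weight aligns with p and the orthogonal component captures
    little of the predictor variance."""
    n, p = 40, 20
    y = np.r_[np.ones(20), -np.ones(20)]
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = np.outer(y, direction) + rng.normal(0, 0.3, (n, p))
    model = fit_opls(pd.DataFrame(X), y)
    r = np.corrcoef(model.w, direction)[0, 1]
    assert abs(r) > 0.95
    ortho_var = np.var(model.To) * np.sum(model.Po**2) if model.w_ortho is not None else 0.0
    assert ortho_var / np.sum(np.var(X, axis=0)) < 0.10


def test_single_predictor_equal_to_response():
    y = np.r_[np.ones(10), -np.ones(10)]
    X = pd.DataFrame({"x": y.astype(float)})
    model = fit_opls(X, y)
    assert model.explained_fit > 99.0
    # Tp reproduces y up to scale
    assert abs(np.corrcoef(model.Tp, y)[0, 1]) > 0.9999


def test_opls_equals_nipals_pls_without_orthogonal_structure(rng):
    """Pure rank-one X (no orthogonal variation): OPLS predictive weights
    coincide with single-component NIPALS PLS to 1e-6."""
    n, p = 30, 8
    y = np.r_[np.ones(15), -np.ones(15)]
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = np.outer(y, direction)
    model = fit_opls(pd.DataFrame(X), y)
    w_pls = _nipals_pls_weight(X, y)
    sign = np.sign(w_pls @ model.w)
    assert np.allclose(model.w, sign * w_pls, atol=1e-6)
    assert model.w_ortho is None  # nothing orthogonal to extract


def test_orthogonal_confound_filtered_from_scores(rng):
    """A strong planted confound (4x the predictive spread).  The OPLS
    predictive weight is provably identical to the one-component PLS weight
    (the orthogonal score is uncorrelated with the response by
    construction), so weight recovery must stay intact; the gain over PLS
    appears in the predictive *score*, which OPLS computes from the
    confound-filtered predictors and which therefore tracks the class
    structure more closely than the raw PLS score."""
    r_w, r_opls_score, r_pls_score = [], [], []
    for _ in range(20):
        X, y, direction = _planted(rng, ortho_scale=4.0)
        model = fit_opls(pd.DataFrame(X), y)
        w_pls = _nipals_pls_weight(X, y)
        assert np.allclose(np.abs(model.w), np.abs(w_pls), atol=1e-8)
        r_w.append(abs(np.corrcoef(model.w, direction)[0, 1]))
        r_opls_score.append(abs(np.corrcoef(model.Tp, y)[0, 1]))
        r_pls_score.append(abs(np.corrcoef((X - X.mean(0)) @ w_pls, y)[0, 1]))
    assert np.median(r_w) > 0.9
    assert np.median(r_opls_score) > np.median(r_pls_score)


def test_scores_orthogonal_and_loading_r_bounded(rng):
    X, y, _ = _planted(rng, ortho_scale=2.0)
    model = fit_opls(pd.DataFrame(X), y)
    tp = model.Tp - model.Tp.mean()
    to = model.To - model.To.mean()
    assert abs(tp @ to) / len(tp) <= 1e-8
    assert np.all(model.loading_R >= -1.0) and np.all(model.loading_R <= 1.0)


def test_coefficients_reproduce_predictions(rng):
    X, y, _ = _planted(rng, ortho_scale=1.5)
    model = fit_opls(pd.DataFrame(X), y)
    llr, _, _ = predict_llr(model, pd.DataFrame(X))
    assert np.max(np.abs(X @ model.b + model.b0 - llr)) <= 1e-8


def test_vip_normalization_and_symmetry(rng):
    X, y, _ = _planted(rng)
    model = fit_opls(pd.DataFrame(X), y)
    vip = vip_scores(model)
    assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-9)
    # exchangeable variables: identical columns up to iid noise -> VIP ~ 1
    Xe = np.outer(y, np.ones(10) / np.sqrt(10)) + rng.normal(0, 0.3, (len(y), 10))
    Xe = (Xe - Xe.mean(0)) / Xe.std(0, ddof=1)
    me = fit_opls(pd.DataFrame(Xe), y)
    assert np.allclose(vip_scores(me), 1.0, atol=0.35)


def test_vip_flags_single_informative_variable(rng):
    y = np.r_[np.ones(20), -np.ones(20)]
    X = rng.normal(size=(40, 20))
    X[:, 7] += y  # one informative variable among 19 noise
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    model = fit_opls(pd.DataFrame(X), y)
    vip = vip_scores(model)
    assert np.argmax(vip) == 7
    assert vip[7] > 1.0


def test_select_predictors_identity_and_bounds(rng):
    X, y, _ = _planted(rng)
    model = fit_opls(pd.DataFrame(X), y)
    same, names = select_predictors(model, threshold=0.0)
    assert names == model.variables
    with pytest.raises(ValueError, match="threshold"):
        select_predictors(model, threshold=float(model.vip.max()) + 10.0)


def test_select_predictors_recovers_informative(rng):
    """At the default VIP threshold 1.0, at least 80% of planted
    informative variables survive selection (aggregated over replicates)."""
    kept_inf = total_inf = 0
    for _ in range(200):
        X, y, direction = _planted(rng)
        model = fit_opls(pd.DataFrame(X), y)
        sel, names = select_predictors(model, threshold=1.0)
        informative = {str(j) for j in range(6)}
        kept_inf += len(informative & set(names))
        total_inf += 6
    assert kept_inf / total_inf >= 0.80


def test_hotelling_calibration_and_outlier(rng):
    n_ok = 0
    runs = 200
    n = 40
    for _ in range(runs):
        X, y, _ = _planted(rng, n=n)
        model = fit_opls(pd.DataFrame(X), y)
        flagged = int((~hotelling_screen(model, level=0.95)).sum())
        n_ok += flagged <= int(np.ceil(0.05 * n))
    assert n_ok / runs >= 0.90
    # a subject displaced 10 sd in predictor space is always flagged
    X, y, _ = _planted(rng)
    X[3] += 10.0
    model = fit_opls(pd.DataFrame(X), y)
    assert not hotelling_screen(model)[3]
    # level = 1 flags nothing
    assert hotelling_screen(model, level=1.0).all()


def test_cv_perfect_signal_and_optimism(rng):
    y = np.r_[np.ones(20), -np.ones(20)]
    X = pd.DataFrame({"x": y.astype(float)})
    assert cross_validated_explained(X, y) > 95.0
    Xn = pd.DataFrame(rng.normal(size=(40, 10)))
    model = fit_opls(Xn, y)
    cv = cross_validated_explained(Xn, y)
    assert cv <= model.explained_fit + 1e-6


def test_cv_null_calibration(rng):
    """Pure-noise predictors (n = 40): cross-validated explained
    variability stays at or below 10% in at least 90% of runs."""
    hits = 0
    runs = 200
    for _ in range(runs):
        y = np.r_[np.ones(25), -np.ones(15)]
        X = pd.DataFrame(rng.normal(size=(40, 10)))
        hits += cross_validated_explained(X, y) <= 10.0
    assert hits / runs >= 0.90


def test_llr_link_identities(rng):
    X, y, _ = _planted(rng)
    model = fit_opls(pd.DataFrame(X), y)
    # llr = 0 maps to probability 0.5; the link is monotone and saturates
    from scipy.special import expit

    assert expit(0.0) == 0.5
    llr, prob, labels = predict_llr(model, pd.DataFrame(X))
    order = np.argsort(llr)
    assert np.all(np.diff(prob[order]) >= 0)
    assert expit(20.0) > 0.999999 and expit(-20.0) < 1e-6
    assert set(labels) <= {"patient", "control"}


def test_separable_data_perfect_in_sample_operating_point(rng):
    X, y, _ = _planted(rng, effect=8.0)
    model = fit_opls(pd.DataFrame(X), y)
    rep = classification_report(model, pd.DataFrame(X), y)
    assert rep.sensitivity == 1.0
    assert rep.specificity == 1.0
    assert rep.sensitivity_ci == (1.0, 1.0)


@pytest.mark.parametrize(
    "p_hat, n, expected",
    [
        (0.875, 24, (0.743, 1.0)),
        (0.75, 12, (0.505, 0.995)),
        (1.0, 17, (1.0, 1.0)),
    ],
)
def test_wald_ci_reference_values(p_hat, n, expected):
    lo, hi = wald_ci(p_hat, n)
    assert lo == pytest.approx(expected[0], abs=5e-4)
    assert hi == pytest.approx(expected[1], abs=5e-4)


def test_wald_ci_contains_point_and_rejects_bad_input():
    lo, hi = wald_ci(0.4, 30)
    assert lo <= 0.4 <= hi
    with pytest.raises(ValueError):
        wald_ci(0.5, 0)
    with pytest.raises(ValueError):
        wald_ci(1.2, 10)


def test_model_summary_columns(rng):
    X, y, _ = _planted(rng)
    model = fit_opls(pd.DataFrame(X), y)
    summary = model_summary(model)
    assert list(summary.columns) == [
        "variable", "loading_R", "t_statistic", "coefficient", "vip",
    ]
    assert len(summary) == X.shape[1]


def test_fit_opls_input_validation(rng):
    X = pd.DataFrame(rng.normal(size=(12, 4)))
    with pytest.raises(ValueError, match="per group"):
        fit_opls(X, np.r_[np.ones(3), -np.ones(9)])
    with pytest.raises(ValueError, match="constant"):
        fit_opls(X, np.ones(12))
    with pytest.raises(ValueError, match="fixed"):
        fit_opls(X, np.r_[np.ones(6), -np.ones(6)], n_ortho=2)
    model = fit_opls(X, np.r_[np.ones(6), -np.ones(6)])
    with pytest.raises(KeyError):
        predict_llr(model, pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "b"]))


def test_agrees_with_sklearn_pls_on_rank_one(rng):
    """Cross-check against an established PLS implementation where the two
    must coincide (no orthogonal variation)."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    n, p = 24, 6
    y = np.r_[np.ones(12), -np.ones(12)]
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    X = np.outer(y, direction)
    model = fit_opls(pd.DataFrame(X), y)
    pls = sklearn.PLSRegression(n_components=1, scale=False).fit(X, y)
    w_sk = pls.x_weights_[:, 0]
    sign = np.sign(w_sk @ model.w)
    assert np.allclose(model.w, sign * w_sk, atol=1e-6)
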