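"""LASSO encoding fits, transfer, partial correlations, delta-R^2, auROC."""

import numpy as np
import pandas as pd
import pytest

from epnpop.encoding_models import (
    DesignMatrix,
    FAMILIES,
    LassoEncoder,
    REDUCED_MODEL_RULES,
    _window_centers,
    build_design_matrix,
    classify_reward_units,
    cross_context_transfer,
    delta_r2,
    fit_lasso_cv,
    model_family_comparison,
    partial_correlation,
)


def _design_from_arrays(X, y, context=None, groups=None):
    n = len(y)
    return DesignMatrix(
        X=pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])]),
        y=np.asarray(y, float),
        context=np.asarray(context if context is not None else ["all"] * n),
        trial_index=np.asarray(groups if groups is not None else np.arange(n)),
        window_centers=np.arange(n, dtype=float),
    )


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def test_window_count_arithmetic():
    # 10 s span, 0.2 s windows every 50 ms: floor((10-0.2)/0.05)+1 = 197
    centers = _window_centers(0.0, 10.0, 0.2, 0.05)
    assert len(centers) == 197
    assert centers[0] == pytest.approx(0.1)
    assert centers[-1] <= 10.0 - 0.1 + 1e-12


def test_design_matrix_structure(small_session, small_session_events):
    cfg, bundle, _ = small_session
    kin, events, _ = small_session_events
    from epnpop.session_io import AnalysisConfig

    design = build_design_matrix(bundle, kin, events, bundle.spikes[0], AnalysisConfig())
    assert set(design.X.columns) == set(FAMILIES["full"])
    assert not design.X.isna().any().any()
    assert set(np.unique(design.context)) <= {"Return", "Wait", "Go", "Evaluation"}
    assert len(design.y) == len(design.X)
    # speed is near-constant within the wait period (animal halted)
    wait = design.subset(design.rows("Wait"))
    assert wait.X["body_speed"].std() < 2.0


# ---------------------------------------------------------------------------
# LASSO fits
# ---------------------------------------------------------------------------


def test_noiseless_planted_model_recovered(rng):
    n, p = 600, 6
    X = rng.normal(size=(n, p))
    beta = np.array([2.0, -1.5, 0.0, 0.0, 1.0, 0.0])
    y = X @ beta
    design = _design_from_arrays(X, y)
    fit = fit_lasso_cv(design, tuple(design.X.columns), folds=10, random_state=0)
    assert fit.cv_r2 >= 0.99
    coefs = np.array([fit.coefficients[c] for c in design.X.columns])
    support = beta != 0
    assert np.all(np.sign(coefs[support]) == np.sign(beta[support]))


def test_null_predictors_give_negligible_cv_r2(rng):
    scores = []
    for k in range(100):
        X = rng.normal(size=(150, 5))
        y = rng.normal(size=150)
        enc = LassoEncoder(folds=10, inner_folds=3, n_alphas=10, random_state=k)
        enc.fit(X, y)
        scores.append(enc.cv_r2_)
    assert np.mean(scores) <= 0.02


def test_collinear_duplicate_column_l1_selection(rng):
    n = 400
    x = rng.normal(size=n)
    X = np.column_stack([x, x, rng.normal(size=n)])
    y = 2.0 * x + 0.1 * rng.normal(size=n)
    enc = LassoEncoder(folds=5, random_state=0)
    enc.fit(X, y)
    pair = np.abs(enc.coef_[:2])
    # at the selected penalty at most one of the twins is active
    assert pair.min() < 0.05 * max(pair.max(), 1e-9)


def test_constant_target_flagged():
    X = np.random.default_rng(0).normal(size=(100, 3))
    enc = LassoEncoder().fit(X, np.full(100, 7.0))
    assert enc.flagged_constant_
    assert np.isnan(enc.cv_r2_)


def test_cv_r2_invariant_to_predictor_rescaling(rng):
    X = rng.normal(size=(300, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 0.2 * rng.normal(size=300)
    enc1 = LassoEncoder(folds=5, random_state=0).fit(X, y)
    X2 = X.copy()
    X2[:, 0] = 100.0 * X2[:, 0] + 7.0
    enc2 = LassoEncoder(folds=5, random_state=0).fit(X2, y)
    assert enc1.cv_r2_ == pytest.approx(enc2.cv_r2_, abs=1e-6)


def test_grouped_folds_never_split_groups(rng):
    groups = np.repeat(np.arange(30), 5)
    ids = LassoEncoder.make_fold_ids(150, 10, groups=groups, seed=0)
    for g in np.unique(groups):
        assert len(np.unique(ids[groups == g])) == 1


# ---------------------------------------------------------------------------
# family comparison and transfer
# ---------------------------------------------------------------------------


def test_family_comparison_planted_spatiotemporal_tuning(rng):
    n_units, n = 50, 300
    rows = []
    for u in range(n_units):
        X = rng.normal(size=(n, 4))
        beta_st = rng.normal(0, 1, 2)
        y = X[:, 2:] @ beta_st + 0.3 * rng.normal(size=n)
        d = _design_from_arrays(X, y)
        kin_fit = fit_lasso_cv(d, ("v0", "v1"), folds=5, random_state=u)
        st_fit = fit_lasso_cv(d, ("v2", "v3"), folds=5, random_state=u)
        full_fit = fit_lasso_cv(d, ("v0", "v1", "v2", "v3"), folds=5, random_state=u)
        rows.append({"kin": kin_fit.cv_r2, "st": st_fit.cv_r2, "full": full_fit.cv_r2})
    table = pd.DataFrame(rows)
    comp = model_family_comparison(table)
    st_vs_kin = comp[(comp.family_a == "kin") & (comp.family_b == "st")].iloc[0]
    assert st_vs_kin["mean_b"] > st_vs_kin["mean_a"]
    assert st_vs_kin["p"] < 0.01
    # full family dominates each sub-family on planted additive models
    assert table["full"].mean() >= table["kin"].mean() - 0.02
    assert table["full"].mean() >= table["st"].mean() - 0.02


def test_identical_families_null_p(rng):
    vals = rng.normal(0.2, 0.05, 30)
    comp = model_family_comparison(pd.DataFrame({"a": vals, "b": vals.copy()}))
    assert comp.iloc[0]["p"] > 0.99


def _two_context_design(rng, flip: bool, n=400, p=4):
    Xa = rng.normal(size=(n, p))
    Xb = rng.normal(size=(n, p))
    beta = np.array([1.5, -1.0, 0.8, 0.0])
    beta_b = -beta if flip else beta
    ya = Xa @ beta + 0.1 * rng.normal(size=n)
    yb = Xb @ beta_b + 0.1 * rng.normal(size=n)
    X = np.vstack([Xa, Xb])
    y = np.concatenate([ya, yb])
    ctx = np.array(["Return"] * n + ["Go"] * n)
    return _design_from_arrays(X, y, context=ctx)


def test_transfer_r2_shared_vs_switched_tuning(rng):
    shared = _two_context_design(rng, flip=False)
    fit = fit_lasso_cv(shared, tuple(shared.X.columns), "Return", folds=5, random_state=0)
    tr = cross_context_transfer(fit, shared, "Go")
    assert abs(tr - fit.cv_r2) < 0.1

    switched = _two_context_design(rng, flip=True)
    fit2 = fit_lasso_cv(
        switched, tuple(switched.X.columns), "Return", folds=5, random_state=0
    )
    tr2 = cross_context_transfer(fit2, switched, "Go")
    assert tr2 < 0.0


def test_transfer_on_training_rows_reproduces_training_r2(rng):
    d = _two_context_design(rng, flip=False)
    fit = fit_lasso_cv(d, tuple(d.X.columns), "Return", folds=5, random_state=0)
    same = cross_context_transfer(fit, d, "Return")
    # the frozen model scored on its own training rows: in-sample R^2,
    # at least as high as the held-out estimate
    assert same >= fit.cv_r2 - 0.02


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------


def test_partial_equals_simple_with_orthogonal_covariates(rng):
    n = 2000
    Q, _ = np.linalg.qr(rng.normal(size=(n, 3)))
    X = Q * np.sqrt(n)  # orthogonal columns
    y = 1.5 * X[:, 0] + 0.05 * rng.normal(size=n)
    d = _design_from_arrays(X, y)
    res = partial_correlation(d, "v0", reduced=("v1", "v2"), n_perm=100, seed=0)
    simple = np.corrcoef(y, X[:, 0])[0, 1]
    assert res.r == pytest.approx(simple, abs=0.01)


def test_partial_correlation_null_calibrated(rng):
    rejections = 0
    for k in range(100):
        n = 200
        X = rng.normal(size=(n, 3))
        y = 2.0 * X[:, 1] + 1.0 * X[:, 2] + 0.2 * rng.normal(size=n)
        d = _design_from_arrays(X, y)
        res = partial_correlation(d, "v0", reduced=("v1", "v2"), n_perm=200, seed=k)
        if res.p <= 0.05:
            rejections += 1
    assert rejections <= 6


def test_partial_correlation_matches_two_stage_oracle(rng):
    n = 300
    X = rng.normal(size=(n, 4))
    y = X @ np.array([0.5, 1.0, -0.7, 0.2]) + 0.3 * rng.normal(size=n)
    d = _design_from_arrays(X, y)
    res = partial_correlation(d, "v0", reduced=("v1", "v2", "v3"), n_perm=50, seed=0)
    # independent two-stage computation
    A = np.column_stack([np.ones(n), X[:, 1:]])
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    oracle = np.corrcoef(resid, X[:, 0])[0, 1]
    assert res.r == pytest.approx(oracle, abs=1e-10)


def test_variable_in_reduced_set_rejected(rng):
    d = _design_from_arrays(rng.normal(size=(50, 3)), rng.normal(size=50))
    with pytest.raises(ValueError):
        partial_correlation(d, "v0", reduced=("v0", "v1"), n_perm=10)


def test_reduced_model_rules_exclude_the_variable():
    for var, covars in REDUCED_MODEL_RULES.items():
        assert var not in covars
    assert "head_speed" not in REDUCED_MODEL_RULES["body_speed"]
    assert all(c in FAMILIES["kinematic"] for c in REDUCED_MODEL_RULES["dist_goal"])


# ---------------------------------------------------------------------------
# delta R^2
# ---------------------------------------------------------------------------


def test_delta_r2_zero_for_uninformative_variable(rng):
    n = 400
    X = rng.normal(size=(n, 3))
    y = 2.0 * X[:, 1] + 0.2 * rng.normal(size=n)
    d = _design_from_arrays(X, y)
    dr = delta_r2(d, "v0", columns=("v0", "v1", "v2"), n_shuffles=5, folds=5, seed=0)
    assert abs(dr) < 0.05


def test_delta_r2_equals_full_for_sole_informative_variable(rng):
    n = 400
    X = rng.normal(size=(n, 3))
    y = 2.0 * X[:, 0] + 0.2 * rng.normal(size=n)
    d = _design_from_arrays(X, y)
    full = fit_lasso_cv(d, ("v0", "v1", "v2"), folds=5, random_state=0)
    dr = delta_r2(d, "v0", columns=("v0", "v1", "v2"), n_shuffles=5, folds=5, seed=0)
    assert dr == pytest.approx(full.cv_r2, abs=0.1)
    assert dr > 0.8


def test_delta_r2_shared_information_not_charged(rng):
    n = 500
    x = rng.normal(size=n)
    X = np.column_stack([x, x + 0.01 * rng.normal(size=n), rng.normal(size=n)])
    y = 2.0 * x + 0.2 * rng.normal(size=n)
    d = _design_from_arrays(X, y)
    dr0 = delta_r2(d, "v0", columns=("v0", "v1", "v2"), n_shuffles=5, folds=5, seed=0)
    dr1 = delta_r2(d, "v1", columns=("v0", "v1", "v2"), n_shuffles=5, folds=5, seed=0)
    assert abs(dr0) < 0.05 and abs(dr1) < 0.05


# ---------------------------------------------------------------------------
# reward classification
# ---------------------------------------------------------------------------


def test_auroc_rank_formula_matches_sklearn(rng, small_session, small_session_events):
    from sklearn.metrics import roc_auc_score
    from scipy.stats import rankdata

    counts = rng.poisson(4, 80).astype(float)
    labels = (rng.random(80) < 0.6).astype(int)
    n1, n0 = labels.sum(), (1 - labels).sum()
    r = rankdata(counts)
    mine = (r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    assert mine == pytest.approx(roc_auc_score(labels, counts), abs=1e-12)


def test_reward_classification_trivial_cases(small_session, small_session_events):
    cfg, bundle, gt = small_session
    _, events, _ = small_session_events
    res = classify_reward_units(bundle, events, n_perm=1000, seed=0)
    by_id = {r.unit_id: r for r in res}
    for unit in gt.units:
        r = by_id[unit.unit_id]
        assert 0.0 <= r.auroc <= 1.0
        if unit.reward_class == "positive":
            assert r.auroc > 0.5
        elif unit.reward_class == "negative":
            assert r.auroc < 0.5


def test_reward_classification_extreme_distributions(rng):
    # synthetic stand-in session with two deterministic units
    from epnpop.session_io import (
        LickEvents,
        SessionBundle,
        SpikeTrain,
        TrackingTable,
        TrialRecord,
    )
    from epnpop.session_io import BODYPARTS

    n_trials = 30
    t = np.arange(0, n_trials * 5.0, 1 / 60)
    coords = {bp: np.full((len(t), 2), 10.0) for bp in BODYPARTS}
    tracking = TrackingTable(time=t, coords=coords)
    trials, events = [], {}
    spikes_hi, spikes_flat = [], []
    for i in range(n_trials):
        rewarded = i % 2 == 0
        pe = 5.0 * i + 2.0
        trials.append(
            TrialRecord(index=i, delta_freq=0.4, instructed_side="right",
                        choice="right",
                        outcome="correct" if rewarded else "incorrect",
                        events={"port_entry": pe}, rewarded=rewarded)
        )
        events[i] = {"port_entry": pe}
        n_spk = 12 if rewarded else 2
        spikes_hi.extend(pe + 0.01 + 0.23 * np.arange(n_spk) / n_spk)
        spikes_flat.extend(pe + 0.01 + 0.23 * np.arange(5) / 5)
    bundle = SessionBundle(
        tracking=tracking,
        spikes=[
            SpikeTrain("hi", np.array(spikes_hi)),
            SpikeTrain("flat", np.array(spikes_flat)),
        ],
        trials=trials,
        licks={p: LickEvents(p, np.empty(0), np.empty(0)) for p in ("left", "right")},
    )
    res = {r.unit_id: r for r in classify_reward_units(bundle, events, n_perm=1000, seed=1)}
    assert res["hi"].auroc == pytest.approx(1.0)
    assert res["hi"].label == "positive"
    assert res["flat"].auroc == pytest.approx(0.5)
    assert res["flat"].label == "insensitive"
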