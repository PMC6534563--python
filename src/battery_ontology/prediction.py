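"""Out-of-sample prediction of real-world outcomes from factor scores.

Outcome targets are themselves factor scores: outcome variables are
residualized on age and sex, factor-analyzed (BIC-selected dimensionality,
oblimin rotation, ten Berge scores), and each target factor is predicted
from task and/or survey factor scores with cross-validated regularized
regression. Cross-validation uses balanced folds (the continuous target is
rank-stratified so fold-wise target distributions match), and the primary
model is ridge regression with the penalty chosen by efficient
leave-one-out error inside each training fold.

The reported cross-validated R^2 is the squared Pearson correlation
between the concatenated out-of-fold predictions and the actual target
(the signed correlation and the 1 - SSE/SST variant are stored alongside,
since squared correlation hides anti-prediction). Significance comes from
an empirical null: the target is shuffled, folds are rebuilt on the
shuffled target, and the whole pipeline — including penalty selection — is
rerun per shuffle. Standardized coefficients from the full-data fit form
the "ontological fingerprint" of each outcome.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .battery import BatteryError, CovariateTable, DVMatrix, residualize_covariates
from .efa import FactorScores, factor_scores, fit_efa, select_dimensionality

RIDGE_ALPHAS = np.logspace(-3, 3, 25)


# -- balanced folds -----------------------------------------------------------

def balanced_kfold(target: np.ndarray, k: int = 10, seed: int | None = 0) -> np.ndarray:
    """Rank-stratified fold assignment (1..k) for a continuous target.

    Participants are ordered by target value (ties broken by stable sort on
    position), split into consecutive rank blocks of size k, and each block
    deals one member to every fold at random. Fold sizes differ by at most
    one and fold-wise target means are tightly balanced.
    """
    y = np.asarray(target, dtype=float)
    n = len(y)
    if k > n:
        raise BatteryError(f"k={k} exceeds n={n}")
    if k < 2:
        raise BatteryError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start:start + k]
        assign = rng.permutation(k)[: len(block)] + 1
        folds[block] = assign
    return folds


# -- fast ridge with leave-one-out penalty selection --------------------------

def _ridge_loo(X: np.ndarray, y: np.ndarray, alphas: np.ndarray):
    """Ridge path via SVD; returns (best alpha, coefficients) on centered data."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uty = U.T @ y
    s2 = s**2
    best = (np.inf, None, None)
    for a in alphas:
        d = s2 / (s2 + a)
        yhat = U @ (d * Uty)
        h = np.einsum("ij,j,ij->i", U, d, U)
        denom = np.clip(1.0 - h, 1e-8, None)
        loo = float(np.mean(((y - yhat) / denom) ** 2))
        if loo < best[0]:
            best = (loo, a, d)
    _, alpha, d = best
    coef = Vt.T @ ((s / (s2 + alpha)) * Uty)
    return alpha, coef


def _standardize_train(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _fit_predict(Xtr, ytr, Xte, model: str, seed: int | None):
    """Fit one model on a training fold and predict the test fold.

    Standardization and any hyperparameter selection happen strictly inside
    the training data.
    """
    Xtr_s, Xte_s = _standardize_train(Xtr, Xte)
    ymu = ytr.mean()
    if model == "ridge":
        _, coef = _ridge_loo(Xtr_s, ytr - ymu, RIDGE_ALPHAS)
        return Xte_s @ coef + ymu
    if model == "lasso":
        from sklearn.linear_model import LassoCV

        est = LassoCV(cv=5, random_state=seed, max_iter=5000)
    elif model == "rf":
        from sklearn.ensemble import RandomForestRegressor

        est = RandomForestRegressor(n_estimators=200, random_state=seed)
    elif model == "svm":
        from sklearn.svm import SVR

        est = SVR()
    else:
        raise BatteryError(f"unknown model {model!r}")
    est.fit(Xtr_s, ytr)
    return est.predict(Xte_s)


def _as_feature_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, FactorScores):
        return features.values, list(features.scores.columns)
    if isinstance(features, DVMatrix):
        return features.values, features.dv_names
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    return X, [f"x{i+1}" for i in range(X.shape[1])]


def _cv_r2(preds: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(squared Pearson r, signed r, constant-prediction flag)."""
    if preds.std() == 0 or y.std() == 0:
        return 0.0, 0.0, True
    r = float(np.corrcoef(preds, y)[0, 1])
    return r * r, r, False


def cv_predict(
    features,
    target,
    model: str = "ridge",
    k: int = 10,
    seed: int | None = 0,
) -> dict:
    """Cross-validated + in-sample prediction of one target.

    Returns cv_r2 (squared correlation of concatenated out-of-fold
    predictions with the target), the signed cv_r, the 1 - SSE/SST variant,
    MAEs, and standardized ridge betas from the full-data fit.
    """
    X, feat_names = _as_feature_matrix(features)
    y = np.asarray(target, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise BatteryError("features/target length mismatch")
    folds = balanced_kfold(y, k=k, seed=seed)
    preds = np.empty_like(y)
    for fold in range(1, k + 1):
        te = folds == fold
        tr = ~te
        preds[te] = _fit_predict(X[tr], y[tr], X[te], model, seed)
    cv_r2, cv_r, flat = _cv_r2(preds, y)
    if flat:
        warnings.warn("constant out-of-fold predictions; cv_r2 set to 0")
    sst = float(((y - y.mean()) ** 2).sum())
    cv_r2_sse = float(1.0 - ((y - preds) ** 2).sum() / sst) if sst > 0 else 0.0
    cv_mae = float(np.mean(np.abs(y - preds)))

    ins = _fit_predict(X, y, X, model, seed)
    ins_r2, _, _ = _cv_r2(ins, y)
    ins_mae = float(np.mean(np.abs(y - ins)))

    # standardized betas from the full-data ridge fit (features and target
    # both z-scored), regardless of the CV model
    Xs, _ = _standardize_train(X, X)
    ysd = y.std(ddof=1)
    yz = (y - y.mean()) / (ysd if ysd > 0 else 1.0)
    alpha, betas = _ridge_loo(Xs, yz, RIDGE_ALPHAS)
    return {
        "cv_r2": cv_r2,
        "cv_r": cv_r,
        "cv_r2_sse": cv_r2_sse,
        "cv_mae": cv_mae,
        "insample_r2": ins_r2,
        "insample_mae": ins_mae,
        "betas": pd.Series(betas, index=feat_names),
        "ridge_alpha": float(alpha),
        "predictions": preds,
        "constant_prediction": flat,
        "model": model,
        "k": k,
    }


def permutation_null(
    features,
    target,
    model: str = "ridge",
    n_perm: int = 2500,
    k: int = 10,
    seed: int | None = 0,
) -> dict:
    """cv_predict plus an empirical null from target shuffling.

    Each permutation shuffles the target, rebuilds balanced folds on the
    shuffled values, and reruns the full CV pipeline including penalty
    selection. p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution")
    X, _ = _as_feature_matrix(features)
    y = np.asarray(target, dtype=float).ravel()
    observed = cv_predict(X, y, model=model, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    preds = np.empty_like(y)
    for p in range(n_perm):
        yp = rng.permutation(y)
        folds = balanced_kfold(yp, k=k, seed=int(rng.integers(2**31 - 1)))
        for fold in range(1, k + 1):
            te = folds == fold
            tr = ~te
            preds[te] = _fit_predict(X[tr], yp[tr], X[te], model, seed)
        null[p], _, _ = _cv_r2(preds, yp)
    obs = observed["cv_r2"]
    observed.update(
        {
            "null_distribution": null,
            "null_95": float(np.percentile(null, 95)),
            "p_value": float((1 + np.sum(null >= obs)) / (1 + n_perm)),
            "n_perm": n_perm,
        }
    )
    return observed


# -- outcome targets ----------------------------------------------------------

def derive_outcome_targets(
    outcome_dvm: DVMatrix,
    covariates: CovariateTable,
    f_candidates=None,
    seed: int | None = 0,
) -> dict:
    """Residualize outcomes on age/sex, then EFA them into target scores."""
    resid = residualize_covariates(outcome_dvm, covariates)
    sweep = select_dimensionality(resid, f_candidates=f_candidates, seed=seed)
    model = fit_efa(resid, sweep.best_f, seed=seed)
    scores = factor_scores(model, resid)
    return {"scores": scores, "model": model, "sweep": sweep}


def predict_targets(
    features,
    targets: FactorScores | pd.DataFrame,
    model: str = "ridge",
    k: int = 10,
    n_perm: int = 2500,
    seed: int | None = 0,
) -> dict:
    """permutation_null for every target column; betas stacked as a matrix."""
    tdf = targets.scores if isinstance(targets, FactorScores) else targets
    results = {}
    for i, col in enumerate(tdf.columns):
        results[col] = permutation_null(
            features, tdf[col].to_numpy(), model=model,
            n_perm=n_perm, k=k,
            seed=None if seed is None else seed + i,
        )
    betas = pd.DataFrame({t: r["betas"] for t, r in results.items()}).T
    summary = pd.DataFrame(
        {
            t: {
                "cv_r2": r["cv_r2"],
                "insample_r2": r["insample_r2"],
                "cv_mae": r["cv_mae"],
                "null_95": r["null_95"],
                "p_value": r["p_value"],
            }
            for t, r in results.items()
        }
    ).T
    return {"per_target": results, "betas": betas, "summary": summary}


def fingerprint(
    betas: pd.DataFrame,
    direction: str = "target_wise",
    name: str | None = None,
) -> pd.DataFrame | pd.Series:
    """Coefficient profiles from a targets x features beta matrix.

    ``target_wise`` reads a row (one outcome's profile over psychological
    factors); ``feature_wise`` reads a column (one factor's relationship to
    all outcomes) — an exact transpose of the other view.
    """
    if direction == "target_wise":
        return betas.loc[name] if name is not None else betas
    if direction == "feature_wise":
        out = betas.T
        return out.loc[name] if name is not None else out
    raise BatteryError(f"unknown direction {direction!r}")
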