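"""Exploratory factor analysis: the quantitative psychological space.

The common factor model writes each standardized DV as a linear combination
of f latent factors plus a unique part,

    X - mu = F L' + eps,

with loading matrix L (m x f), factor correlation matrix Phi (oblique
rotation does not force orthogonality), and uniquenesses Psi on the
diagonal. Estimation is maximum likelihood on the correlation matrix
(Wishart likelihood, concentrated over L so the optimization runs over the
m uniquenesses only), followed by direct-oblimin (quartimin) rotation via
gradient projection. Factor scores use the ten Berge correlation-preserving
construction, whose defining property is that the score correlation matrix
reproduces the estimated Phi.

Dimensionality is selected by BIC: chi2 - df * ln(n), with the
Bartlett-corrected likelihood-ratio chi2 and df = ((m-f)^2 - (m+f)) / 2.
The chi2 and BIC are rotation-invariant, so the dimensionality sweep skips
rotation entirely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .battery import BatteryError, DVMatrix, standardize

logger = logging.getLogger(__name__)

PSI_LOWER = 0.001  # uniqueness bound; fits pinned here are flagged as Heywood


class EFAError(RuntimeError):
    pass


# -- linear-algebra helpers ---------------------------------------------------

def _mat_power(M: np.ndarray, power: float, eps: float = 1e-12) -> np.ndarray:
    """Symmetric matrix power via eigendecomposition, eigenvalues clipped."""
    w, V = linalg.eigh(M)
    w = np.clip(w, eps, None)
    return (V * w**power) @ V.T


def _correlation_matrix(dvm: DVMatrix) -> np.ndarray:
    z = standardize(dvm).values
    R = np.corrcoef(z, rowvar=False)
    return np.atleast_2d(R)


def _ensure_pd(R: np.ndarray) -> np.ndarray:
    w = linalg.eigvalsh(R)
    if w.min() < 1e-10:
        logger.info("correlation matrix near-singular; adding 1e-8 ridge")
        R = R + 1e-8 * np.eye(R.shape[0])
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading vectors."""
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def congruence_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tucker congruence between columns of A and columns of B."""
    An = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    return An.T @ Bn


def align_factors(L: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permutation + sign alignment of L's factors to a reference solution.

    Solves the assignment problem maximizing total absolute Tucker
    congruence; returns (column permutation, signs).
    """
    from scipy.optimize import linear_sum_assignment

    C = congruence_matrix(ref, L)
    rows, cols = linear_sum_assignment(-np.abs(C))
    order = np.empty(L.shape[1], dtype=int)
    signs = np.empty(L.shape[1])
    for r, c in zip(rows, cols):
        order[r] = c
        signs[r] = 1.0 if C[r, c] >= 0 else -1.0
    return order, signs


# -- maximum-likelihood fit ---------------------------------------------------

def _ml_objective_grad(psi: np.ndarray, R: np.ndarray, f: int):
    m = R.shape[0]
    d = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(d, d)
    w, V = linalg.eigh(Rs)
    w = w[::-1]
    V = V[:, ::-1]
    tail = w[f:]
    tail = np.clip(tail, 1e-12, None)
    obj = float(np.sum(tail - np.log(tail) - 1.0))
    load = V[:, :f] * np.sqrt(np.clip(w[:f] - 1.0, 0.0, None))
    load = load * np.sqrt(psi)[:, None]
    g = ((load @ load.T + np.diag(psi) - R).diagonal()) / psi**2
    return obj, g


def _ml_fit(R: np.ndarray, f: int) -> dict:
    """Concentrated Wishart ML over uniquenesses; unrotated canonical loadings."""
    m = R.shape[0]
    if f >= m:
        raise EFAError(f"n_factors={f} must be < n_dvs={m}")
    Rinv_diag = np.diag(linalg.inv(R))
    psi0 = np.clip((1.0 - 0.5 * f / m) / Rinv_diag, PSI_LOWER, 1.0)
    # perfect-fit shortcut: with psi = 1 and no common variance the model may
    # already be exact (e.g. an identity correlation matrix, where the fit is
    # otherwise non-identified); prefer that degenerate optimum when it holds
    obj_ones, _ = _ml_objective_grad(np.ones(m), R, f)
    if obj_ones < 1e-12:
        psi0 = np.ones(m)
    res = optimize.minimize(
        _ml_objective_grad,
        psi0,
        args=(R, f),
        jac=True,
        method="L-BFGS-B",
        bounds=[(PSI_LOWER, 1.0)] * m,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-7},
    )
    psi = res.x
    d = 1.0 / np.sqrt(psi)
    w, V = linalg.eigh(R * np.outer(d, d))
    w = w[::-1]
    V = V[:, ::-1]
    L = V[:, :f] * np.sqrt(np.clip(w[:f] - 1.0, 0.0, None))
    L = L * np.sqrt(psi)[:, None]
    heywood = psi <= PSI_LOWER * 1.0001
    return {
        "loadings": L,
        "psi": psi,
        "objective": float(res.fun),
        "converged": bool(res.success),
        "heywood": heywood,
        "n_iter": int(res.nit),
        "message": str(res.message),
    }


def _fit_stats(objective: float, m: int, f: int, n: int) -> dict:
    df = ((m - f) ** 2 - (m + f)) / 2.0
    bartlett = n - 1 - (2 * m + 5) / 6.0 - 2 * f / 3.0
    chi2 = max(bartlett, 1.0) * objective
    bic = chi2 - df * np.log(n) if df > 0 else np.nan
    return {
        "objective": objective,
        "chi2": float(chi2),
        "df": float(df),
        "bic": float(bic),
        "n_obs": int(n),
    }


# -- oblimin (quartimin) rotation via gradient projection ---------------------

def _quartimin(L: np.ndarray):
    k = L.shape[1]
    L2 = L * L
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    return float(np.sum(L2 * X) / 4.0), L * X


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, max_iter: int = 500, tol: float = 1e-7):
    """Gradient-projection oblique rotation (quartimin criterion)."""
    T = T0.copy()
    Ti = linalg.inv(T)
    L = A @ Ti.T
    fval, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X * X).sum(axis=0))
            Ti_t = linalg.inv(X)
            Lt = A @ Ti_t.T
            ft, Gq_t = _quartimin(Lt)
            if ft < fval - 0.5 * s * s * al:
                break
            al /= 2.0
        T, L, fval, Gq, Ti = X, Lt, ft, Gq_t, Ti_t
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, fval, converged


def _rotate_oblimin(A: np.ndarray, rng: np.random.Generator, n_starts: int = 10):
    """Quartimin rotation with identity + random starts; lowest criterion wins."""
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1))
    best = None
    starts = [np.eye(k)]
    for _ in range(max(0, n_starts - 1)):
        X = rng.normal(size=(k, k))
        starts.append(X / np.sqrt((X * X).sum(axis=0)))
    for T0 in starts:
        try:
            L, Phi, fval, _ = _gpa_oblique(A, T0)
        except linalg.LinAlgError:
            continue
        if best is None or fval < best[2]:
            best = (L, Phi, fval)
    if best is None:
        raise EFAError("oblimin rotation failed from all starts")
    return best[0], best[1]


def _canonical_order(L: np.ndarray, Phi: np.ndarray):
    """Sort factors by explained SS loadings, flip signs to positive sums."""
    ss = (L * L).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


# -- ten Berge factor-score weights -------------------------------------------

def _tenberge_weights(R: np.ndarray, L: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Correlation-preserving score weights for oblique factors.

    With scores S = Z W, the construction guarantees corr(S) = Phi at the
    sample correlation R used to build W.
    """
    Phi_h = _mat_power(Phi, 0.5)
    Lp = L @ Phi_h
    R_ih = _mat_power(R, -0.5)
    M = Lp.T @ linalg.solve(R, Lp, assume_a="pos")
    C = R_ih @ Lp @ _mat_power(M, -0.5)
    return R_ih @ C @ Phi_h


# -- public containers --------------------------------------------------------

@dataclass
class FactorModel:
    """Fitted oblique factor model for one battery (or battery subset)."""

    loadings: pd.DataFrame        # m x f
    phi: np.ndarray               # f x f factor correlations
    uniqueness: pd.Series         # length m
    weights: pd.DataFrame         # m x f ten Berge score weights
    communality: pd.Series        # length m, diag(L Phi L')
    n_factors: int
    fit: dict                     # objective, chi2, df, bic, n_obs
    rotation: str = "oblimin"
    converged: bool = True
    heywood: np.ndarray | None = None

    @property
    def dv_names(self) -> list[str]:
        return list(self.loadings.index)

    def to_json(self, path) -> None:
        payload = {
            "dv_names": self.dv_names,
            "n_factors": self.n_factors,
            "rotation": self.rotation,
            "converged": self.converged,
            "loadings": self.loadings.to_numpy().tolist(),
            "phi": np.asarray(self.phi).tolist(),
            "uniqueness": self.uniqueness.to_numpy().tolist(),
            "weights": self.weights.to_numpy().tolist(),
            "fit": self.fit,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class FactorScores:
    scores: pd.DataFrame  # n x f
    method: str = "tenBerge"

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


@dataclass
class DimensionalitySweep:
    sweep: pd.DataFrame  # index f; columns objective, chi2, df, bic, converged
    best_f: int

    def to_csv(self, path) -> None:
        out = self.sweep.copy()
        out.index.name = "n_factors"
        out.to_csv(path)


# -- main operations ----------------------------------------------------------

def fit_efa_from_corr(
    R: np.ndarray,
    f: int,
    n_obs: int,
    dv_names: Sequence[str] | None = None,
    seed: int | None = 0,
    rotate: bool = True,
    rotation_starts: int = 10,
) -> FactorModel:
    """Fit the factor model directly from a correlation matrix."""
    R = _ensure_pd(np.asarray(R, dtype=float))
    m = R.shape[0]
    if dv_names is None:
        dv_names = [f"dv{i}" for i in range(m)]
    ml = _ml_fit(R, f)
    if not ml["converged"]:
        raise EFAError(
            f"ML estimation did not converge for f={f}: {ml['message']} "
            f"(objective {ml['objective']:.6g} after {ml['n_iter']} iter)"
        )
    A = ml["loadings"]
    rng = np.random.default_rng(seed)
    if rotate and f > 1:
        L, Phi = _rotate_oblimin(A, rng, n_starts=rotation_starts)
    else:
        L, Phi = A.copy(), np.eye(f)
    L, Phi = _canonical_order(L, Phi)
    W = _tenberge_weights(R, L, Phi)
    h2 = np.einsum("ij,jk,ik->i", L, Phi, L)
    cols = [f"F{i+1}" for i in range(f)]
    return FactorModel(
        loadings=pd.DataFrame(L, index=list(dv_names), columns=cols),
        phi=Phi,
        uniqueness=pd.Series(ml["psi"], index=list(dv_names)),
        communality=pd.Series(h2, index=list(dv_names)),
        weights=pd.DataFrame(W, index=list(dv_names), columns=cols),
        n_factors=f,
        fit=_fit_stats(ml["objective"], m, f, n_obs),
        rotation="oblimin" if (rotate and f > 1) else "unrotated",
        converged=ml["converged"],
        heywood=ml["heywood"],
    )


def fit_efa(
    dvm: DVMatrix,
    f: int,
    seed: int | None = 0,
    rotate: bool = True,
    rotation_starts: int = 10,
) -> FactorModel:
    """ML + oblimin factor model of a battery's correlation matrix."""
    R = _correlation_matrix(dvm)
    return fit_efa_from_corr(
        R, f, dvm.n_participants, dv_names=dvm.dv_names, seed=seed,
        rotate=rotate, rotation_starts=rotation_starts,
    )


def select_dimensionality(
    dvm: DVMatrix,
    f_candidates: Sequence[int] | None = None,
    seed: int | None = 0,
) -> DimensionalitySweep:
    """BIC sweep over candidate factor counts; best_f = argmin BIC.

    Rotation leaves the likelihood (hence chi2 and BIC) unchanged, so the
    sweep fits the ML solution only.
    """
    m = dvm.n_dvs
    if f_candidates is None:
        f_candidates = range(1, min(m // 3, 25) + 1)
    f_candidates = [int(f) for f in f_candidates]
    if not f_candidates or max(f_candidates) >= m:
        raise EFAError("f_candidates must be nonempty and all < n_dvs")
    R = _ensure_pd(_correlation_matrix(dvm))
    rows = []
    for f in f_candidates:
        try:
            ml = _ml_fit(R, f)
            stats = _fit_stats(ml["objective"], m, f, dvm.n_participants)
            rows.append({"f": f, **stats, "converged": ml["converged"]})
        except EFAError:
            rows.append(
                {"f": f, "objective": np.nan, "chi2": np.nan, "df": np.nan,
                 "bic": np.nan, "n_obs": dvm.n_participants, "converged": False}
            )
    sweep = pd.DataFrame(rows).set_index("f")
    ok = sweep[sweep["converged"] & sweep["bic"].notna()]
    if ok.empty:
        raise EFAError("no candidate dimensionality converged")
    best_f = int(ok["bic"].idxmin())
    return DimensionalitySweep(sweep=sweep, best_f=best_f)


def factor_scores(model: FactorModel, dvm: DVMatrix) -> FactorScores:
    """ten Berge factor scores for the battery the model was fit on."""
    return apply_weights(model, dvm)


def apply_weights(model: FactorModel, dvm: DVMatrix) -> FactorScores:
    """Score new participants with the model's frozen weight matrix.

    Standardization uses the new sample's own means and SDs (the scaling
    convention for reapplying a weight matrix to a fresh cohort).
    """
    missing = [d for d in model.dv_names if d not in dvm.dv_names]
    extra = [d for d in dvm.dv_names if d not in model.dv_names]
    if missing:
        raise BatteryError(f"battery lacks model DVs: {missing}; extra: {extra}")
    sub = dvm.select_dvs(model.dv_names)
    Z = standardize(sub).values
    S = Z @ model.weights.to_numpy()
    return FactorScores(
        scores=pd.DataFrame(S, index=sub.data.index, columns=model.weights.columns)
    )


def bootstrap_loadings(
    dvm: DVMatrix,
    f: int,
    n_boot: int = 1000,
    keep_frac: float = 0.9,
    seed: int | None = 0,
    rotation_starts: int = 2,
    base_model: FactorModel | None = None,
) -> dict:
    """Element-wise mean and sd of loadings over participant subsamples.

    Each replicate refits the EFA on a ``keep_frac`` subsample drawn
    without replacement; factors are permutation/sign aligned to the base
    solution by maximal total absolute Tucker congruence before averaging.
    """
    rng = np.random.default_rng(seed)
    if base_model is None:
        base_model = fit_efa(dvm, f, seed=seed)
    ref = base_model.loadings.to_numpy()
    n = dvm.n_participants
    n_keep = max(int(round(keep_frac * n)), f + 2)
    sums = np.zeros_like(ref)
    sq = np.zeros_like(ref)
    failures = 0
    done = 0
    for _ in range(n_boot):
        idx = rng.choice(n, size=n_keep, replace=False)
        sub = DVMatrix(dvm.data.iloc[np.sort(idx)], dvm.meta.copy())
        try:
            mod = fit_efa(sub, f, seed=int(rng.integers(2**31 - 1)),
                          rotation_starts=rotation_starts)
        except (EFAError, BatteryError):
            failures += 1
            continue
        L = mod.loadings.to_numpy()
        order, signs = align_factors(L, ref)
        La = L[:, order] * signs
        sums += La
        sq += La * La
        done += 1
    if failures > 0.1 * n_boot:
        raise EFAError(f"{failures}/{n_boot} bootstrap refits failed")
    mean = sums / done
    var = np.maximum(sq / done - mean**2, 0.0)
    cols = base_model.loadings.columns
    return {
        "mean": pd.DataFrame(mean, index=dvm.dv_names, columns=cols),
        "sd": pd.DataFrame(np.sqrt(var), index=dvm.dv_names, columns=cols),
        "n_success": done,
        "n_failures": failures,
    }


def drop_measure_robustness(
    dvm: DVMatrix, f: int, seed: int | None = 0, rotation_starts: int = 2
) -> pd.DataFrame:
    """Refit the EFA dropping each measure (all of its DVs) in turn.

    Returns per-measure, per-factor Tucker congruence with the base
    solution (computed on the shared DVs after alignment). Congruence near
    1 means the factor does not depend on that measure.
    """
    measures = dvm.meta["measure"].unique().tolist()
    if len(measures) < 2:
        raise BatteryError("need at least 2 measures to drop one out")
    base = fit_efa(dvm, f, seed=seed)
    rows = {}
    for meas in measures:
        keep = [d for d, m in dvm.meta["measure"].items() if m != meas]
        if len(keep) <= f:
            logger.warning("dropping measure %r leaves m <= f; skipped", meas)
            continue
        sub = dvm.select_dvs(keep)
        mod = fit_efa(sub, f, seed=seed, rotation_starts=rotation_starts)
        ref = base.loadings.loc[keep].to_numpy()
        L = mod.loadings.to_numpy()
        order, signs = align_factors(L, ref)
        La = L[:, order] * signs
        rows[meas] = [
            abs(tucker_congruence(ref[:, j], La[:, j])) for j in range(f)
        ]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(base.loadings.columns)
    )


def factor_score_reliability(
    scores_t1: FactorScores, scores_t2: FactorScores
) -> dict:
    """Per-factor retest reliability of factor scores, plus a 2-D PCA view.

    Computes Pearson r and ICC(3,k) per factor over matched participants and
    projects the stacked T1/T2 scores onto the top two principal components
    (to visualize within-person stability against between-person spread).
    """
    ids = [i for i in scores_t1.scores.index if i in set(scores_t2.scores.index)]
    if len(ids) < 3:
        raise BatteryError("need at least 3 matched participants")
    a = scores_t1.scores.loc[ids].to_numpy()
    b = scores_t2.scores.loc[ids].to_numpy()
    n, f = a.shape
    rs = np.array([np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(f)])
    # ICC(3,k) per factor from the two-session ANOVA
    vals = np.stack([a, b], axis=2)
    grand = vals.mean(axis=(0, 2))
    row_mean = vals.mean(axis=2)
    col_mean = vals.mean(axis=0)
    ss_rows = 2 * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand[:, None]) ** 2).sum(axis=1)
    ss_tot = ((vals - grand[None, :, None]) ** 2).sum(axis=(0, 2))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / (n - 1)
    icc = (ms_rows - ms_err) / ms_rows
    from sklearn.decomposition import PCA

    stacked = np.vstack([a, b])
    pca = PCA(n_components=2).fit(stacked)
    proj = pca.transform(stacked)
    table = pd.DataFrame(
        {"pearson_r": rs, "icc3k": icc}, index=scores_t1.scores.columns
    )
    return {
        "table": table,
        "pca_coords_t1": proj[:n],
        "pca_coords_t2": proj[n:],
        "pca_variance_explained": pca.explained_variance_ratio_,
    }
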