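"""Task-survey separability: partial-correlation graphs and cross-category prediction.

Two complementary views of how the two measurement categories relate.
First, a sparse undirected graph over all DVs: the graphical lasso
estimates an L1-penalized precision matrix, with the penalty chosen by the
extended BIC, and edges carry partial correlations
rho_ij = -omega_ij / sqrt(omega_ii * omega_jj). Second, held-out
prediction: every DV is predicted from all other task DVs and, separately,
from all other survey DVs with cross-validated ridge regression, giving
four within/across-category R^2 distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.covariance import graphical_lasso

from .battery import BatteryError, DVMatrix, standardize

logger = logging.getLogger(__name__)


class NetworkError(RuntimeError):
    pass


@dataclass
class PartialCorrGraph:
    nodes: pd.DataFrame          # index dv_name; column category
    partial_corr: pd.DataFrame   # m x m, zero diagonal
    precision: np.ndarray
    lambda_selected: float
    ebic_gamma: float
    ebic_curve: pd.DataFrame     # lambda, n_edges, ebic

    def edges(self, min_abs: float = 0.0) -> pd.DataFrame:
        names = list(self.partial_corr.index)
        P = self.partial_corr.to_numpy()
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(P[i, j]) >= min_abs and P[i, j] != 0.0:
                    rows.append((names[i], names[j], P[i, j]))
        return pd.DataFrame(rows, columns=["dv_i", "dv_j", "pcorr"])


def _support(prec: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    scaled = np.abs(prec) / np.outer(d, d)
    S = scaled > tol
    np.fill_diagonal(S, True)
    return S


def _constrained_mle(R: np.ndarray, support: np.ndarray,
                     max_cycles: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Unpenalized Gaussian MLE of the precision matrix with a fixed edge set.

    Modified-regression/IPF algorithm: cycle over variables, solving each
    node's regression restricted to its neighbors until the implied
    covariance stabilizes.
    """
    m = R.shape[0]
    W = R.copy()
    betas = np.zeros((m, m))
    for _ in range(max_cycles):
        W_old = W.copy()
        for j in range(m):
            others = np.arange(m) != j
            nb = support[:, j] & others
            beta = np.zeros(m)
            if nb.any():
                beta[nb] = linalg.solve(
                    W[np.ix_(nb, nb)], R[nb, j], assume_a="sym"
                )
            W[others, j] = W[np.ix_(others, nb)] @ beta[nb]
            W[j, others] = W[others, j]
            betas[:, j] = beta
        if np.abs(W - W_old).max() < tol:
            break
    prec = np.zeros((m, m))
    for j in range(m):
        others = np.arange(m) != j
        theta_jj = 1.0 / (R[j, j] - W[others, j] @ betas[others, j])
        prec[j, j] = theta_jj
        prec[others, j] = -betas[others, j] * theta_jj
    prec = (prec + prec.T) / 2.0
    prec[~support] = 0.0
    return prec


def _ebic(prec: np.ndarray, R: np.ndarray, n: int, gamma: float) -> tuple[float, int]:
    m = R.shape[0]
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return np.inf, 0
    loglik = (n / 2.0) * (logdet - np.trace(R @ prec))
    n_edges = int(np.count_nonzero(np.triu(_support(prec) , k=1) & ~np.eye(m, dtype=bool)))
    ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(m)
    return float(ebic), n_edges


def fit_partial_correlation_graph(
    dvm: DVMatrix,
    ebic_gamma: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> PartialCorrGraph:
    """Graphical-lasso partial-correlation network with EBIC model selection.

    The penalty grid is log-spaced from lambda_max (the largest absolute
    off-diagonal correlation, above which the graph is empty) down to
    ``lambda_min_ratio * lambda_max``.
    """
    n = dvm.n_participants
    if n <= 3:
        raise NetworkError("need more than 3 participants")
    Z = standardize(dvm).values
    R = np.corrcoef(Z, rowvar=False)
    w = linalg.eigvalsh(R)
    if w.min() < 1e-10:
        logger.info("near-singular correlation matrix; adding 1e-8 ridge")
        R = R + 1e-8 * np.eye(R.shape[0])
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    if lambda_grid is None:
        lam_max = np.abs(R - np.eye(R.shape[0])).max()
        lam_max = max(lam_max, 1e-3)
        lambda_grid = np.logspace(
            np.log10(lambda_min_ratio * lam_max), np.log10(lam_max), n_lambda
        )
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    # the lasso path proposes candidate edge sets; each distinct support is
    # refit by constrained MLE so EBIC compares edge sets on the unpenalized
    # likelihood (a true BIC over graphs, not over shrinkage levels)
    rows, best = [], None
    seen: dict = {}
    for lam in lambda_grid:
        try:
            _, prec_pen = graphical_lasso(R, alpha=float(lam), max_iter=500)
        except FloatingPointError as exc:  # pragma: no cover
            raise NetworkError(f"graphical lasso failed at lambda={lam}: {exc}")
        support = _support(prec_pen)
        key = support.tobytes()
        if key not in seen:
            seen[key] = _constrained_mle(R, support)
        prec = seen[key]
        ebic, n_edges = _ebic(prec, R, n, ebic_gamma)
        rows.append({"lambda": lam, "n_edges": n_edges, "ebic": ebic})
        if best is None or ebic < best[0]:
            best = (ebic, lam, prec)
    _, lam_sel, prec = best
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 0.0)
    pcorr[np.abs(pcorr) < 1e-10] = 0.0
    names = dvm.dv_names
    return PartialCorrGraph(
        nodes=dvm.meta[["category"]].copy(),
        partial_corr=pd.DataFrame(pcorr, index=names, columns=names),
        precision=prec,
        lambda_selected=float(lam_sel),
        ebic_gamma=ebic_gamma,
        ebic_curve=pd.DataFrame(rows),
    )


def threshold_and_export(
    graph: PartialCorrGraph,
    min_abs_pcorr: float = 0.05,
    edge_path=None,
    graphml_path=None,
) -> dict:
    """Thresholded edge list, optional CSV/GraphML export, density summary."""
    edges = graph.edges(min_abs=min_abs_pcorr)
    if edge_path is not None:
        edges.to_csv(edge_path, index=False)
    if graphml_path is not None:
        import networkx as nx

        G = nx.Graph()
        for name, row in graph.nodes.iterrows():
            G.add_node(name, category=row["category"])
        for _, e in edges.iterrows():
            G.add_edge(e["dv_i"], e["dv_j"], weight=float(e["pcorr"]))
        nx.write_graphml(G, graphml_path)
    cat = graph.nodes["category"]
    counts = {"within_task": 0, "within_survey": 0, "cross": 0, "other": 0}
    possible = {"within_task": 0, "within_survey": 0, "cross": 0, "other": 0}
    names = list(graph.nodes.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ci, cj = cat[names[i]], cat[names[j]]
            if ci == cj == "task":
                key = "within_task"
            elif ci == cj == "survey":
                key = "within_survey"
            elif {ci, cj} == {"task", "survey"}:
                key = "cross"
            else:
                key = "other"
            possible[key] += 1
    for _, e in edges.iterrows():
        ci, cj = cat[e["dv_i"]], cat[e["dv_j"]]
        if ci == cj == "task":
            counts["within_task"] += 1
        elif ci == cj == "survey":
            counts["within_survey"] += 1
        elif {ci, cj} == {"task", "survey"}:
            counts["cross"] += 1
        else:
            counts["other"] += 1
    density = {
        k: (counts[k] / possible[k] if possible[k] else np.nan) for k in counts
    }
    return {"edges": edges, "counts": counts, "density": density}


def cross_category_prediction(
    dvm: DVMatrix, k: int = 10, seed: int | None = 0
) -> pd.DataFrame:
    """Held-out prediction of every DV from each category's other DVs.

    Returns one row per (DV, predictor category) with the cross-validated
    R^2 (squared correlation of out-of-fold predictions with the truth).
    The predicted DV is always excluded from its own predictor pool.
    """
    from .prediction import cv_predict

    cats = dvm.meta["category"]
    present = [c for c in ("task", "survey") if (cats == c).any()]
    if len(present) < 2:
        raise BatteryError("need both task and survey DVs")
    rows = []
    for target_dv in dvm.dv_names:
        y = dvm.data[target_dv].to_numpy(dtype=float)
        for pred_cat in present:
            pool = [
                d for d in dvm.dv_names
                if cats[d] == pred_cat and d != target_dv
            ]
            if not pool:
                raise BatteryError(f"empty predictor pool for {pred_cat}")
            X = dvm.data[pool].to_numpy(dtype=float)
            res = cv_predict(X, y, model="ridge", k=k, seed=seed)
            rows.append(
                {
                    "dv_name": target_dv,
                    "target_category": cats[target_dv],
                    "predictor_category": pred_cat,
                    "within": cats[target_dv] == pred_cat,
                    "cv_r2": res["cv_r2"],
                    "cv_r": res["cv_r"],
                }
            )
    return pd.DataFrame(rows)
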