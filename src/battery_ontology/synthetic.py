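"""Synthetic battery generator with planted ground truth.

Emulates the structure of a large individual-differences study: ~522
participants measured on 129 task DVs and 64 survey DVs, oblique latent
factors with block loading structure, weak task-survey coupling, per-DV
test-retest reliability (surveys high and homogeneous, tasks heterogeneous),
a 150-participant retest subsample, and real-world outcome variables driven
by survey-side factors at configurable predictive strength.

The data model per DV i is

    x_i = L_i f + s_i xi_i + e_i,

with trait factor scores f ~ N(0, Phi_joint), a stable specific factor xi_i
(retained across sessions), and session noise e_i (redrawn at retest),
scaled so each DV has unit variance and retest correlation
h2_i + s_i^2 = the configured reliability. Reliability >= communality by
construction: the common signal cannot exceed the stable variance.

Everything is seeded and bit-reproducible; planted loadings, factor
correlations, reliabilities, cluster labels and outcome coefficients are
returned as a GroundTruth for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .battery import BatteryError, CovariateTable, DVMatrix, RetestPair


class ConfigError(ValueError):
    pass


@dataclass
class CategoryConfig:
    """Loading-block design for one measurement category."""

    n_dvs: int
    n_factors: int
    primary_range: tuple[float, float] = (0.5, 0.8)
    cross_range: tuple[float, float] = (-0.15, 0.15)
    within_factor_corr: float = 0.3
    reliability_mean: float = 0.8
    reliability_sd: float = 0.06
    reliability_clip: tuple[float, float] = (0.05, 0.95)
    dvs_per_measure: int = 3  # measures group consecutive DVs (for drop-outs)


@dataclass
class OutcomeConfig:
    """Outcome layer: latent targets driven by survey factors."""

    n_latent: int = 8
    dvs_per_latent: int = 3
    loading_range: tuple[float, float] = (0.6, 0.8)
    # population R^2 of each latent target given survey factors; profile
    # spans the moderate-to-weak range typical of survey-based prediction
    target_r2: tuple[float, ...] = (0.29, 0.15, 0.12, 0.10, 0.08, 0.06, 0.05, 0.03)
    n_driving_factors: int = 3
    coef_range: tuple[float, float] = (0.4, 0.8)
    age_beta: float = 0.2
    sex_beta: float = 0.2


@dataclass
class GeneratorConfig:
    n_participants: int = 522
    n_retest: int = 150
    task: CategoryConfig = field(
        default_factory=lambda: CategoryConfig(
            n_dvs=129, n_factors=5,
            reliability_mean=0.45, reliability_sd=0.21,
        )
    )
    survey: CategoryConfig = field(
        default_factory=lambda: CategoryConfig(
            n_dvs=64, n_factors=12,
            reliability_mean=0.80, reliability_sd=0.06,
        )
    )
    cross_category_corr: float = 0.1
    outcomes: OutcomeConfig = field(default_factory=OutcomeConfig)
    max_communality_frac: float = 0.95  # communality <= this fraction of reliability
    seed: int = 0

    def validate(self) -> None:
        for name, cat in (("task", self.task), ("survey", self.survey)):
            if cat.n_dvs < cat.n_factors:
                raise ConfigError(f"{name}: fewer DVs than factors")
            if not 0 < cat.reliability_clip[0] <= cat.reliability_clip[1] <= 1:
                raise ConfigError(f"{name}: bad reliability clip range")
        if not 0 <= self.cross_category_corr < 1:
            raise ConfigError("cross_category_corr must be in [0, 1)")
        if len(self.outcomes.target_r2) != self.outcomes.n_latent:
            raise ConfigError("target_r2 length must equal n_latent")
        if any(not 0 <= r < 1 for r in self.outcomes.target_r2):
            raise ConfigError("target R^2 must be in [0, 1)")
        if not 0 <= self.n_retest <= self.n_participants:
            raise ConfigError("n_retest must be <= n_participants")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class GroundTruth:
    loadings: pd.DataFrame          # m x (f_task + f_survey), planted L
    phi: np.ndarray                 # joint factor correlation matrix
    reliability: pd.Series          # per DV
    specific_sd: pd.Series          # s_i per DV
    cluster_labels: pd.Series       # primary-factor block per DV
    factor_scores: pd.DataFrame     # n x f traits (task factors first)
    specific_scores: np.ndarray     # n x m stable specific factors
    session_noise_sd: pd.Series     # per DV
    factor_names: list[str] = field(default_factory=list)
    outcome_B: np.ndarray | None = None       # survey factors x latent targets
    outcome_latents: pd.DataFrame | None = None
    outcome_r2: np.ndarray | None = None

    def survey_factor_scores(self) -> pd.DataFrame:
        cols = [c for c in self.factor_scores.columns if c.startswith("survey")]
        return self.factor_scores[cols]

    def task_factor_scores(self) -> pd.DataFrame:
        cols = [c for c in self.factor_scores.columns if c.startswith("task")]
        return self.factor_scores[cols]


# -- internals ----------------------------------------------------------------

def _joint_phi(cfg: GeneratorConfig) -> tuple[np.ndarray, list[str]]:
    ft, fs = cfg.task.n_factors, cfg.survey.n_factors
    f = ft + fs
    phi = np.full((f, f), cfg.cross_category_corr)
    phi[:ft, :ft] = cfg.task.within_factor_corr
    phi[ft:, ft:] = cfg.survey.within_factor_corr
    np.fill_diagonal(phi, 1.0)
    w = np.linalg.eigvalsh(phi)
    if w.min() <= 1e-8:
        raise ConfigError("joint factor correlation matrix not positive-definite")
    names = [f"task_F{i+1}" for i in range(ft)] + [f"survey_F{i+1}" for i in range(fs)]
    return phi, names


def _category_loadings(
    cat: CategoryConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Block loading matrix (n_dvs x n_factors) and primary-factor labels."""
    L = np.zeros((cat.n_dvs, cat.n_factors))
    primary = np.arange(cat.n_dvs) % cat.n_factors
    primary = np.sort(primary)  # consecutive blocks
    for i in range(cat.n_dvs):
        j = primary[i]
        sign = 1.0 if rng.random() < 0.8 else -1.0
        L[i, j] = sign * rng.uniform(*cat.primary_range)
        others = [k for k in range(cat.n_factors) if k != j]
        L[i, others] = rng.uniform(cat.cross_range[0], cat.cross_range[1],
                                   size=len(others))
    return L, primary


def _reliabilities(cat: CategoryConfig, rng: np.random.Generator) -> np.ndarray:
    r = rng.normal(cat.reliability_mean, cat.reliability_sd, size=cat.n_dvs)
    return np.clip(r, *cat.reliability_clip)


# -- main operations ----------------------------------------------------------

def generate_battery(cfg: GeneratorConfig) -> tuple[DVMatrix, GroundTruth]:
    """Draw one session of the full battery plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    phi, factor_names = _joint_phi(cfg)
    ft = cfg.task.n_factors

    Lt, prim_t = _category_loadings(cfg.task, rng)
    Ls, prim_s = _category_loadings(cfg.survey, rng)
    m_t, m_s = cfg.task.n_dvs, cfg.survey.n_dvs
    m = m_t + m_s
    L = np.zeros((m, ft + cfg.survey.n_factors))
    L[:m_t, :ft] = Lt
    L[m_t:, ft:] = Ls

    rel = np.concatenate([
        _reliabilities(cfg.task, rng), _reliabilities(cfg.survey, rng),
    ])

    # enforce communality <= max_communality_frac * reliability by shrinking
    # the loading row (direction preserved, so planted structure is intact)
    h2 = np.einsum("ij,jk,ik->i", L, phi, L)
    cap = cfg.max_communality_frac * rel
    shrink = np.sqrt(np.where(h2 > cap, cap / np.maximum(h2, 1e-12), 1.0))
    L = L * shrink[:, None]
    h2 = h2 * shrink**2
    if np.any(h2 > rel + 1e-9):
        raise ConfigError("infeasible: communality exceeds reliability")

    s2 = rel - h2                 # stable specific variance
    e2 = 1.0 - rel                # session-noise variance
    s_sd = np.sqrt(s2)
    e_sd = np.sqrt(e2)

    n = cfg.n_participants
    chol = np.linalg.cholesky(phi)
    F = rng.standard_normal((n, phi.shape[0])) @ chol.T
    Xi = rng.standard_normal((n, m))
    E = rng.standard_normal((n, m))
    X = F @ L.T + Xi * s_sd + E * e_sd

    dv_names = (
        [f"task_dv{i+1:03d}" for i in range(m_t)]
        + [f"survey_dv{i+1:03d}" for i in range(m_s)]
    )
    pid = [f"p{i+1:04d}" for i in range(n)]

    def _measures(prefix, prim, per):
        # measures group consecutive DVs within a primary-factor block
        out = []
        counters: dict = {}
        for j in prim:
            k = counters.get(j, 0)
            out.append(f"{prefix}_measure_{j+1}_{k // per + 1}")
            counters[j] = k + 1
        return out

    measures = (
        _measures("task", prim_t, cfg.task.dvs_per_measure)
        + _measures("survey", prim_s, cfg.survey.dvs_per_measure)
    )
    meta = pd.DataFrame(
        {
            "measure": measures,
            "category": ["task"] * m_t + ["survey"] * m_s,
        },
        index=pd.Index(dv_names, name="dv_name"),
    )
    dvm = DVMatrix(pd.DataFrame(X, index=pid, columns=dv_names), meta)
    gt = GroundTruth(
        loadings=pd.DataFrame(L, index=dv_names, columns=factor_names),
        phi=phi,
        reliability=pd.Series(rel, index=dv_names),
        specific_sd=pd.Series(s_sd, index=dv_names),
        cluster_labels=pd.Series(
            np.concatenate([prim_t + 1, prim_s + 1 + ft]), index=dv_names
        ),
        factor_scores=pd.DataFrame(F, index=pid, columns=factor_names),
        specific_scores=Xi,
        session_noise_sd=pd.Series(e_sd, index=dv_names),
        factor_names=factor_names,
    )
    return dvm, gt


def generate_retest(
    cfg: GeneratorConfig, gt: GroundTruth, battery: DVMatrix
) -> RetestPair:
    """Second session: traits and specifics fixed, session noise redrawn."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    n, m = battery.data.shape
    E2 = rng.standard_normal((n, m))
    X2 = (
        gt.factor_scores.to_numpy() @ gt.loadings.to_numpy().T
        + gt.specific_scores * gt.specific_sd.to_numpy()
        + E2 * gt.session_noise_sd.to_numpy()
    )
    t2 = DVMatrix(
        pd.DataFrame(X2, index=battery.data.index, columns=battery.data.columns),
        battery.meta.copy(),
    )
    ids = list(battery.data.index)
    subset = sorted(rng.choice(n, size=cfg.n_retest, replace=False))
    shared = [ids[i] for i in subset]
    return RetestPair(
        t1=battery.select_participants(shared),
        t2=t2.select_participants(shared),
        shared_ids=shared,
    )


def generate_covariates(cfg: GeneratorConfig, participant_ids) -> CovariateTable:
    rng = np.random.default_rng([cfg.seed, 2])
    ids = list(participant_ids)
    tab = pd.DataFrame(
        {
            "age": rng.uniform(18, 65, size=len(ids)),
            "sex": rng.integers(0, 2, size=len(ids)).astype(float),
        },
        index=ids,
    )
    return CovariateTable(tab)


def default_outcome_B(cfg: GeneratorConfig) -> np.ndarray:
    """Sparse survey-factor -> latent-target coefficient matrix."""
    rng = np.random.default_rng([cfg.seed, 3])
    fs = cfg.survey.n_factors
    oc = cfg.outcomes
    B = np.zeros((fs, oc.n_latent))
    for k in range(oc.n_latent):
        nd = min(oc.n_driving_factors, fs)
        drivers = rng.choice(fs, size=rng.integers(1, nd + 1), replace=False)
        B[drivers, k] = rng.uniform(*oc.coef_range, size=len(drivers)) * rng.choice(
            [-1.0, 1.0], size=len(drivers)
        )
    return B


def generate_outcomes(
    gt: GroundTruth,
    cfg: GeneratorConfig,
    covariates: CovariateTable,
    B: np.ndarray | None = None,
) -> tuple[DVMatrix, GroundTruth]:
    """Outcome DV matrix driven by survey factors at the configured R^2.

    Each latent target t_k is the survey-factor combination B_k scaled so
    its population R^2 (after covariate residualization) equals the
    configured target, plus age/sex effects; outcome DVs load on one latent
    target each. Returns the outcome battery and the ground truth updated
    with B, latent targets and the planted R^2 profile.
    """
    cfg.validate()
    oc = cfg.outcomes
    rng = np.random.default_rng([cfg.seed, 4])
    Fs = gt.survey_factor_scores()
    ids = list(Fs.index)
    n = len(ids)
    fs = Fs.shape[1]
    if B is None:
        B = default_outcome_B(cfg)
    B = np.asarray(B, dtype=float)
    if B.shape != (fs, oc.n_latent):
        raise ConfigError(f"B must be {fs} x {oc.n_latent}")
    # survey-factor block of the joint correlation matrix
    ft = sum(1 for c in gt.factor_names if c.startswith("task"))
    phi_s = gt.phi[ft:, ft:]
    r2 = np.asarray(oc.target_r2, dtype=float)
    signal_var = np.einsum("jk,jl,lk->k", B, phi_s, B)
    if np.any((r2 > 0) & (signal_var <= 0)):
        raise ConfigError("target R^2 > 0 with zero-signal coefficient column")
    scale = np.sqrt(np.where(signal_var > 0, r2 / np.maximum(signal_var, 1e-12), 0.0))
    signal = Fs.to_numpy() @ (B * scale)          # var = r2 per column
    latent = signal + rng.standard_normal((n, oc.n_latent)) * np.sqrt(1.0 - r2)

    cov = covariates.aligned_to(ids)
    z_age = (cov["age"] - cov["age"].mean()).to_numpy()
    z_age = z_age / max(z_age.std(ddof=1), 1e-12)
    z_sex = (cov["sex"] - cov["sex"].mean()).to_numpy()
    sd_sex = z_sex.std(ddof=1)
    z_sex = z_sex / max(sd_sex, 1e-12) if sd_sex > 0 else z_sex
    latent_obs = latent + np.outer(z_age, np.full(oc.n_latent, oc.age_beta)) \
        + np.outer(z_sex, np.full(oc.n_latent, oc.sex_beta))

    m_o = oc.n_latent * oc.dvs_per_latent
    names = [
        f"outcome_dv{k+1}_{j+1}" for k in range(oc.n_latent)
        for j in range(oc.dvs_per_latent)
    ]
    X = np.zeros((n, m_o))
    col = 0
    for k in range(oc.n_latent):
        for _ in range(oc.dvs_per_latent):
            u = rng.uniform(*oc.loading_range)
            X[:, col] = u * latent_obs[:, k] + np.sqrt(1 - u**2) * \
                rng.standard_normal(n)
            col += 1
    meta = pd.DataFrame(
        {
            "measure": [f"outcome_scale_{k+1}" for k in range(oc.n_latent)
                        for _ in range(oc.dvs_per_latent)],
            "category": "outcome",
        },
        index=pd.Index(names, name="dv_name"),
    )
    dvm = DVMatrix(pd.DataFrame(X, index=ids, columns=names), meta)
    gt.outcome_B = B * scale
    gt.outcome_latents = pd.DataFrame(
        latent, index=ids, columns=[f"target_{k+1}" for k in range(oc.n_latent)]
    )
    gt.outcome_r2 = r2
    return dvm, gt
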