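"""Parametric empirical Bayes over subject DCM posteriors, Bayesian model
reduction, greedy pruning, model averaging and split-sample replication.

The hierarchical model treats each subject's nine A-matrix posterior means
as Gaussian observations of group effects,

    mu_i = (x_i kron I_9) beta + eps_i,   eps_i ~ N(0, Sigma_i + exp(-gamma) I),

where x_i is the subject's row of the between-subject design (a column of
ones for the group mean plus mean-centred covariates: QIDS, HADS-A, age,
sex, site, current-MDE), Sigma_i the subject's Laplace covariance and
exp(gamma) a between-subject random-effects precision with a standard-normal
prior on gamma. For fixed gamma the posterior over the 63 group effects is
closed-form; gamma is optimized against the free energy. Reduced models
(effects switched off by collapsing their prior variance) are scored
analytically by Bayesian model reduction without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

N_APARAMS = 9
COVARIATES = ("mean", "qids", "hads_a", "age", "sex", "site", "mde")

#: name of the depression-sensitive connection within the 9 A-parameters
#: (order matches dcm.A_OFF + self connections)
A_PARAM_NAMES = (
    "a_vis<-vs",
    "a_vis<-mpfc",
    "a_vs<-vis",
    "a_vs<-mpfc",
    "a_mpfc<-vis",
    "a_mpfc<-vs",
    "a_self_vis",
    "a_self_vs",
    "a_self_mpfc",
)
MPFC_TO_VS_INDEX = 3  # a_vs<-mpfc


@dataclass
class PEBDesign:
    """Between-subject design: ones + mean-centred covariates."""

    X: np.ndarray
    columns: tuple[str, ...] = COVARIATES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design must be 2-D")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be all ones")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column labels do not match the design width")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_cov(self) -> int:
        return self.X.shape[1]


def _code_covariate(covariates: pd.DataFrame, name: str) -> np.ndarray:
    v = covariates[name]
    if name == "sex":
        return np.where(v.astype(str) == "F", 0.5, -0.5)
    if name == "site":
        return np.where(v.astype(str) == "A", 0.5, -0.5)
    if name == "mde":
        return (v.astype(str) == "current").astype(float)
    return v.to_numpy(dtype=float)


def build_design(
    covariates: pd.DataFrame, columns=COVARIATES[1:], drop_degenerate: bool = False
) -> PEBDesign:
    """Design matrix from a covariate table; everything after the intercept
    is mean-centred, with sex/site coded +-0.5 and MDE as current vs not.

    With ``drop_degenerate`` columns that are constant after coding (e.g. no
    currently depressed subject in a small subsample) are omitted rather
    than producing a rank-deficient design.
    """
    n = len(covariates)
    cols = [np.ones(n)]
    labels = ["mean"]
    for name in columns:
        x = _code_covariate(covariates, name)
        if drop_degenerate and np.ptp(x) == 0:
            continue
        cols.append(x - x.mean())
        labels.append(name)
    return PEBDesign(X=np.column_stack(cols), columns=tuple(labels))


@dataclass
class PEBResult:
    mean: np.ndarray  # (n_cov * 9,) group effects, covariate-major
    cov: np.ndarray
    prior_mean: np.ndarray
    prior_cov: np.ndarray
    free_energy: float
    gamma: float  # log between-subject precision
    design: PEBDesign
    effect_names: tuple[str, ...] = field(default_factory=tuple)

    def effect(self, covariate: str, param: str | int) -> tuple[float, float]:
        """(posterior mean, posterior sd) of one covariate x parameter effect."""
        idx = self.effect_index(covariate, param)
        return float(self.mean[idx]), float(np.sqrt(self.cov[idx, idx]))

    def effect_index(self, covariate: str, param: str | int) -> int:
        c = self.design.columns.index(covariate)
        p = param if isinstance(param, int) else A_PARAM_NAMES.index(param)
        return c * N_APARAMS + p


def _default_effect_priors(design: PEBDesign, subject_prior_var: np.ndarray) -> np.ndarray:
    """Diagonal prior variances: commonalities inherit the subject-level
    prior; covariate effects are shrunk by a further factor 16."""
    v = []
    for c in range(design.n_cov):
        scale = 1.0 if c == 0 else 1.0 / 16.0
        v.append(subject_prior_var * scale)
    return np.concatenate(v)


DEFAULT_SUBJECT_PRIOR_VAR = np.array([1.0 / 16.0] * 6 + [1.0 / 64.0] * 3)


def peb_fit(
    subject_means: np.ndarray,
    subject_covs: np.ndarray,
    design: PEBDesign,
    prior_var: np.ndarray | None = None,
    gamma_prior: tuple[float, float] = (0.0, 1.0),
) -> PEBResult:
    """Fit the group model; returns posteriors over all covariate effects.

    ``subject_means`` is (n, 9) and ``subject_covs`` (n, 9, 9). The free
    energy is the Laplace-approximate log evidence at the optimal
    between-subject log-precision gamma.
    """
    mus = np.asarray(subject_means, dtype=float)
    covs = np.asarray(subject_covs, dtype=float)
    n, d = mus.shape
    if d != N_APARAMS:
        raise ValueError(f"expected {N_APARAMS} parameters per subject")
    if design.n_subjects != n:
        raise ValueError("design rows must match the number of subjects")
    if np.linalg.matrix_rank(design.X) < design.n_cov:
        raise np.linalg.LinAlgError("between-subject design is rank deficient")
    pv = (
        _default_effect_priors(design, DEFAULT_SUBJECT_PRIOR_VAR)
        if prior_var is None
        else np.asarray(prior_var, dtype=float)
    )
    nb = design.n_cov * d
    B0inv = np.diag(1.0 / pv)
    g_mu, g_var = gamma_prior

    def evidence(gamma: float):
        P = B0inv.copy()
        h = np.zeros(nb)
        quad = 0.0
        logdets = 0.0
        for i in range(n):
            Vi = covs[i] + np.exp(-gamma) * np.eye(d)
            Vinv = np.linalg.inv(Vi)
            x = design.X[i]
            # X_i = kron(x, I_d); accumulate without forming dense kron
            XtV = np.kron(x[:, None], Vinv)  # (n_cov*d, d)
            P += np.kron(np.outer(x, x), Vinv)
            h += XtV @ mus[i]
            quad += mus[i] @ Vinv @ mus[i]
            s, ld = np.linalg.slogdet(2 * np.pi * Vi)
            logdets += ld
        m = np.linalg.solve(P, h)
        _, ldP = np.linalg.slogdet(P)
        ldB0 = np.sum(np.log(pv))
        logev = -0.5 * (logdets + quad - h @ m + ldB0 + ldP)
        logev += -0.5 * (gamma - g_mu) ** 2 / g_var - 0.5 * np.log(2 * np.pi * g_var)
        return logev, m, P

    res = minimize_scalar(
        lambda g: -evidence(g)[0], bounds=(-4.0, 10.0), method="bounded",
        options={"xatol": 1e-3},
    )
    gamma = float(res.x)
    F, m, P = evidence(gamma)
    cov = np.linalg.inv(P)
    cov = 0.5 * (cov + cov.T)
    names = tuple(f"{c}:{p}" for c in design.columns for p in A_PARAM_NAMES)
    return PEBResult(
        mean=m,
        cov=cov,
        prior_mean=np.zeros(nb),
        prior_cov=np.diag(pv),
        free_energy=float(F),
        gamma=gamma,
        design=design,
        effect_names=names,
    )


def bmr_reduce(
    post_mean: np.ndarray,
    post_cov: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    red_prior_mean: np.ndarray,
    red_prior_cov: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Bayesian model reduction: evidence change and posterior under a
    reduced prior, computed analytically from the full Gaussian posterior.

    Returns ``(delta_F, reduced_mean, reduced_cov)`` where ``delta_F`` is the
    log-evidence of the reduced model minus that of the full model.
    """
    m = np.asarray(post_mean, float)
    S = np.asarray(post_cov, float)
    m0 = np.asarray(prior_mean, float)
    S0 = np.asarray(prior_cov, float)
    m0r = np.asarray(red_prior_mean, float)
    S0r = np.asarray(red_prior_cov, float)
    P = np.linalg.inv(S)
    P0 = np.linalg.inv(S0)
    P0r = np.linalg.inv(S0r)
    Pr = P + P0r - P0
    sign, _ = np.linalg.slogdet(Pr)
    if sign <= 0:
        raise np.linalg.LinAlgError("reduced precision is not positive definite")
    hr = P @ m + P0r @ m0r - P0 @ m0
    mr = np.linalg.solve(Pr, hr)
    Sr = np.linalg.inv(Pr)

    def ld(M):
        return np.linalg.slogdet(M)[1]

    delta_f = 0.5 * (
        ld(P) - ld(Pr) + ld(P0r) - ld(P0)
        + hr @ mr
        - (m @ P @ m + m0r @ P0r @ m0r - m0 @ P0 @ m0)
    )
    return float(delta_f), mr, 0.5 * (Sr + Sr.T)


OFF_VAR = 1e-8  # prior variance of a switched-off effect


def _reduced_prior(peb: PEBResult, off: frozenset[int]):
    pv = np.diag(peb.prior_cov).copy()
    pm = peb.prior_mean.copy()
    idx = sorted(off)
    pv[idx] = OFF_VAR
    pm[idx] = 0.0
    return pm, np.diag(pv)


@dataclass
class ReducedModel:
    off: frozenset[int]
    delta_f: float
    mean: np.ndarray
    cov: np.ndarray


def score_reduced(peb: PEBResult, off: frozenset[int]) -> ReducedModel:
    pm, pc = _reduced_prior(peb, off)
    dF, mr, Sr = bmr_reduce(peb.mean, peb.cov, peb.prior_mean, peb.prior_cov, pm, pc)
    return ReducedModel(off=off, delta_f=dF, mean=mr, cov=Sr)


def greedy_search(peb: PEBResult, candidates: list[int] | None = None) -> list[ReducedModel]:
    """Iteratively prune group effects that do not pay for themselves.

    At each sweep every remaining effect is evaluated (weakest first, by
    |posterior mean| / sd) and switched off whenever doing so does not lower
    the free energy. The returned model set contains the final pruned model
    plus its single-effect neighbours with their evidences, ready for
    Bayesian model averaging. Deterministic given the fitted PEB.
    """
    nb = peb.mean.size
    candidates = list(range(nb)) if candidates is None else list(candidates)
    off: frozenset[int] = frozenset()
    current = score_reduced(peb, off)
    changed = True
    while changed:
        changed = False
        sd = np.sqrt(np.diag(current.cov))
        strength = np.abs(current.mean) / np.maximum(sd, 1e-12)
        for e in sorted((c for c in candidates if c not in off), key=lambda c: strength[c]):
            cand = score_reduced(peb, off | {e})
            if cand.delta_f >= current.delta_f:
                off = off | {e}
                current = cand
                changed = True
    models = [current]
    for e in candidates:
        if e in off:
            neigh = off - {e}
        else:
            neigh = off | {e}
        models.append(score_reduced(peb, frozenset(neigh)))
    return models


@dataclass
class BMAResult:
    mean: np.ndarray
    cov: np.ndarray
    p_nonzero: np.ndarray
    weights: np.ndarray
    models: list[ReducedModel]

    def effect_summary(self, peb: PEBResult, covariate: str, param: str | int):
        idx = peb.effect_index(covariate, param)
        return float(self.mean[idx]), float(self.p_nonzero[idx])


def bma(models: list[ReducedModel]) -> BMAResult:
    """Evidence-weighted average of reduced-model posteriors.

    Weights are softmax of the model evidences; the mixture covariance adds
    the between-model spread. ``p_nonzero[k]`` is the summed weight of models
    in which effect k remains switched on.
    """
    if not models:
        raise ValueError("need at least one model")
    f = np.array([m.delta_f for m in models])
    w = np.exp(f - f.max())
    w /= w.sum()
    nb = models[0].mean.size
    mean = sum(wi * m.mean for wi, m in zip(w, models))
    cov = sum(wi * (m.cov + np.outer(m.mean - mean, m.mean - mean)) for wi, m in zip(w, models))
    p_on = np.zeros(nb)
    for wi, m in zip(w, models):
        on = np.ones(nb)
        on[sorted(m.off)] = 0.0
        p_on += wi * on
    return BMAResult(mean=mean, cov=cov, p_nonzero=p_on, weights=w, models=models)


def split_sample_replication(
    subject_means: np.ndarray,
    subject_covs: np.ndarray,
    covariates: pd.DataFrame,
    n_splits: int = 100,
    seed: int | np.random.Generator | None = None,
    covariate: str = "qids",
    param: int | str = MPFC_TO_VS_INDEX,
    design_columns=COVARIATES[1:],
) -> dict:
    """Split-sample bootstrap of one covariate effect.

    The cohort is split into two disjoint halves ``n_splits`` times (the
    first half larger by one when the cohort size is odd); a PEB model
    (without model reduction) is fitted per half with covariates re-centred
    within the half, and the sign of the requested effect recorded. Returns
    the proportion of negative halves and the per-half effect values.
    """
    n = subject_means.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subjects for split-sample replication")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        halves = (perm[: (n + 1) // 2], perm[(n + 1) // 2 :])
        for idx in halves:
            sub = covariates.iloc[idx]
            design = build_design(sub, columns=design_columns, drop_degenerate=True)
            res = peb_fit(subject_means[idx], subject_covs[idx], design)
            val, _ = res.effect(covariate, param)
            values.append(val)
    values = np.asarray(values)
    return {
        "proportion_negative": float(np.mean(values < 0)),
        "values": values,
        "n_models": int(values.size),
    }
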