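"""Hierarchical empirical-Bayes fitting and iBIC model comparison.

Subjects are fitted by MAP estimation under a Gaussian group prior in the
unconstrained parameter space; the prior itself is estimated by
expectation-maximization over the cohort (E-step: per-subject MAP plus
Laplace covariance; M-step: moment-matching of the prior mean and
variance). Models are scored with the integrated BIC: the group marginal
likelihood is estimated by Monte-Carlo sampling from the fitted prior and
penalized by the number of prior parameters times the log of the total
number of likelihood-bearing (choice) trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import rl
from .rl import MODELS, RLModelSpec


class FitError(RuntimeError):
    """All optimizer restarts failed to converge."""


@dataclass
class GroupPrior:
    """Diagonal Gaussian empirical prior over transformed parameters."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have the same shape")
        if np.any(self.sigma2 <= 0):
            raise ValueError("prior variances must be positive")

    @property
    def n_params(self) -> int:
        return self.mu.size


@dataclass
class SubjectFit:
    theta_map: np.ndarray
    laplace_cov: np.ndarray
    log_posterior: float
    marginal_loglik: float
    n_ll_evals: int
    converged: bool = True


@dataclass
class ModelComparison:
    ibic: dict[int, float]
    winner: int
    subject_logliks: dict[int, np.ndarray]
    priors: dict[int, GroupPrior] = field(default_factory=dict)
    fits: dict[int, list[SubjectFit]] = field(default_factory=dict)


def _subject_arrays(subject):
    trials = subject.trials if hasattr(subject, "trials") else subject
    if isinstance(trials, tuple):
        return trials
    return rl.trials_to_arrays(trials)


def _neg_log_posterior(theta, arrays, model, prior):
    try:
        nll, g = rl.negative_log_likelihood(arrays, model, theta, with_grad=True)
    except FloatingPointError:
        # line searches can probe numerically hopeless points; steer back
        return 1e12, -theta
    d = theta - prior.mu
    return nll + 0.5 * np.sum(d * d / prior.sigma2), g + d / prior.sigma2


def _numeric_hessian(fun_grad, theta, h=1e-4):
    p = theta.size
    H = np.zeros((p, p))
    for k in range(p):
        e = np.zeros(p)
        e[k] = h
        _, gp = fun_grad(theta + e)
        _, gm = fun_grad(theta - e)
        H[:, k] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_map(
    subject,
    model: RLModelSpec,
    prior: GroupPrior,
    n_restarts: int = 5,
    seed: int | np.random.Generator | None = None,
    x0: np.ndarray | None = None,
) -> SubjectFit:
    """MAP estimate of one subject's transformed parameters.

    Minimizes ``NLL(theta) - log N(theta; mu, diag(sigma2))`` by L-BFGS with
    ``n_restarts`` jittered starting points; the Laplace covariance is the
    inverse Hessian at the optimum and ``marginal_loglik`` the corresponding
    Laplace estimate of the subject's marginal likelihood.
    """
    if prior.n_params != model.n_params:
        raise ValueError("prior dimension does not match the model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = _subject_arrays(subject)

    def fg(theta):
        return _neg_log_posterior(theta, arrays, model, prior)

    sd = np.sqrt(prior.sigma2)
    starts = [prior.mu if x0 is None else np.asarray(x0, dtype=float)]
    starts += [prior.mu + sd * rng.standard_normal(model.n_params) for _ in range(max(0, n_restarts - 1))]
    best = None
    n_evals = 0
    for start in starts:
        res = minimize(fg, start, jac=True, method="L-BFGS-B", options={"gtol": 1e-6, "maxiter": 200})
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("all restarts failed")

    H = _numeric_hessian(fg, best.x)
    # guard against indefinite numerical Hessians
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, 1e-6)
    cov = (V / w) @ V.T
    p = model.n_params
    log_post = -best.fun - 0.5 * np.sum(np.log(2 * np.pi * prior.sigma2))
    sign, logdet = np.linalg.slogdet(cov)
    marginal = log_post + 0.5 * p * np.log(2 * np.pi) + 0.5 * logdet
    return SubjectFit(
        theta_map=best.x,
        laplace_cov=cov,
        log_posterior=float(log_post),
        marginal_loglik=float(marginal),
        n_ll_evals=int(n_evals),
        converged=bool(best.success),
    )


def _pooled_mle(arrays_list, model, rng, n_restarts=3):
    """Single parameter vector maximizing the summed likelihood (EM init)."""

    def fg(theta):
        tot, g = 0.0, np.zeros(model.n_params)
        for arr in arrays_list:
            nll, gi = rl.negative_log_likelihood(arr, model, theta, with_grad=True)
            tot += nll
            g += gi
        # weak ridge keeps the pooled fit away from the boundary
        return tot + 0.005 * theta @ theta, g + 0.01 * theta

    best = None
    for k in range(n_restarts):
        x0 = np.zeros(model.n_params) if k == 0 else rng.standard_normal(model.n_params)
        res = minimize(fg, x0, jac=True, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def em_group_fit(
    cohort,
    model: RLModelSpec,
    max_iter: int = 40,
    tol: float = 1e-3,
    n_restarts: int = 2,
    seed: int | np.random.Generator | None = None,
    init_prior: GroupPrior | None = None,
) -> tuple[GroupPrior, list[SubjectFit]]:
    """Empirical-Bayes EM over a cohort; returns the fitted prior and fits.

    M-step moment matching: ``mu = mean(theta_map)`` and
    ``sigma2 = mean(theta_map^2 + diag(cov)) - mu^2`` floored at 1e-4.
    Convergence when ``max |delta mu| < tol``; on non-convergence the last
    iterate is returned with a warning.
    """
    if len(cohort) < 2:
        raise ValueError("EM needs at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays_list = [_subject_arrays(s) for s in cohort]
    if init_prior is not None:
        prior = init_prior
    else:
        prior = GroupPrior(mu=_pooled_mle(arrays_list, model, rng), sigma2=np.ones(model.n_params))
    fits: list[SubjectFit] = []
    warm: list[np.ndarray | None] = [None] * len(arrays_list)
    for it in range(max_iter):
        k_restarts = n_restarts if it == 0 else 1
        fits = [
            fit_map(arr, model, prior, n_restarts=k_restarts, seed=rng, x0=w)
            for arr, w in zip(arrays_list, warm)
        ]
        warm = [f.theta_map for f in fits]
        thetas = np.array([f.theta_map for f in fits])
        variances = np.array([np.diag(f.laplace_cov) for f in fits])
        mu = thetas.mean(axis=0)
        sigma2 = np.maximum((thetas**2 + variances).mean(axis=0) - mu**2, 1e-4)
        delta = np.max(np.abs(mu - prior.mu))
        prior = GroupPrior(mu=mu, sigma2=sigma2)
        if delta < tol:
            break
    else:
        warnings.warn("EM did not converge; returning last iterate", RuntimeWarning)
    return prior, fits


def ibic(
    cohort,
    model: RLModelSpec,
    prior: GroupPrior,
    n_mc_samples: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Integrated BIC of a model for a cohort under a fitted group prior.

    ``-2 sum_i log[(1/K) sum_k exp(-NLL_i(theta_k))] + m log |D|`` with
    ``theta_k`` sampled from the prior, ``m = 2 * n_params`` prior parameters
    (mean and variance each) and ``|D|`` the total choice-trial count.
    Returns the score and the per-subject marginal log-likelihood estimates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays_list = [_subject_arrays(s) for s in cohort]
    K = int(n_mc_samples)
    theta = prior.mu + np.sqrt(prior.sigma2) * rng.standard_normal((K, prior.n_params))
    logliks = np.empty(len(arrays_list))
    n_choice_total = 0
    for i, arr in enumerate(arrays_list):
        cond, _, _, missed = arr
        n_choice_total += int(np.sum((cond == 0) & ~missed))
        nll = rl.nll_batch(arr, model, theta)
        # log-mean-exp of -nll, guarded against underflow
        mx = (-nll).max()
        logliks[i] = mx + np.log(np.mean(np.exp(-nll - mx)))
    penalty = 2 * model.n_params * np.log(max(n_choice_total, 1))
    return float(-2.0 * logliks.sum() + penalty), logliks


def compare_models(
    cohort,
    model_set=(1, 2, 3, 4, 5),
    seed: int | np.random.Generator | None = None,
    n_mc_samples: int = 2000,
    em_kwargs: dict | None = None,
) -> ModelComparison:
    """Fit each candidate model hierarchically and rank them by iBIC."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    em_kwargs = em_kwargs or {}
    scores: dict[int, float] = {}
    logliks: dict[int, np.ndarray] = {}
    priors: dict[int, GroupPrior] = {}
    all_fits: dict[int, list[SubjectFit]] = {}
    for mid in model_set:
        model = MODELS[mid] if not isinstance(mid, RLModelSpec) else mid
        prior, fits = em_group_fit(cohort, model, seed=rng, **em_kwargs)
        score, ll = ibic(cohort, model, prior, n_mc_samples=n_mc_samples, seed=rng)
        scores[model.model_id] = score
        logliks[model.model_id] = ll
        priors[model.model_id] = prior
        all_fits[model.model_id] = fits
    winner = min(scores, key=scores.get)
    return ModelComparison(ibic=scores, winner=winner, subject_logliks=logliks, priors=priors, fits=all_fits)
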