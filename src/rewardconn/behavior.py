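"""Behavioural statistics: rank correlation, Welch's t and a default
Bayes factor for the presence/absence of a correlation."""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from .task import CHOICE


def _as_vec(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and t-approx p."""
    x, y = _as_vec(x), _as_vec(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x, y = _as_vec(x), _as_vec(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("both groups have zero variance")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def default_bf_correlation(x, y) -> float:
    """Default Bayes factor BF10 for a Pearson correlation.

    Tests rho != 0 against the point null using Jeffreys' approximation to
    the likelihood of the sample correlation,

        p(r | rho, n)  proportional to  (1 - rho^2)^((n-1)/2) (1 - rho r)^((3 - 2n)/2),

    integrated numerically under a uniform(-1, 1) prior on rho (the kappa=1
    stretched-beta of the standard "default" test). BF10 < 1 is evidence for
    the absence of a correlation.
    """
    x, y = _as_vec(x), _as_vec(y)
    n = x.size
    if n != y.size or n < 4:
        raise ValueError("need equal-length vectors with >= 4 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return bf10_from_r(r, n)


def bf10_from_r(r: float, n: int) -> float:
    """BF10 from a sample Pearson correlation and sample size (quadrature)."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")

    def log_lik(rho):
        return 0.5 * (n - 1) * np.log1p(-rho**2) + 0.5 * (3 - 2 * n) * np.log1p(-rho * r)

    ref = log_lik(0.0)  # = 0, kept explicit for clarity

    def integrand(rho):
        return 0.5 * np.exp(log_lik(rho) - ref)

    val, err = integrate.quad(integrand, -1.0, 1.0, limit=200)
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * max(val, 1.0):
        raise FloatingPointError("Bayes factor integration failed")
    return float(val)


def summarize_behavior(subject) -> tuple[int, int]:
    """(number of rewarded trials, number of missed trials) for a session."""
    trials = subject.trials if hasattr(subject, "trials") else subject
    n_rewards = sum(1 for t in trials if not t.missed and t.outcome == 1)
    n_missed = sum(1 for t in trials if t.missed)
    return n_rewards, n_missed


def choice_trial_accuracy(subject) -> float:
    """Fraction of non-missed choice trials on which the high arm was taken."""
    trials = subject.trials if hasattr(subject, "trials") else subject
    sel = [t for t in trials if t.condition == CHOICE and not t.missed]
    if not sel:
        return float("nan")
    return float(np.mean([t.action == "high" for t in sel]))
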