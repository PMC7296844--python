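"""Reinforcement-learning models of choice/no-choice reward learning.

Five Rescorla-Wagner variants encode competing hypotheses about how people
learn when they do versus do not control the decision:

* model 1 - learns from choice outcomes only (single alpha, single rho)
* model 2 - learns from all outcomes (single alpha, single rho)
* model 3 - separate learning rates for choice / no-choice outcomes
* model 4 - separate reward sensitivities for choice / no-choice outcomes
* model 5 - both learning rates and sensitivities split

Q-values track sensitivity-scaled expected reward, ``rpe = rho * r - q[a]``
and ``q[a] += alpha * rpe``. The policy is a softmax over the two rho-scaled
Q-values at unit temperature, so rho doubles as the effective inverse
temperature (the identifiable parameterization for binary rewards). Fitting
happens in an unconstrained space: logit for learning rates, log for
sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .task import CHOICE, HIGH, LOW, TrialRecord

# Expanded parameter order used by the likelihood kernels:
#   0 alpha_choice, 1 alpha_nochoice, 2 rho_choice, 3 rho_nochoice
_EXPANDED = 4

ACTIONS = (HIGH, LOW)
ACTION_INDEX = {HIGH: 0, LOW: 1}


@dataclass(frozen=True)
class RLModelSpec:
    """Structure of one of the five learning models."""

    model_id: int
    learns_from_no_choice: bool
    split_learning_rate: bool
    split_sensitivity: bool

    @property
    def n_params(self) -> int:
        return 2 + int(self.split_learning_rate) + int(self.split_sensitivity)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["alpha_choice", "alpha_nochoice"] if self.split_learning_rate else ["alpha"]
        names += ["rho_choice", "rho_nochoice"] if self.split_sensitivity else ["rho"]
        return tuple(names)

    @property
    def alias_matrix(self) -> np.ndarray:
        """(4, n_params) map from free transformed params to the expanded set."""
        M = np.zeros((_EXPANDED, self.n_params))
        if self.split_learning_rate:
            M[0, 0] = 1.0
            M[1, 1] = 1.0
            r0 = 2
        else:
            M[0, 0] = 1.0
            M[1, 0] = 1.0
            r0 = 1
        if self.split_sensitivity:
            M[2, r0] = 1.0
            M[3, r0 + 1] = 1.0
        else:
            M[2, r0] = 1.0
            M[3, r0] = 1.0
        return M


MODELS: dict[int, RLModelSpec] = {
    1: RLModelSpec(1, learns_from_no_choice=False, split_learning_rate=False, split_sensitivity=False),
    2: RLModelSpec(2, learns_from_no_choice=True, split_learning_rate=False, split_sensitivity=False),
    3: RLModelSpec(3, learns_from_no_choice=True, split_learning_rate=True, split_sensitivity=False),
    4: RLModelSpec(4, learns_from_no_choice=True, split_learning_rate=False, split_sensitivity=True),
    5: RLModelSpec(5, learns_from_no_choice=True, split_learning_rate=True, split_sensitivity=True),
}


def logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-np.asarray(p, dtype=float))


def expit(x: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit as _expit

    return _expit(x)


def _expand_theta(theta: np.ndarray, model: "RLModelSpec"):
    """Free transformed vector -> expanded natives, without range validation
    (the optimizer may probe extreme values; clip to keep exp finite)."""
    ex = np.clip(model.alias_matrix @ np.asarray(theta, dtype=float), -60.0, 60.0)
    return float(expit(ex[0])), float(expit(ex[1])), float(np.exp(ex[2])), float(np.exp(ex[3]))


@dataclass
class RLParams:
    """Native-space parameters; shared parameters are aliased per model."""

    alpha_choice: float
    alpha_nochoice: float
    rho_choice: float
    rho_nochoice: float

    def __post_init__(self) -> None:
        for a in (self.alpha_choice, self.alpha_nochoice):
            if not 0.0 < a < 1.0:
                raise ValueError("learning rates must lie in (0, 1)")
        for r in (self.rho_choice, self.rho_nochoice):
            if r <= 0:
                raise ValueError("reward sensitivities must be positive")

    @classmethod
    def from_theta(cls, theta: np.ndarray, model: RLModelSpec) -> "RLParams":
        """Map an unconstrained free vector to native space."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (model.n_params,):
            raise ValueError(f"model {model.model_id} expects {model.n_params} parameters")
        ex = model.alias_matrix @ theta
        return cls(
            alpha_choice=float(expit(ex[0])),
            alpha_nochoice=float(expit(ex[1])),
            rho_choice=float(np.exp(ex[2])),
            rho_nochoice=float(np.exp(ex[3])),
        )

    def to_theta(self, model: RLModelSpec) -> np.ndarray:
        """Free transformed vector (logit alphas, log rhos)."""
        vals = []
        if model.split_learning_rate:
            vals += [logit(self.alpha_choice), logit(self.alpha_nochoice)]
        else:
            vals += [logit(self.alpha_choice)]
        if model.split_sensitivity:
            vals += [np.log(self.rho_choice), np.log(self.rho_nochoice)]
        else:
            vals += [np.log(self.rho_choice)]
        return np.array(vals, dtype=float)

    def expanded(self) -> tuple[float, float, float, float]:
        return (self.alpha_choice, self.alpha_nochoice, self.rho_choice, self.rho_nochoice)


def trials_to_arrays(trials: list[TrialRecord]):
    """Encode a trial list for the numeric kernels.

    condition: 0 choice / 1 no-choice; action: 0 high / 1 low; outcome -1 on
    missed trials (skipped by every kernel).
    """
    n = len(trials)
    cond = np.zeros(n, dtype=np.int64)
    action = np.zeros(n, dtype=np.int64)
    outcome = np.zeros(n, dtype=np.int64)
    missed = np.zeros(n, dtype=np.bool_)
    for i, t in enumerate(trials):
        cond[i] = 0 if t.condition == CHOICE else 1
        missed[i] = t.missed
        if t.missed:
            action[i] = 0
            outcome[i] = -1
            continue
        if t.action is None or t.outcome is None:
            raise ValueError(f"trial {t.index} has no action/outcome; simulate or load data first")
        action[i] = ACTION_INDEX[t.action]
        outcome[i] = int(t.outcome)
    return cond, action, outcome, missed


@njit(cache=True)
def _nll_grad_kernel(cond, action, outcome, missed, ac, anc, rc, rnc, learns_nc):
    """NLL over choice trials and its gradient w.r.t. the 4 expanded
    transformed parameters (logit alpha_c, logit alpha_nc, log rho_c, log rho_nc)."""
    q = np.zeros(2)
    dq = np.zeros((2, 4))
    nll = 0.0
    g = np.zeros(4)
    for t in range(cond.shape[0]):
        if missed[t]:
            continue
        a = action[t]
        if cond[t] == 0:
            m = q[0] if q[0] > q[1] else q[1]
            lse = m + np.log(np.exp(q[0] - m) + np.exp(q[1] - m))
            nll += lse - q[a]
            p0 = np.exp(q[0] - lse)
            p1 = np.exp(q[1] - lse)
            for k in range(4):
                g[k] += p0 * dq[0, k] + p1 * dq[1, k] - dq[a, k]
            alpha = ac
            rho = rc
            ai = 0
            ri = 2
        else:
            if not learns_nc:
                continue
            alpha = anc
            rho = rnc
            ai = 1
            ri = 3
        r = outcome[t]
        rpe = rho * r - q[a]
        for k in range(4):
            dq[a, k] = (1.0 - alpha) * dq[a, k]
        dq[a, ai] += alpha * (1.0 - alpha) * rpe
        dq[a, ri] += alpha * rho * r
        q[a] += alpha * rpe
    return nll, g


def negative_log_likelihood(
    trials, model: RLModelSpec, params: RLParams | np.ndarray, with_grad: bool = False
):
    """Negative log likelihood of the observed choices.

    Only choice trials contribute (no-choice actions are forced); Q-values
    are propagated through every non-missed outcome according to the model's
    update rule. ``params`` may be native :class:`RLParams` or a free
    transformed vector; the gradient (if requested) is in transformed space.
    """
    if isinstance(trials, tuple):
        cond, action, outcome, missed = trials
    else:
        cond, action, outcome, missed = trials_to_arrays(trials)
    if isinstance(params, RLParams):
        ac, anc, rc, rnc = params.expanded()
    else:
        ac, anc, rc, rnc = _expand_theta(np.asarray(params, dtype=float), model)
    nll, g4 = _nll_grad_kernel(
        cond, action, outcome, missed, ac, anc, rc, rnc, model.learns_from_no_choice
    )
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite likelihood at valid parameters")
    if with_grad:
        return nll, model.alias_matrix.T @ g4
    return nll


def nll_batch(trials, model: RLModelSpec, theta_batch: np.ndarray) -> np.ndarray:
    """Vectorized NLL for a batch of free transformed parameter vectors.

    Used by Monte-Carlo marginal-likelihood estimation; propagates Q-values
    for all K samples simultaneously.
    """
    cond, action, outcome, missed = (
        trials if isinstance(trials, tuple) else trials_to_arrays(trials)
    )
    theta_batch = np.atleast_2d(np.asarray(theta_batch, dtype=float))
    ex = np.clip(theta_batch @ model.alias_matrix.T, -60.0, 60.0)  # (K, 4)
    AC = expit(ex[:, 0])
    ANC = expit(ex[:, 1])
    RC = np.exp(ex[:, 2])
    RNC = np.exp(ex[:, 3])
    K = theta_batch.shape[0]
    q = np.zeros((K, 2))
    nll = np.zeros(K)
    for t in range(cond.shape[0]):
        if missed[t]:
            continue
        a = action[t]
        if cond[t] == 0:
            m = np.maximum(q[:, 0], q[:, 1])
            lse = m + np.log(np.exp(q[:, 0] - m) + np.exp(q[:, 1] - m))
            nll += lse - q[:, a]
            alpha, rho = AC, RC
        else:
            if not model.learns_from_no_choice:
                continue
            alpha, rho = ANC, RNC
        q[:, a] += alpha * (rho * outcome[t] - q[:, a])
    return nll


@dataclass
class QState:
    """Q-value bookkeeping for the two stimuli (index 0 high, 1 low)."""

    q: np.ndarray

    @classmethod
    def initial(cls) -> "QState":
        return cls(q=np.zeros(2))


def update_q(
    qstate: QState,
    action: str,
    outcome: int,
    condition: str,
    params: RLParams,
    model: RLModelSpec,
) -> tuple[QState, float]:
    """One Rescorla-Wagner update; returns the new state and the RPE.

    For model 1 on no-choice trials the state is left untouched but the RPE
    is still reported so that fMRI regressors cover every outcome event.
    """
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    a = ACTION_INDEX[action]
    is_choice = condition == CHOICE
    alpha = params.alpha_choice if is_choice else params.alpha_nochoice
    rho = params.rho_choice if is_choice else params.rho_nochoice
    rpe = rho * outcome - qstate.q[a]
    q = qstate.q.copy()
    if is_choice or model.learns_from_no_choice:
        q[a] += alpha * rpe
    return QState(q=q), float(rpe)


def choice_prob(qstate: QState) -> float:
    """Probability of selecting the high-probability stimulus.

    Softmax over the two rho-scaled Q-values at unit temperature.
    """
    q = np.asarray(qstate.q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("Q-values must be finite")
    d = q[0] - q[1]
    return float(expit(d))


def rpe_series(
    trials: list[TrialRecord],
    model: RLModelSpec,
    params: RLParams,
    zero_nochoice_rpe: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Reward-prediction-error value per non-missed outcome event.

    Returns ``(onsets, rpes)`` aligned to outcome onsets. With
    ``zero_nochoice_rpe`` model 1 reports 0 on no-choice trials instead of
    the non-updating surprise term.
    """
    qs = QState.initial()
    onsets, rpes = [], []
    for t in trials:
        if t.missed:
            continue
        qs, rpe = update_q(qs, t.action, t.outcome, t.condition, params, model)
        if (
            zero_nochoice_rpe
            and t.condition != CHOICE
            and not model.learns_from_no_choice
        ):
            rpe = 0.0
        onsets.append(t.outcome_onset)
        rpes.append(rpe)
    return np.asarray(onsets), np.asarray(rpes)
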