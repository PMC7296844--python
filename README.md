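# rewardconn

Reinforcement-learning behaviour modelling, model-based fMRI analysis and
effective-connectivity group inference for choice/no-choice probabilistic
reward tasks — exercised end to end on synthetic cohorts.

## The scientific problem

Depressive symptom severity has repeatedly been linked to blunted reward
signals in the striatum, and more recently to weakened top-down influence
of the medial prefrontal cortex (mPFC) on the ventral striatum during
reward learning. Testing that chain of claims requires a long pipeline:

1. **Behaviour.** Subjects play 66 trials of a two-armed probabilistic
   reward task (80%/20% win rates, 100 points per win). A cue announces
   whether the subject chooses freely ("choice") or follows the computer
   ("no-choice"). Five Rescorla–Wagner variants encode hypotheses about
   learning with and without control over the decision; with Q-update
   `q[a] += α_c (ρ_c r − q[a])` and a softmax policy over ρ-scaled values,
   the models differ in whether α and ρ are split by condition and whether
   no-choice outcomes are learned from at all.
2. **Fitting and comparison.** Subjects are fitted by MAP under an
   empirical-Bayes group prior (estimated by EM); models are compared with
   the integrated BIC,
   `iBIC = −2 Σᵢ log ⟨exp(−NLLᵢ(θ))⟩_{θ∼prior} + 2p·log|D|`,
   where `|D|` counts choice trials.
3. **Model-based fMRI.** Reward-prediction errors from the winning model
   become parametric modulators in an event-related GLM (canonical
   double-gamma HRF, 16 microtime bins per TR), with cluster-extent
   thresholds calibrated by Monte-Carlo simulation of smooth Gaussian
   fields.
4. **Effective connectivity.** A bilinear three-region DCM (visual cortex,
   ventral striatum, mPFC; `dx/dt = (A + Σ uⱼBⱼ)x + Cu`, balloon–Windkessel
   hemodynamics) is inverted per subject by variational Laplace. Subjects
   whose model explains <10% of the ROI variance are excluded.
5. **Group inference.** The nine A-matrix posteriors enter a parametric-
   empirical-Bayes model against a between-subject design (mean + centred
   QIDS depression score, HADS-A anxiety, age, sex, site, current-MDE).
   Bayesian model reduction with a greedy search prunes effects, Bayesian
   model averaging combines the surviving models, and split-sample
   bootstrap replication checks the sign stability of the QIDS effect on
   the mPFC→striatum connection.

Raw data for the motivating study design are access-controlled, so the
package ships a first-class synthetic-cohort generator (`rewardconn.synth`)
that emulates the task, the covariate structure and a planted
connectivity–symptom effect (mPFC→striatum coupling decreasing with
depression severity, no visual→striatum or striatum→mPFC coupling), and
every analysis stage is validated by recovery of what was planted.

## Worked example

```python
import numpy as np
from rewardconn import synth, hierfit, rl, behavior

cohort = synth.generate_cohort(80, model=3, seed=7)          # simulate
prior, fits = hierfit.em_group_fit(cohort, rl.MODELS[3], seed=0)
alpha_c  = rl.expit(np.array([f.theta_map[0] for f in fits]))
alpha_nc = rl.expit(np.array([f.theta_map[1] for f in fits]))
print(f"population means (native): alpha_choice={rl.expit(prior.mu[0]):.2f} "
      f"alpha_nochoice={rl.expit(prior.mu[1]):.2f} rho={np.exp(prior.mu[2]):.2f}")
print(f"subjects with faster choice learning: {np.mean(alpha_c > alpha_nc):.0%}")

comp = hierfit.compare_models(cohort, model_set=[1, 2, 3], seed=0)
print("iBIC:", {k: round(v, 1) for k, v in comp.ibic.items()},
      "-> winner: model", comp.winner)

qids = [s.qids for s in cohort]
rewards = [behavior.summarize_behavior(s)[0] for s in cohort]
rho, p = behavior.spearman(qids, rewards)
bf = behavior.default_bf_correlation(qids, rewards)
print(f"Spearman(QIDS, rewards) = {rho:.3f} (P = {p:.3f}), BF10 = {bf:.3f}")
```

prints

```
population means (native): alpha_choice=0.37 alpha_nochoice=0.28 rho=3.36
subjects with faster choice learning: 70%
iBIC: {1: 2476.5, 2: 2384.8, 3: 2374.5} -> winner: model 3
Spearman(QIDS, rewards) = -0.044 (P = 0.700), BF10 = 0.157
```

Read: the cohort was simulated from model 3 (condition-specific learning
rates) and the iBIC comparison selects model 3; fitted learning rates are
faster on free-choice trials for most subjects; depression scores are
unrelated to rewards earned (the Bayes factor favours the null), so any
imaging correlate is not a performance artefact.

The command line exposes the same stages
(`rewardconn simulate|fit-behavior|compare-models|glm|fit-dcm|peb|replicate|all`,
each taking `--config`, `--seed`, `--out-dir`); `rewardconn all` runs a
demo cohort end to end and writes `results.json`.

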