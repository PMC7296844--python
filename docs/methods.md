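# Methods

`rewardconn` implements, end to end on synthetic cohorts, the computational
analysis of a choice/no-choice probabilistic reward learning task studied
with event-related fMRI: reinforcement-learning models of behaviour fitted by
hierarchical empirical Bayes and compared by integrated BIC; model-based GLM
regressors built from reward-prediction errors; a bilinear three-region
dynamic causal model (visual cortex, ventral striatum, medial prefrontal
cortex) inverted by variational Laplace; parametric-empirical-Bayes group
inference over the endogenous connectivity with Bayesian model reduction,
greedy pruning and model averaging; and split-sample replication of the
depression-severity effect on the mPFC-to-striatum connection.

## Task model

Each session has 66 trials, 33 free-choice and 33 forced ("no-choice"),
interleaved at random. The two stimuli pay 100 points with probability 0.8
(high arm) and 0.2 (low arm). Trials unfold as cue (2 s), decision window
(3 s) and outcome display (1.5 s), separated by uniform jitter. Two pacing
variants exist:

* the default `TaskConfig` uses jitter U(2, 6) s; a 66-trial session then
  needs ~1220 s, so the default session length is 840 scans at TR 1.56 s;
* `TaskConfig.compact()` uses jitter U(1, 2) s so that 66 trials fit within
  500 scans (780 s); imaging-length simulations use this variant.

A `miss_rate` option produces missed trials (no response, no outcome, a
nuisance regressor in the GLM); the simulator emits none by default.

## Learning models

Five Rescorla-Wagner variants share the update
`rpe = rho_c * r - q[a]`, `q[a] += alpha_c * rpe`, with `r in {0, 1}` and
condition-specific parameters: model 1 updates on choice outcomes only;
model 2 on all outcomes with a single learning rate `alpha` and reward
sensitivity `rho`; model 3 splits `alpha` by condition; model 4 splits
`rho`; model 5 splits both. The policy is a softmax over the two rho-scaled
Q-values at unit temperature: because rewards are binary, `rho` doubles as
the effective inverse temperature, which is the identifiable
parameterization; `q0 = 0` for both stimuli. Model 1 still reports RPEs on
no-choice outcomes (without updating) so fMRI regressors cover every
outcome event; an option zeroes them instead. Fitting is unconstrained:
logit for learning rates, log for sensitivities. The choice likelihood is
accumulated over non-missed choice trials only — forced actions carry no
information — while Q-values propagate through all non-missed outcomes.
The four outcome input channels used later by the DCM (reward, no-reward,
choice-outcome, no-choice-outcome indicators) are exactly collinear
(reward + no-reward = choice + no-choice), so driving weights on them are
identified only up to that null direction; analyses use identifiable
combinations.

## Hierarchical fitting and model comparison

Subjects are fitted by MAP under a diagonal Gaussian group prior in the
transformed space (L-BFGS with the analytic likelihood gradient; jittered
restarts; Laplace covariance from a central-difference Hessian of the
negative log posterior). The prior is estimated by
expectation-maximization: E-step MAP + Laplace covariance per subject
(warm-started across iterations), M-step moment matching
`mu = mean(theta_map)`, `sigma2 = mean(theta_map^2 + diag(cov)) - mu^2`
floored at 1e-4, stopping when `max |delta mu| < 1e-3` or 40 iterations.
Initialization: pooled maximum likelihood for `mu`, unit variances.

The integrated BIC of a model is
`-2 sum_i log[(1/K) sum_k exp(-NLL_i(theta_k))] + 2 p log |D|` with
`theta_k` drawn from the fitted prior (K = 2000 by default, seeded), `2p`
prior parameters (a mean and a variance per model parameter) and `|D|` the
total number of likelihood-bearing (choice) trials in the cohort. The
winner minimizes iBIC.

Two statistical limits of this design are worth stating because they are
properties of the data, not the code. First, with 66 trials per subject the
population *means* of the learning rates are weakly determined: the
maximum-marginal-likelihood estimate itself has a sampling error around 0.3
logits at n = 100 (and at `rho ~ 1` the alpha/rho likelihood ridge lets the
ML optimum sit far from the generating means), so tests assert that the EM
solution attains at least the marginal likelihood of the generating
hyperparameters rather than proximity of the learning-rate means. Second,
per-subject learning-rate estimates carry substantial shrinkage; rank
(Spearman) recovery of ~0.5-0.7 against the simulated truth is the realistic
ceiling at this trial count.

## Behavioural statistics

Spearman correlations use average ranks for ties with the t-approximation
for p-values; group comparisons use Welch's unequal-variance t-test. The
"default" Bayes factor for a Pearson correlation integrates Jeffreys'
approximate likelihood of the sample correlation,
`p(r | rho, n) ∝ (1 - rho^2)^((n-1)/2) (1 - rho r)^((3-2n)/2)`, under a
uniform(-1, 1) prior on rho (the kappa = 1 stretched beta of the default
test) by adaptive quadrature, against the point null. At `r = 0`, `n = 475`
this yields BF10 ~ 0.057, i.e. the evidence-for-absence band between 1/30
and 1/10.

## GLM

Event trains are truncated delta functions at 16 microtime bins per TR,
convolved with the canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 6, 32 s support, no
derivatives) and downsampled to the scan grid. The categorical first-level
design has 2 cue, 4 outcome (reward/no-reward x choice/no-choice), 2
response and 1 nuisance column plus 6 motion covariates; the modulated
variant replaces the outcome block by one all-outcomes column plus a
parametric modulator (binary reward or model-derived RPE) mean-centred
before convolution. Event types with no occurrences are omitted rather than
producing all-zero regressors. Estimation is OLS; second-level inference
correlates first-level contrasts with symptom scores across subjects
(Spearman).

Cluster-extent thresholds are calibrated by Monte Carlo: white Gaussian
fields on the grid are smoothed (sigma = FWHM/2.355 per axis, truncated
edges with per-voxel variance renormalization), thresholded two-sided at
the voxel p, and the largest 26-connected cluster recorded; the extent is
the ceiling of the (1 - FWE p) quantile. On a 64 x 64 x 32 grid of 3.4 mm
voxels with 8 mm smoothing (voxel p < .05, FWE p < .001) the threshold
lands within a factor of two of the ~131-voxel extent expected for this
acquisition geometry; an exact match is not expected because the in-brain
mask of a real analysis covers fewer voxels than the full grid. ROI series
are the first principal component over voxels, sign-aligned to a positive
mean loading and scaled to unit variance.

## Dynamic causal model

Neural dynamics are bilinear with one state per region,
`dx/dt = (A + sum_j u_j B_j) x + C u`, self-connections `-0.5 exp(a_ii)`.
Inputs (8 channels): the four outcome types drive the visual region and
modulate all nine connections; the two cue types drive the visual region;
button presses (brief 0.3 s motor events) drive all three regions. All
channels are mean-centred so A reads as average effective connectivity.
Hemodynamics are the balloon-Windkessel cascade per region (kappa = 0.64,
gamma = 0.32, alpha = 0.32, E0 = 0.4, V0 = 4) with only a log transit-time
deviation estimated (prior N(0, 1/256)). Shrinkage priors: off-diagonal A
and B ~ N(0, 1/16), log self-scaling ~ N(0, 1/64), C ~ N(0, 1), noise
log-precision ~ N(4, 1).

Integration uses Heun's method (explicit trapezoid) at dt = TR/16. A
fixed-step Euler scheme at the same grid was rejected because its
step-halving error (~4% RMS on planted dynamics) exceeds the 1% target;
Heun meets it at double the per-step cost.

Inversion is variational Laplace: damped Gauss-Newton updates of the
posterior mean with a forward-difference Jacobian, closed-form Gaussian
posterior covariance, and Newton updates of the iid-noise log-precision.
Candidate steps are accepted only if they increase the free energy, so the
recorded free-energy trace is non-decreasing. Two optimizer-level devices
deal with the pronounced multi-modality of this objective (a zero start
reliably reaches a basin whose free energy is 30-100 nats below the best
one, with a sign-flipped mPFC-to-visual coupling and a spurious
striatum-to-mPFC coupling):

* graduated noise annealing — the noise precision starts four log-units
  below its running estimate and is released over the first iterations,
  smoothing the early objective;
* cohort-level basin sharing (`invert_cohort`) — subjects are processed
  sequentially while a pool of discovered solutions (full parameter
  vectors, keyed by the sign pattern of the endogenous couplings) is
  shared; the first subjects additionally explore random sign-pattern
  restarts polished without annealing (with modulatory terms reset to
  zero), and a final pass re-offers the cohort's winning solutions to
  every subject. Sharing whole vectors matters: drives and hemodynamic
  parameters carried over from another basin re-attract the polish into
  that basin. Per subject the highest-free-energy solution wins. This
  mirrors group-informed re-initialization practices in hierarchical DCM
  fitting.

Explained variance is `100 (1 - ||y - g||^2 / ||y - mean||^2)`; subjects
below 10% are excluded from group analysis, and a Welch test of QIDS
between included and excluded subjects is reported with the filter.

## Group inference (PEB)

Subject-level posteriors over the nine A-parameters enter a hierarchical
Gaussian model `mu_i = (x_i ⊗ I_9) beta + eps_i`,
`eps_i ~ N(0, Sigma_i + exp(-gamma) I)`, where `x_i` is the row of the
between-subject design (ones, then mean-centred QIDS, HADS-A, age, sex,
site, current-MDE; sex/site coded ±0.5). For fixed `gamma` the posterior
over the 63 group effects is conjugate; `gamma ~ N(0, 1)` is optimized
against the evidence by bounded scalar search. This treats the subject
posterior means as observations with their Laplace covariances — a
deliberate simplification of full hierarchical schemes that additionally
subtract the first-level prior; with the shrinkage priors used here the
difference is small and the formulation is numerically robust. Group-effect
priors: commonality columns inherit the subject-level prior variances;
covariate columns are shrunk by a further factor 16.

Bayesian model reduction computes the evidence change and posterior of any
reduced prior (effects switched off by collapsing their prior variance to
1e-8) analytically from the full Gaussian posterior. The greedy search
sweeps effects weakest-first (|posterior mean|/SD), switching off any whose
removal does not lower the free energy, until a sweep changes nothing; the
final model set (pruned model plus single-effect neighbours) is combined by
evidence-weighted Bayesian model averaging, with `P(effect != 0)` the summed
weight of models retaining it.

Split-sample replication repeatedly halves the cohort (disjoint halves, the
first larger by one when odd), refits the PEB model per half with
covariates re-centred within the half (covariates constant within a half
are dropped), and reports the proportion of halves with a negative QIDS
effect on the mPFC-to-striatum connection. Note that all halves of one
cohort share that cohort's sampling noise, so under a null effect the
*within-cohort* proportion is strongly overdispersed; sign symmetry (~0.5)
holds only when halves are pooled over independent cohorts, which is how
the null behaviour is verified.

## Synthetic cohorts

The generator plays the role of the study population and fixes the
conditions under which every recovery claim is evaluated.

* Behaviour: transformed parameters are Gaussian around population means
  (model 3: learning rates 0.45 / 0.20 in native space, log-sensitivity
  log 3) with learning-rate logit-SD ~1.2 — wide heterogeneity of the kind
  seen in community samples — and log-sensitivity SD 0.5. These moments
  produce ~80% high-arm accuracy and, after fitting, ~90% of subjects with
  faster choice-than-forced learning, matching the qualitative pattern
  reported for the real cohort. An optional per-parameter slope on centred
  QIDS plants parameter-symptom effects (zero by default).
* Covariates: QIDS is negative-binomial (shape 2, mean 4.5, truncated to
  0-27, right-skewed); HADS-A follows a latent Gaussian correlated ~0.5
  with QIDS; age ~ N(58, 9); sex and site are balanced binary; MDE status
  ("current" ~4%, "past" ~23%) tracks a noisy QIDS ranking so that
  diagnosis correlates with severity as in the clinical table.
* Imaging: each subject's BOLD is generated by the same DCM forward model
  used for inversion. The planted endogenous matrix has no visual-to-
  striatum and no striatum-to-mPFC coupling; striatum-to-visual -0.35,
  mPFC-to-visual +0.35, visual-to-mPFC +0.3; and mPFC-to-striatum
  0.3 - 0.03 x centred QIDS, the planted depression effect. Feedback
  magnitudes of 0.35 Hz were chosen so that every planted connection is
  detectably nonzero at the simulated SNR, emulating a network whose
  connections the group analysis should find decisively present (as the
  real cohort's were); modulatory effects are zero in the generator.
  Observation noise is white Gaussian with SD = signal SD / SNR (SNR 1 by
  default, explained variance of the true model ~50%).
* `synthetic_a_posteriors` is a synthetic stand-in for subject-level
  inversion output (truth + between-subject SD 0.05 + posterior SD 0.08,
  isotropic Laplace covariance) used to exercise group-level machinery at
  desk scale without forward-model integration.

What passing tests on these cohorts show — and do not show. They establish
that each stage recovers what it is supposed to recover when its own
generative assumptions hold at realistic noise levels. Real data add model
mismatch the generator does not emulate: scanner drift and physiological
noise, hemodynamic variability beyond transit time, head motion,
non-Gaussian symptom distributions tied to behaviour, and task engagement
effects. Sign-stability results at n = 40 are a scaled-down analogue of the
published n = 165 analysis, not a reproduction of its effect sizes.

## Problem sizes and determinism

Recovery studies use the sizes at which their claims are stated: 50-subject
cohorts (20 seeds) for model recovery, 100 subjects for parameter recovery,
40 subjects at 500 scans and SNR 1 for connectivity sign recovery, 100
splits (200 PEB fits) for the planted split-sample check and 20 x 5 splits
for its pooled null. Every stochastic routine takes a seed or Generator;
fixed seeds make schedules, simulations and Monte-Carlo thresholds
bit-reproducible.

## Known limitations

* The exact policy link (and any lapse/bias terms) of the original
  behavioural analysis is not public; the softmax-on-scaled-Q link is a
  reasoned default, so fitted sensitivities are comparable only within this
  package.
* The PEB free energy omits the Laplace correction for the gamma
  hyperparameter (a constant-order term that does not affect comparisons
  within a fit).
* Driving weights on the four outcome channels are identified only up to
  their exact collinearity (see above).
* The variational objective is multi-modal; the cohort-sharing optimizer
  makes wrong-basin solutions rare but cannot guarantee global optima, and
  for a minority of subjects at SNR 1 the weak feedback connections are
  genuinely ambiguous (their global optimum sits near zero).
* Voxel-level analyses use small synthetic grids; real-image spatial
  preprocessing, anatomical masking and whole-brain inference are out of
  scope.
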