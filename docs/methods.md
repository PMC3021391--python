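# Methods

`motordcm` implements a complete bilinear dynamic-causal-modelling (DCM)
analysis chain for a four-region frontal motor network — dorsolateral
prefrontal cortex (PFC), lateral premotor cortex (PM), pre-supplementary
motor area (preSMA) and primary motor cortex (M1) — in the context of an
action-selection task ("specified" button presses cued externally vs.
"chosen" presses selected by the subject). This note records the models,
the numerical choices, and the design decisions made where the design was
genuinely open.

## Model space

Forty-eight models are enumerated as six intrinsic-connectivity structures
(A–F) crossed with eight contextual-modulation patterns (1–8). The
anatomical skeleton is five region pairs (PFC–PM, PFC–preSMA, PM–preSMA,
PM–M1, preSMA–M1; deliberately no direct PFC–M1 edge). Structure sets A/B
use only the rostro-caudal (feed-forward) member of each pair; C–F close
all five pairs bidirectionally (10 directed intrinsic connections). Sets
B, D and F add the chosen-vs-specified difference as a second driving
input to PFC. Sets C/D modulate only the forward member of each modulated
pair; E/F modulate both directions — so C-models are nested in their
E-counterparts. Patterns 1–4 modulate single pairs (PFC–PM, PFC–preSMA,
PM–M1, preSMA–M1 respectively), 5 the rostral pairs, 6 the caudal pairs,
7 rostral+caudal, 8 all five pairs including the lateral PM–preSMA link.
The assignment of patterns 3 vs 4 to the two caudal pairs, and the
direction of the lateral link in the unidirectional skeleton
(preSMA→PM), are conventions; both tables are module-level data and the
forward-edge list is an argument of `build_model`.

All matrices use the DCM convention `A[target, source]`. Inhibitory
self-connections sit implicitly on the diagonal of the effective coupling
matrix at a fixed −0.5 /s and are never counted as user-specified
parameters; model E2 therefore has 10 + 2 + 1 free connectivity
parameters.

## Forward model

Neural states follow the bilinear equation
`dz/dt = (A_eff + u2·B) z + C u`, with `u1` the 1-s go-cue box-car of any
non-null trial and `u2` the chosen-trial context. Each region's activity
drives a balloon model (vasodilatory signal, inflow, venous volume,
deoxyhemoglobin; kappa = 0.64 /s, gamma = 0.32 /s, tau = 2 s,
alpha = 0.32, E0 = 0.32, V0 = 0.04 — canonical values, all configurable)
and BOLD percent signal change is read out through the standard two-term
observation equation (k1 = 7E0, k2 = 2, k3 = 2E0 − 0.2).

**Temporal support of the contextual input.** The chosen-vs-specified
context is a cognitive state of the trial rather than a transient
stimulus, so `u2` stays on for the full trial cycle (one SOA, 2.5 s) of a
chosen trial by default (`u2_span="trial"`); restricting it to the 1-s
cue (`u2_span="cue"`) is supported. This choice matters: with cue-limited
modulation windows, contextual coupling changes of the size studied here
(0.05–0.06 Hz) are essentially undetectable at realistic noise levels,
and model comparison degenerates to a complexity contest won by the
smallest model. A mean-centred ±½ coding of `u2` is available
(`center_u2`); the default is the 0/1 indicator.

Integration is fixed-step explicit RK4 on a 0.1-s microtime grid with
inputs held piecewise-constant per step; flow, volume and dHb are
integrated in log space so they stay positive. A numba kernel evaluates
batches of parameter vectors in one call (this is what makes
finite-difference Jacobians cheap); a pure-numpy reference implementation
of the same scheme is kept and tested for equality at 1e-9, and the
integrator is checked against a tight-tolerance adaptive solver and
against step-halving (relative error ~1e-7, far inside the 1e-3
acceptance band; an Euler scheme at this step size would not pass, which
is why RK4 was chosen).

## Inversion

One (session, model) pair is inverted by variational Laplace: a Gaussian
posterior over the masked A/B/C entries plus log-scaling factors on kappa
and tau, and one noise log-precision per region updated by EM (ML-II,
floored/capped for safety). Priors are zero-mean with variance 1/16 (A,
B), 1/32 (C) and 1/64 (hemodynamic log-scalings). The free energy is
accuracy minus complexity, with accuracy the expected log-likelihood
under the posterior and complexity the KL divergence of posterior from
prior; the identity `F = accuracy − complexity` holds by construction and
on a conjugate linear-Gaussian problem F equals the closed-form log
evidence to ~1e-13 nats (the variational bound is tight there).

Gauss–Newton steps use central finite-difference Jacobians (step 1e-4)
evaluated in a single batched forward call; Levenberg-style damping on
the curvature is increased by decades on rejected steps and relaxed on
accepted ones; convergence is declared when an accepted step improves F
by less than 1e-2 nats (at most 64 iterations; non-convergence is flagged
and the last iterate returned). A constant and a linear drift are
projected out of data and predictions before the likelihood, with the
corresponding reduction of the effective degrees of freedom. The
accepted-iteration F trace is monotone non-decreasing and exposed via
`free_energy_curve`.

Posterior covariance over the connectivity block is normalised to a
correlation matrix by `posterior_correlation` (13×13 for E2: 78 unique
off-diagonal elements); zero-variance parameters yield flagged NaNs.

## Group model selection

Fixed effects: per-model summed log evidence over sessions (the group
Bayes factor on the log scale), ΔF against the best model, and softmax
posterior model probabilities under a uniform model prior. Bayes factors
are categorised by the conventional bands (3–20 positive, 20–150 strong,
>150 very strong; log-evidence differences 1.1–3, 3–5, >5).

Random effects: the hierarchical Dirichlet model fitted by the standard
variational loop (responsibilities = softmax of F plus digamma terms;
Dirichlet counts = prior alpha 1 + summed responsibilities), with
exceedance probabilities from 1e5 seeded Dirichlet draws and their
Monte-Carlo standard errors. A Gibbs sampler for the same hierarchical
model is provided as an independent cross-check; the variational fixed
point agrees with it to <0.02 when session evidence is decisive or
symmetric. When evidence is diffuse the mean-field factorisation is
systematically sharper than the exact posterior (deviations up to ~0.08
on 5-subject toys, confirmed against brute-force integration over the
simplex); this is a property of the standard algorithm, not an
implementation error, and the Gibbs route is the reference when it
matters. Rows are subject-sessions by default; an option averages
sessions within subject.

## Synthetic cohorts

`default_study_config` reproduces the study structure: 28 young adults
(one session), 15 older controls (two sessions, labels A/B randomly
assigned per subject), 16 PD patients (on/off medication, order permuted
within blocks of six), 90 sessions; sessions of 150 volumes at TR 2 s
with 40 specified + 40 chosen + 40 null trials at SOA 2.5 s in seeded
random order. Controls and patients-on generate from model E2
(modulation of PFC↔preSMA), patients-off from E1 (modulation of
PFC↔PM) — the medial-to-lateral shift under dopamine withdrawal.

Group-mean parameters: driving input 0.10 Hz to PFC (0.09 for the young
group); bilinear terms 0.06 (forward) and 0.05 (reciprocal) on the
modulated pair. The intrinsic couplings are a heterogeneous rostro-caudal
hierarchy — strong feed-forward (PFC→PM 0.45, PFC→preSMA 0.45,
PM→preSMA 0.35, PM→M1 0.20, preSMA→M1 0.20 Hz) and weak feedback
(0.05 Hz elsewhere). Three considerations fix this shape: couplings are
demonstrably heterogeneous across connections in this network; strongly
reciprocal couplings are dynamically unstable against the fixed −0.5 /s
self-decay, whereas a feed-forward hierarchy is stable at realistic
coupling sizes; and convergent drive onto preSMA is what renders the
feedback (preSMA→PFC) modulation — the feature separating E2 from its
nested forward-only competitor C2 — identifiable at all.

Subjects draw each parameter from the group mean with between-subject
SD 0.05 Hz; each session adds within-subject jitter SD 0.02 Hz; draws are
rejected unless the resting coupling matrix decays with margin 0.05 /s
and the fully modulated configuration is non-expanding, and a session
whose switched dynamics nevertheless diverge is redrawn (bounded,
logged) — eigenvalue tests on the individual configurations do not rule
out divergence of a switched system. Observation noise is i.i.d.
Gaussian per region (optional AR(1)), scaled per region to a target
time-series SNR of 2 (noiseless signal SD over noise SD), mirroring
per-ROI eigenvariate series whose scale is region-specific. All
randomness descends from one master seed through named `SeedSequence`
substreams, so any subset of the cohort is reproducible in isolation.

What the generator does not emulate: voxel-level data and eigenvariate
extraction, physiological (cardiac/respiratory) noise, motion artefacts,
session-to-session hemodynamic drift, and any disease effect on
neurovascular coupling. Passing tests therefore demonstrate
self-consistency of the analysis chain under the stated generative
assumptions, not performance on real fMRI.

## Reliability battery

Cross-session Pearson (reported as r²) and Spearman correlations per
parameter; a sign-preservation chi-squared test
(`2(n_same − n/2)²/(n/2)`, df 1) whose printed values follow half-up
rounding to one decimal (so 2.25 → 2.3); a split-plot ANOVA with group
between subjects and session × connection within (hand-implemented —
no installed Python package covers one between + two within factors —
and validated against R `aov` to 4 significant figures on a frozen
fixture, including unequal group sizes; Greenhouse–Geisser correction
optional); element-wise one-sample t-tests on per-subject posterior
correlation matrices with Bonferroni correction over the unique
off-diagonal elements and the fraction of negative elements; and the
Spearman agreement of group-mean matrices between sessions. The B/A
ratio is computed with a guard (undefined when |A| < 1e-6) and
one-sample Kolmogorov–Smirnov normality checks run against a normal with
the sample's mean and SD.

## Problem sizes used in validation

The acceptance checks run the selection properties at the study's own
size — the 15-subject two-session control arm and the 16-patient off-
medication arm — rather than a reduced roster: batched-Jacobian
inversion takes ~2–3 s per (session, model) pair, so the full arms
complete in a few minutes and small-cohort runs were observed to be
dominated by subject-draw luck. Parameter recovery uses 20 single-session
subjects; the noise-robustness comparison uses ten two-session subjects
at five-fold noise against a structurally distinct alternative (A2).
At the default conditions, the recovered-vs-true bilinear correlation is
~0.8–0.85 across 20 subjects, while the between-session correlation of
the same parameter within subjects is low (~0.3) and collapses at
five-fold noise even as group model selection still identifies the
generating model — selection is more robust than parameter estimation,
which is the pipeline's central qualitative behaviour.

## Known limitations

- Evidence differences between E2 and its nested forward-only competitor
  C2 are intrinsically small at these effect sizes (the KL cost of the
  extra identified parameter nearly cancels its accuracy gain), so
  random-effects selection between them can ride on a handful of
  strong-modulation subjects in any single cohort.
- The variational RFX point estimate is sharper than the exact posterior
  for diffuse evidence (see above); use `rfx_gibbs` when calibrated
  probabilities matter.
- Hemodynamic estimation is restricted to global log-scalings of kappa
  and tau; per-region hemodynamics are not estimated.
- The EM noise update is ML-II without a hyperprior; with noiseless data
  the precision is capped rather than regularised.
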