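# motordcm

Bilinear dynamic causal modelling (DCM) of effective connectivity in a
four-region frontal motor network, built for studying how action
*selection* (freely chosen vs. externally specified movements) reshapes
coupling between dorsolateral prefrontal cortex (PFC), lateral premotor
cortex (PM), the pre-supplementary motor area (preSMA) and primary motor
cortex (M1) — and how reliably such analyses behave across repeated
sessions, in health and in Parkinson's disease on and off dopaminergic
medication.

The package is aimed at methodologists and clinical-neuroimaging groups
who want a fully testable, self-contained version of this analysis chain:
every stage can be exercised end-to-end on synthetic cohorts with known
ground truth, without any imaging data.

## What it implements

- **Model space** — 48 bilinear DCMs: six intrinsic-connectivity
  structures (unidirectional or bidirectional closure of five anatomical
  region pairs, with or without a contextual driving input) crossed with
  eight patterns of contextual modulation. Model E2, for example, has ten
  intrinsic connections, two bilinear terms (PFC↔preSMA) and one driving
  input.
- **Generative model** — bilinear neural dynamics
  `dz/dt = (A + u2·B) z + C u` coupled to the balloon hemodynamic model,
  integrated by batched fixed-step RK4 (numba-accelerated) and sampled as
  noisy BOLD percent signal change.
- **Inversion** — variational Laplace / EM: Gaussian posterior over masked
  connectivity parameters and hemodynamic scalings, per-region noise
  precisions, and the negative free energy
  `F = accuracy − complexity` (complexity = KL of posterior from prior)
  as the log-evidence bound. Exact on conjugate linear-Gaussian problems.
- **Group Bayesian model selection** — fixed effects (summed log
  evidence / group Bayes factors with the conventional 3–20–150 evidence
  bands) and random effects (hierarchical Dirichlet model: variational
  fit, expected posterior probabilities, Monte-Carlo exceedance
  probabilities, plus an independent Gibbs-sampling reference).
- **Reliability battery** — cross-session Pearson/Spearman correlations,
  sign-preservation chi-squared tests, split-plot ANOVA (group × session ×
  connection, validated against R `aov`), and group summaries of
  normalised posterior covariance (identifiability) matrices with
  Bonferroni-corrected t maps.
- **Synthetic cohorts** — study-shaped data with ground truth: 28 young
  adults, 15 older controls (two sessions), 16 PD patients (on/off), 150
  volumes at TR 2 s per session, 40 specified + 40 chosen + 40 null trials
  at SOA 2.5 s; controls and patients-on generate from model E2,
  patients-off from E1.

See `docs/methods.md` for the model equations, priors, numerical
tolerances and design decisions.

## Worked example

Simulate the older-control arm (15 subjects, two sessions each, ground
truth E2), invert the three leading models on every session, and compare
them at the group level (about five minutes on one CPU; seeded and fully
reproducible):

```python
from dataclasses import replace
from motordcm import (default_study_config, generate_cohort,
                      fixed_effects, random_effects, bayes_factor)
from motordcm.pipeline import invert_sessions, evidence_table

cfg = default_study_config(seed=0)
cfg = replace(cfg, groups=tuple(g for g in cfg.groups if g.label == "OC"))
sessions, truth = generate_cohort(cfg)            # 30 sessions, truth E2
results = invert_sessions(sessions, ["E2", "E1", "C2"])
table = evidence_table(results)

ffx = fixed_effects(table)
rfx = random_effects(table, seed=0)
```

This prints (via the snippet in `scripts/`-style reporting):

```
E2: summed F relative to best =    0.00
E1: summed F relative to best =  -36.44
C2: summed F relative to best =  -93.69
FFX ranking: E2 > E1 > C2
RFX expected prob: {'E2': 0.488, 'E1': 0.059, 'C2': 0.453}
RFX exceedance:   {'E2': 0.579, 'E1': 0.0, 'C2': 0.421}
group Bayes factor E2 vs E1 = 6.71e+15 (very strong evidence)
```

Reading the numbers: the generating model E2 wins the fixed-effects
comparison by 36 nats of summed log evidence over E1 (overwhelming as a
group Bayes factor) and by 94 over C2. The random-effects comparison also
ranks E2 first, but much less decisively against C2 (exceedance 0.58 vs
0.42): C2 is nested inside E2 — it lacks only the feedback
(preSMA→PFC) modulation — and at realistic effect sizes the extra
parameter's evidence contribution is small in any single subject. That
contrast between robust selection of the model family and fragile
subject-level margins (and, below the model level, poorly reliable
parameter estimates) is exactly the methodological behaviour the package
is designed to expose.

The same chain is available from the shell:

```sh
motordcm simulate --out cohort/ --seed 0 --groups OC
motordcm invert cohort/ --models E2,E1,C2 --out posteriors/   # resumable
motordcm bms posteriors/evidence.csv --group OC
motordcm reliability posteriors/ --model E2 --group OC
motordcm reproduce-study --out study/ --seed 0 --subjects 5
```

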