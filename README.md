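# dmncausal

Effective connectivity of the default-mode network (DMN) by Granger
causality, for researchers studying how the network's hubs — posterior
cingulate (PCC), medial prefrontal cortex (MPFC) and bilateral inferior
parietal cortex (IPC) — communicate with the remaining DMN nodes
(bilateral inferior temporal cortex and hippocampal formation), and how
that communication degrades in Alzheimer's-type cohorts.

Given per-subject ROI time courses (8 regions, resting-state BOLD at
TR = 2 s), the package:

1. **preprocesses** each series (discard initial volumes, linear detrend,
   ideal 0.01–0.1 Hz band-pass, global-signal regression);
2. fits, for every ordered node pair, a **bivariate VAR of order 5** by
   Fast Orthogonal Search (or OLS) and computes Geweke's directed
   measures, e.g. F_{x→y} = ln(σ²(y | own past) / σ²(y | both pasts));
3. tests each direction against **IAAFT surrogate** null distributions of
   the source series (1000 surrogates, one-sided p < 0.05);
4. assembles the significant influences into a **directed causal graph**
   and computes the hub index **D_outer/D_all** — the fraction of
   significant connections joining a hub to a non-hub;
5. compares cohorts (Welch one-tailed t-test, ANOVA) and finds the
   **ROC-optimal cutoff** (Youden's J) of the hub index for classifying
   patients (who score lower) against controls.

A first-class synthetic-cohort module generates stable VAR processes with
known hub-centric causal structure (and an "attenuated" AD-like variant),
so the full pipeline is testable end to end against exact ground truth.
ROI utilities (sphere masks, thresholded-map intersection, template
goodness-of-fit component selection, time-series extraction) support
working from volumetric maps.

## Worked example

Directed causality for one coupled pair (`y_t = 0.9·x_{t−1} + e_t`):

```python
>>> import numpy as np
>>> from dmncausal import BivariateVAR
>>> rng = np.random.default_rng(0)
>>> x = rng.normal(size=10000)
>>> e = rng.normal(size=10000)
>>> y = e.copy(); y[1:] += 0.9 * x[:-1]
>>> res = BivariateVAR(x, y, order=5).fit(method="ols")
>>> round(res.f_x_to_y, 4), round(res.f_y_to_x, 5)
(0.5883, 0.00055)
```

F_{x→y} ≈ 0.588 matches the population value ln(1.81) ≈ 0.593 for this
process (the restricted variance of y is 0.81 + 1, the full variance 1),
while F_{y→x} ≈ 0 — no information flows backwards.

The full two-cohort study (16 synthetic controls vs 15 attenuated
AD-like subjects, 295 time points, order 5, 200 surrogates per directed
pair) runs from the command line:

```bash
dmncausal all --out run_output --seed 1 --fast
```

which on this seed reports (from `run_output/report.json`):

```
hub index D_outer/D_all   control: 0.712 ± 0.027   patient: 0.635 ± 0.046
one-tailed Welch p        5.5e-06
ROC cutoff                0.650   (sensitivity 73.3%, specificity 100%)
```

The control group keeps ~71% of its significant causal traffic between
hubs and non-hubs; attenuating the MPFC/IPC couplings pulls the index
down to ~0.63, and the index separates the cohorts at a cutoff of ≈0.65.
Per-subject edge tables, causal graphs, group edge-proportion tables
(with the >80% / 60–80% / 50–60% display bands), the hub-index table and
the ROC sweep are written alongside the report. Subcommands `simulate`,
`preprocess`, `granger`, `graph`, `index` and `roc` expose the individual
stages; `dmncausal.plotting` renders the ring-layout group graphs and the
hub-index scattergram with the cutoff line.

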