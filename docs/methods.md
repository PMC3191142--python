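# Methods

`dmncausal` estimates directed (effective) connectivity between the eight
default-mode-network (DMN) nodes — PCC, MPFC, left/right IPC, left/right
ITC, left/right hippocampal formation — from resting-state BOLD time
courses, summarizes each subject as a directed causal graph, reduces the
graph to the hub index D_outer/D_all, and uses that index to discriminate
cohorts. This note records the model, the numerical choices, what the
synthetic cohorts do and do not emulate, and known limitations.

## Granger causality by bivariate VAR

For an ordered pair of series (x, y), the full model regresses each series
on p lags of both series plus an intercept; the restricted model uses own
lags only. With residual variances estimated as RSS / (T − p), Geweke's
measures are

    F_{x→y} = ln( σ²(y | own past) / σ²(y | both pasts) )
    F_{y→x} = ln( σ²(x | own past) / σ²(x | both pasts) )
    F_{x·y} = ln( σ²_f(x) σ²_f(y) / det Σ_f )

All are non-negative (nested least squares) and invariant under per-series
affine transforms. F_{x·y} (instantaneous, undirected) is computed and
reported but never used for graph edges; only the two directed measures
drive the analysis.

Choices:

* **Order p = 5** by default (inter-regional BOLD delays of roughly 8 s at
  TR = 2 s). Configurable everywhere.
* **Variance divisor** is T − p (the effective sample size), not a
  degrees-of-freedom-corrected divisor; the correction cancels in the
  ratio asymptotically and the uncorrected form keeps the nested
  inequality exact.
* **Intercept always included** in full and restricted designs, and
  force-admitted by the greedy fitter: detrending makes series nearly but
  not exactly mean-free per window.

## Fast Orthogonal Search (FOS)

The pipeline's default fitter is a greedy orthogonal search over the
candidate set {intercept, lags 1..p of both series}: at each step the
candidate giving the largest residual-sum-of-squares reduction (computed
by Gram–Schmidt orthogonalization against the admitted terms, entirely in
Gram-matrix space) is admitted, until the best *relative* reduction falls
below `mse_reduction_threshold` (default 1e-3, relative to the current
RSS) or candidates are exhausted. Un-admitted candidates get coefficient
zero; admitted coefficients are the least-squares solution on the admitted
subset. At threshold 0 FOS admits everything and equals OLS to rounding,
which the tests verify at 1e-8; OLS is retained throughout as the oracle
fitter. Because the greedy searches of the full and restricted models can
stop at different subsets, a FOS variance ratio can fall microscopically
below 1; F values are clipped at zero. Candidates whose residual norm
falls below 1e-10 of their original scale are treated as collinear and
skipped.

## IAAFT surrogate significance

The null "the source carries no temporally structured information about
the target" is represented by Iterated Amplitude Adjusted Fourier
Transform surrogates of the **source only**; the target is held fixed, so
the restricted model is untouched and the test isolates the
cross-prediction gain (replacing both is available via
`SurrogateConfig(surrogate_both=True)`). Each surrogate starts from a
random permutation and alternates (a) spectrum adjustment — impose the
original FFT amplitude on the current phases — and (b) amplitude
adjustment — rank-remap onto the original sorted values — stopping when
the rank ordering stabilizes or after 100 iterations; the last step is
always an amplitude adjustment, so the surrogate's value multiset equals
the original's exactly, and its periodogram matches to a few percent.

With n surrogates the p-value is the add-one estimator
(1 + #{F_surr ≥ F_obs}) / (1 + n), never exactly zero, and significance is
the one-sided comparison p < α. Defaults are n = 1000 and α = 0.05; the
fast profile (n = 200) resolves p at 1/201 and keeps the attainable level
at 10/201 ≈ 0.0498. Per-pair and per-subject seeds derive from a master
seed through seed-sequence spawn keys, so runs are reproducible and pairs
are independent. No correction is applied across the 56 simultaneous pair
tests of a subject — the analysis treats each directed pair as its own
test, which inflates the per-graph edge count at the nominal rate; a
warning is logged.

## Graphs, hub index, classification

Edge (s, t) is present iff the s→t test is significant. Per node, d_out
and d_in count outgoing/incoming edges; D_all is the total edge count and
D_outer counts edges with exactly one endpoint in the hub set
{PCC, MPFC, lIPC, rIPC}. The hub index is D_outer/D_all; an empty graph
yields an undefined (flagged, NaN) index rather than zero — 0/0 is not
evidence of absent hub communication — and such subjects are excluded
from group statistics with a warning. Degree conservation
(Σd_out = Σd_in = D_all) and the partition
D_all = D_outer + hub↔hub + nonhub↔nonhub hold identically and are
asserted property-style in the tests.

Group edge-proportion bands mirror the figure convention: >0.8, [0.6, 0.8],
[0.5, 0.6), <0.5 (not drawn); lower boundaries inclusive, "more than 80%"
strict.

Group comparison uses Welch's unequal-variance one-tailed t-test (the
direction being control > patient) plus a one-way ANOVA. ROC analysis
sweeps candidate thresholds (midpoints of pooled unique scores plus ±∞);
a subject is called positive (patient) when its index falls strictly
*below* the threshold, since the patient group scores lower. The optimal
cutoff maximizes Youden's J = sensitivity + specificity − 1, ties broken
by higher specificity then lower threshold (logged).

## Temporal preprocessing

Fixed order: discard the first 5 volumes → per-column linear detrend →
ideal frequency-domain band-pass (keep FFT bins with
0.01 Hz ≤ f ≤ 0.1 Hz inclusive; a projection, hence idempotent) → global
signal removal by least-squares regression on [intercept, global signal].
When no separate whole-brain series is supplied the global signal is the
mean of the ROI columns. Preprocessing defaults to on for loaded data and
off for synthetic cohorts, whose causal ground truth is defined at the
VAR level (an ideal band-pass is itself a temporal filter and would
distort lag structure).

## ROI utilities

Sphere ROIs are voxel sets whose centers lie within the radius of a peak
coordinate, distances measured between voxel centers in world (mm)
coordinates (10 mm for region extraction, 5 mm for template spheres).
ROI definition intersects a sphere with the supra-threshold group
statistical map; "exceeds" is strict. The template goodness-of-fit score
of a component map is the mean intensity inside the union of template
spheres minus the mean outside all spheres; the best-fitting component is
the arg-max, ties to the lowest index (logged). ROI time series are
unweighted voxel means per time point. NIfTI input is supported for
axis-aligned affines; the ICA decomposition itself is out of scope — the
module consumes externally produced component maps.

## Synthetic cohorts: what they emulate and what they do not

Cohorts are drawn from a stable VAR over the 8 nodes: 16 control-like and
15 patient-like subjects, 295 time points (300 acquisitions minus 5
discarded) at TR = 2 s, innovation sd 1, between-subject variability as
multiplicative Gaussian jitter (relative sd 0.1) on each edge coefficient,
truncated at 0.05 so couplings never vanish or flip sign; a jitter draw
breaking stationarity is resampled (capped at 20 attempts). Each subject
is generated by iterating the recursion after a 200-step burn-in, and the
whole cohort is a pure function of its spec including the master seed.

The control coupling is hub-centric and acyclic: the four non-hub nodes
are exogenous sources driving MPFC, lIPC and rIPC (coupling coefficient
0.4); those hubs drive each other in a fixed hierarchy
(MPFC → lIPC → rIPC); and all seven nodes converge on PCC, which sends
nothing — matching a resting-state picture in which PCC only receives
causal influence and non-hub regions do not interact directly. Every
hub↔hub and hub↔non-hub pair carries exactly one directed coupling;
non-hub pairs carry none. The AD-like variant multiplies all couplings
incident to MPFC/lIPC/rIPC by an attenuation factor (default 0.4), except
PCC-incident couplings, which are preserved — in the patient group PCC
keeps causal relations with every node while MPFC/IPC communication
degrades.

Three structural choices keep the **bivariate** ground truth identical to
the structural edge set, which is what makes exact recovery testable:
(1) all couplings act at a common lag 1, except (2) the couplings into
the PCC sink, which act at lag 3 — a sink aggregating every node at the
common lag would otherwise serve as an extra noisy sensor of each hub's
recent drivers and become a genuine bivariate Granger cause of the hubs
it never influences; and (3) non-hub sources are white (hub nodes carry
self-AR terms 0.3 and 0.1 at lags 1–2). Under heterogeneous lags or
autocorrelated shared sources, structurally absent pairs acquire real
population-level bivariate causality, which no correct pairwise method
can distinguish from true edges.

Consequently the generator emulates the *dimensions and logic* of a
resting-state study, not the physiology of BOLD: no hemodynamic
convolution by default (an optional double-gamma HRF flag exists, off,
because convolution blurs the lag structure the recovery tests rely on),
no measurement noise floor, no autocorrelated scanner drift, no spatial
structure. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model class, not robustness to
hemodynamic variability or to indirect-influence confounding in real
brains — the latter is a known limitation of bivariate Granger analysis,
not of this implementation.

## Problem sizes used by the automated checks

The validation suite runs at the study dimensions wherever feasible: null
calibration with 200 white-noise pairs × 200 surrogates (length 295,
order 5); structure recovery on a 16-subject control cohort with 200
surrogates per directed pair; cohort separation (control vs attenuation
0.4, 16 vs 15 subjects, 200 surrogates) replicated over 5 master seeds
with at least 4 required to show mean(control) > mean(patient) at
one-tailed p < 0.05. Five replicates (rather than more) is the package's
chosen balance between statistical resolution of that pass fraction and
total runtime; the per-replicate computation is identical to a full study
run. Analytic and oracle checks (Geweke closed form at T = 10000,
FOS-vs-OLS, exhaustive graph and ROC enumerations) run at the sizes
stated in the tests.

## Known limitations

* Bivariate only: no conditional/multivariate Granger causality, no
  frequency-domain decomposition. Indirect influences through unmodelled
  nodes are attributed to pairs by construction of the method.
* Surrogate significance is uncorrected across pairs (mirrored design
  choice; see above).
* The ROC cutoff is in-sample; no cross-validation or AUC confidence
  intervals.
* The ICA stage that would produce component maps for the ROI utilities
  is out of scope; only the post-ICA template-fit selection is
  implemented.
* The attenuation factor of the AD-like cohort is a free simulation
  parameter, not an estimate of a physiological effect size.
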