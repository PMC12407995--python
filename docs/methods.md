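# Methods

This note documents the statistical machinery implemented in `edgeproject`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Edge-wise discovery model

Static connectivity is the plain Pearson correlation between component
time courses; correlations are used raw by default (no Fisher z), with an
`fisher_z` switch where the windowed variant feeds clustering, because the
variance-stabilized convention is also common in connectivity pipelines.
Edges are indexed in row-major upper-triangle order (i ascending, then
j > i), components 0-based in memory and 1-based in file outputs; this
ordering is arbitrary but must be (and is) shared by every module and file
format.

Discovery fits one ordinary-least-squares model per edge: outcome on
covariates plus that edge. The implementation residualizes the outcome and
all edges against the covariate design once (thin QR; the
Frisch–Waugh–Lovell reduction) and recovers per-edge beta, SE, t, p and the
partial correlation r = sign(t)·sqrt(t²/(t²+df)) with df = n − rank(design) − 1.
This is algebraically identical to fitting each full model and is verified
against statsmodels OLS to 1e−8 in the test suite. Binary outcomes (group
comparisons) run through the same linear machinery — the t, p and partial r
of a covariate-adjusted two-group contrast are invariant to which side of
the regression the indicator sits on — with a logistic option deliberately
out of the default path.

Multiple testing uses Benjamini–Hochberg step-up q-values across the family
of all testable edges (1,378 for 53 components). Degenerate edges (constant
after covariate adjustment) are flagged and excluded from the family rather
than given a pseudo-p. The BH implementation is a direct vectorized
step-up; the suite checks it exactly against a naive loop oracle and
against `statsmodels.multipletests` (the library is the cross-check, not
the implementation, so floating-point op order stays under our control and
oracle agreement can be exact).

Robustness checks follow two conventions worth making explicit:

* **Permutation validation** shuffles the outcome vector only, leaving
  covariates and edges aligned to subjects — this breaks the outcome's link
  to the covariates as well, which is the literal reading of shuffling the
  behavioral score. Empirical p uses the add-one convention
  (1 + #exceedances)/(1 + n_perm), so a perfect association attains
  1/(n_perm+1), never zero. Only the originally selected edges are
  re-tested per shuffle; the FDR set is not re-selected each time.
* **Bootstrap sensitivity** draws round(0.70·n) subjects *without*
  replacement each iteration (with-replacement is an option), reruns the
  full discovery including FDR, and reports per-edge selection frequency.
  Each iteration consumes its own pre-spawned random stream, so results are
  identical for any worker count.

## Constrained projection

The target-cohort stage fits the same edge model (with the target
covariates: age, age², sex, age×sex, income, years of education, site,
trauma type) for the discovered edges only, and applies BH across exactly
m = |discovery set| tests, per symptom scale. Per-symptom FDR families are
the default (a pooled family is available); this matches per-scale
reporting and keeps each scale's error rate interpretable on its own. Two
provable properties anchor the tests: the reference cohort projected onto
its own discovery set keeps every defining edge significant, and
restricting the family to any superset of the full-family rejection set
preserves those rejections. (The latter is *not* true for arbitrary edge
subsets; the test exercises the discover-then-project situation it holds
in.)

## Dynamic states and occupancy

Windowed connectivity uses a tapered window: a rectangle of 20 TRs
convolved with a discrete Gaussian of σ = 3 TRs (support ±ceil(3σ),
"same" alignment, normalized to sum 1). At a TR of 2.36 s this is a
47.2 s window, inside the 30–60 s range generally considered effective for
capturing connectivity dynamics. The taper enters as observation weights
in weighted means and covariances, so a uniform taper reduces exactly to
the static estimator on the window slice; step size is 1 TR, making a
229-timepoint scan yield exactly 210 windows.

Clustering is seeded Lloyd k-means on the pooled subject×window rows of a
designated edge subset (typically the union of discovered edges for a
behavioral domain, not the full connectome), squared-Euclidean objective,
best of n_init = 10 seeded initializations (k-means++ seeding), up to 1,000
iterations. It is implemented in-package because the analysis contract
requires seeded bitwise determinism, a documented empty-cluster rule
(re-seed from the point farthest from its assigned centroid; consumed
points cannot be picked twice in one pass), and a per-iteration inertia
trace asserted monotone in tests; scikit-learn's KMeans serves as the
independent cross-check on separable data.

The cluster number is chosen by the elbow of r(k) = within-cluster /
between-cluster dispersion over k = 2..9: if r at the smallest candidate is
already ≈ 0 the data are perfectly separated there and that k is chosen;
otherwise the k maximizing the discrete second difference of r over the
interior of the range wins (the endpoints admit no curvature estimate).
The selector is a formalization choice — "the elbow" has no canonical
formula — and the full curve is always returned for inspection.

Occupancy rates (OCR_i = windows in state i / total windows) sum to one by
construction and are therefore compositional: each OCR is related to
symptom severity in its own GLM (never all k together with an intercept,
which would be singular), with BH across the k × symptoms family. A
consequence worth remembering when reading signs: because the OCRs are
negatively coupled, the marginal slope on one OCR absorbs the planted
couplings of the states it trades off against (with k = 2 the two betas
are exact negatives).

## Synthetic cohorts

The generators define the study conditions for every simulation-based test.

**Static cohorts** (defaults: n = 2,000 subjects, C = 53 components,
T = 229 timepoints, ages 45–85 across three sites for the reference style;
n = 306, ages 18–75, four sites plus income/education/trauma covariates for
the target style). Each subject gets a latent correlation matrix: a
network-blocked base (0.30 within, 0.10 between blocks — ordinary resting
FNC magnitudes) plus a perturbation β_e·u on each planted edge, where u is
the subject's latent behavior signal, plus a small linear age trend
(0.001/year) on planted edges. A T×C Gaussian series is sampled from it
and the *empirical* correlations are emitted, so discovery faces realistic
sampling noise. The planted "standardized effect" is the population
partial correlation between the empirical edge and the outcome given
covariates; β_e is calibrated analytically from the large-sample sd of a
T-sample correlation, sd(r) ≈ (1−ρ²)/√(T−3), and the behavior noise (sd 1
on a unit-variance signal). Rarely, extreme u pushes a matrix out of the
positive-definite cone; it is repaired by eigenvalue clipping at 1e−4 and
diagonal renormalization, with the repair count recorded in the truth.

**Dynamic cohorts** (defaults: n = 306, C = 9, T = 229, k = 3 states, mean
dwell 30 TRs). A hidden Markov chain (stay probability 1 − 1/dwell,
uniform off-diagonal) switches the covariance of the series among
single-factor sign-pattern states: state m has correlations a²·s_i·s_j for
a sign vector s that flips the m-th contiguous component block. The
loading a is set from the requested separation — the per-edge contrast
2a² between states, in units of the windowed-correlation noise sd computed
from the taper's Kish effective sample size — with separation 5 as the
default well-separated regime. Truth records the TR-level state sequence,
window-level majority labels (ties broken toward the lower state index),
and true OCRs computed with the same occupancy function the analysis uses.
Symptoms are intercept (20) + small covariate effects + b·trueOCR + noise
(sd 1), with b = (0, +10, −10) planting opposing clinical valence for
states 2 and 3.

What the generators deliberately do **not** emulate: hemodynamics, scanner
drift, motion and physiological noise, site-dependent acquisition
differences beyond a site covariate, heavy-tailed or skewed symptom
distributions, and spatial structure of components. Passing tests
therefore demonstrate that the *statistical pipeline* behaves as designed
under its own assumptions (linear covariate effects, Gaussian series,
Markov switching) — not that those assumptions hold in scanner data.

## Problem sizes and numerical choices

* Whole-connectome fits and permutations are exact linear algebra; the only
  tolerances are 1e−8 vs the statsmodels oracle and 1e−12 for weighted
  moments, both ordinary double-precision headroom.
* Simulation suites run at: 50 null cohorts of n = 2,000 for FDR control;
  20 cohorts of n = 2,000 with ten planted edges for sensitivity; 20
  three-state cohorts of 30 subjects for elbow recovery; 50 three-state
  cohorts of 80 subjects for occupancy and coupling recovery. These sizes
  give stable Monte-Carlo estimates of the proportions being asserted
  while keeping the default suite quick; the acceptance script uses the
  same conditions with 10–20 replicates per quantity.
* Subject sampling is chunked (256 subjects) to bound peak memory;
  batched Cholesky factorization falls back to per-subject repair only
  when a factorization fails.
* Noiseless fits (residual sum of squares at rounding level) report
  p = 0, |partial r| = 1 and the SE as its 0-limit rather than NaN.
* Missing phenotype fields drop subjects per-model with a reported count;
  designs are checked full-rank after categorical expansion, and rank
  failures name the collinear columns.

## Known limitations

* OLS on a binary outcome estimates a linear probability model; inference
  for the *selection* step matches the package's design contract, but
  per-edge betas for binary outcomes are in probability units.
* The elbow selector can be indifferent when states are weakly separated
  (the curve is then nearly hyperbolic); the returned curve should be
  inspected rather than trusting the argmax blindly.
* Projection assumes the target cohort's edge table was built with the
  same component set and edge ordering as the reference; only the edge
  count is verifiable at run time.
* The packaged 53-component partition is a synthetic stand-in with
  realistic network block sizes; analyses of real data should supply the
  study's own component-to-network table.
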