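# Methods

## Model and fitting procedure

Events from a two-channel cytometric measurement are treated as draws from
a c-component bivariate Gaussian mixture with full covariance matrices;
every quantity the package reports (cluster count, positions, per-cluster
cell numbers, off-gate fraction) derives from one fitted mixture per
sample. The fit is maximum likelihood by EM. All density work happens in
the log domain with log-sum-exp row normalization, so components whose
axis standard deviations differ by three orders of magnitude (tight cell
clusters vs. plate-wide background) coexist without underflow; covariances
are factorized by Cholesky, never inverted explicitly.

**Initialization.** Rather than requiring 6c − 1 user-supplied start
values, each event's component-membership probabilities are sampled
row-wise from a symmetric Dirichlet(α), α = 1 by default, and the M step
runs first so the first parameter estimates are data moments. Independent
restarts (default 10) draw from per-start substreams of one master seed;
the winner is the highest final log-likelihood, ties to the lowest start
index. With a warm-start prior model, fitting begins with an E step on the
prior and uses a single start.

**Termination.** Iteration stops when |Δ log L| ≤ ε with ε = 1 by default
(exposed as a flag; stricter values trade time for slightly tighter fits).
Two guards qualify the test, both documented here because they are easy to
get wrong:

- The row-wise Dirichlet start is a near-symmetric configuration — after
  the first M step every component sits close to the global data moments,
  which is a fixed point of EM. Escape from it is driven by O(n^-1/2)
  sampling asymmetries and proceeds geometrically, producing per-iteration
  increments that *grow* from far below ε for some tens of iterations.
  Testing |Δ log L| ≤ ε from iteration 1 freezes fits at this plateau
  (observed: "convergence" in 2 iterations, thousands of log-units below
  the real optimum, and a BIC curve flat from c = 2). The stopping test
  therefore fires only when the increment is also non-increasing — at a
  genuine local maximum EM increments shrink monotonically, during the
  transient they grow — and not before `min_iter` (default 20) iterations
  for randomly initialized multi-component fits. Warm-started runs and
  c = 1 have no such transient and are tested from iteration 1.
- Non-convergence within `max_iter` (default 10 000) returns the best
  iterate flagged `converged=False` rather than raising.

**Degenerate components.** A component whose covariance estimate loses
positive definiteness gets a trace-scaled ridge (1e-6 · trace/2, escalated
until Cholesky succeeds); a component whose responsibility mass falls
below 10·eps·n is reborn at a randomly chosen event with the pooled data
covariance. Both policies avoid silent NaNs on pathological inputs.

## Choosing the number of clusters

BIC(c) = −2 log L + (6c − 1) ln n, natural logarithms throughout. The scan
range defaults to c ∈ [2, 20] — community samples typically hold 10–20
subcommunities, and scanning from 2 keeps the procedure free of tuning.
The selected c is the smallest whose successive difference
|BIC(c) − BIC(c+1)| first drops to δ = 50; if no pair qualifies, the
largest candidate is returned with a warning and `rule_satisfied=False`
(the range was too narrow to see the curve flatten). First-occurrence
semantics (rather than persistence over all later pairs) is deliberate:
the curve's head is steep and its tail noisy, and the first flattening is
the interpretable signal.

**Two-stage fitting.** Stage 1 scans on a deterministic stride subsample —
every 20th event by default, every 40th for very large samples; stride
subsampling is reproducible without extra seeds and, because acquisition
order carries no biological meaning, distributionally equivalent to random
thinning. Stage 2 warm-starts single EM runs on the full data for
c ∈ [c*, c* + extension] (default extension 3): the stage-1 winner seeds
c = c*; for larger c the extra components are born at randomly drawn
events with the pooled covariance and weight 1/(c+1), all weights
renormalized. The final model is the best *full-data* BIC in that range —
a deliberate re-decision, since rare clusters can vanish from a subsample
and reappear on full data. Warm starts cut full-data iteration counts
hard: at desk scale (20 000 events, 4 components, 10 seeds) the median
warm-started run needs 3 full-data iterations against 25.5 for a cold
single start — and a cold multi-start protocol pays that cost ten times.

## Background separation and counting

A fitted component is background iff min over the two axis standard
deviations √Σ_dd ≥ 2 500 channel units (inclusive), i.e. only components
diffuse on *both* axes; the threshold is exposed for communities whose
clusters are unusually tight or wide. Each event is attributed to the
component with the highest unweighted density 𝒩(x | μ, Σ) (argmax ties to
the lowest index; a posterior-weighted variant is available). Events of
background components are "off-gate". Events of a foreground component
count toward its cluster iff their squared Mahalanobis distance is within
−2 ln(1 − q), the 2-dof chi-square quantile — the elliptic confidence
region at level q (default 0.95, configurable to e.g. 0.90/0.99);
otherwise they are "outliers". A literal density-threshold mode
(𝒩(x|μ,Σ)(1−π) ≥ q) is retained behind a flag for comparison; on raw
0–65 536 axes a bivariate density is far below any probability level
everywhere, so that form is only meaningful on normalized data and the
Mahalanobis region is the default. Counts conserve exactly by
construction: Σ clusters + off-gate + outliers = n.

## Synthetic data: what it does and does not emulate

The generator draws each event's component from the weight vector, its
coordinates from that component's Gaussian, and clips to the detector
range [0, 65 536] — clipping (not rejection) mimics saturation and
slightly biases the moments of edge-hugging clusters. `default_community_spec`
produces a realistic layout: cluster means uniform over the central plot
region, axis SDs log-uniform in [300, 2 000] channel units with random
orientation, Dirichlet abundances (a few dominant, several rare
subcommunities), plus one wide background component (SDs ≥ 2 500 at
10–30% weight, matching the 70–90% foreground fractions of real community
samples). Background is modeled as a single very wide Gaussian rather
than a uniform field so that it is recoverable as a mixture component by
the same fitter. Role labels are validated against the separation rule at
construction, so generator truth and classifier agree by design.

Not emulated: doublets, fluorescence spillover/compensation, acquisition
drift over time, and non-Gaussian cluster shapes (real rare clusters are
often flat-topped). Passing tests on this generator therefore demonstrate
correctness of the machinery and statistical calibration under the model's
own assumptions, not robustness to every artifact of real instruments.

## Evaluation conventions

Congruent-cluster matching pairs foreground components of two models
greedily, closest mean distance first, eligible only when the means agree
within a tolerance on *both* axes (default 2 500 channel units — one
background-threshold unit; always reported alongside results). Event-level
F1 matches predicted to reference clusters one-to-one by maximizing total
overlap on the confusion table, scores each matched pair as
2TP/(2TP+FP+FN) over events, and averages weighted by reference cluster
size; background/outlier labels count as negatives on either side. This is
the most conservative reproducible protocol; published F1 values computed
under unspecified protocols are treated as indicative only. When comparing
cluster means against biexponentially displayed manual gatings, the
transform 10^(mean/16 384) maps the linear scale to four display decades.

## Problem sizes and test design

The suite runs entirely on generated data. Statistical checks use sizes
chosen for stable assertions at desk scale: coverage at n = 10 000 draws
(3 binomial standard errors), moment recovery at n = 50 000, model-order
recovery on 20 000-event samples over 20 fixed seeds (3- and 5-cluster
layouts; the 5-cluster check exercises the full two-stage selection and
requires ≥ 80% recovery of the true foreground count), and the warm-start
iteration comparison over 10 seeds. Recovery rates below 100% are
intrinsic to the near-symmetric Dirichlet initialization, whose restarts
explore few basins; cross-checks against an independent EM implementation
under the same initialization scheme find the same optima.

## Known limitations

- Two channels only; higher-dimensional gating is out of scope.
- Gaussian components only; flat or heavy-tailed clusters are absorbed
  into background or split across several components.
- The delta-BIC threshold (50) is calibrated for subsample scans of a few
  thousand events; on much smaller scans the penalty term dominates and
  the fallback (largest candidate, warning) engages, after which the
  full-data stage re-decides.
- Multi-start EM remains a local optimizer: with few restarts the
  subsample scan occasionally merges adjacent clusters at the true c and
  flattens one step early or late; the full-data re-decision corrects most
  but not all such cases.
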