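# Methods

This note records the modeling choices, default parameters, and numerical
decisions behind `stripefit`, in enough detail to reproduce any number the
package emits.

## The regulatory input function

Each nucleus *i* carries a vector of regulator concentrations
x<sub>1i</sub> … x<sub>Ki</sub>. The probability that the target (an
enhancer-driven reporter or gene) is ON in that nucleus is modeled with
logistic regression:

    eta_i = beta_0 + sum_k beta_k * x_ki  (+ sum_q beta_qq * x_qi^2)
    p_i   = 1 / (1 + exp(-eta_i))

The optional squared terms implement concentration-dependent dual
regulation: a regulator with a positive linear and negative quadratic
coefficient activates at low concentration and represses at high
concentration. Its role switches at the crossover concentration

    x* = -beta_q / (2 * beta_qq)

computed by `model.dual_crossover`. The quantity is reported in the same
(relative fluorescence) units as the input channel.

## Fitting

`model.fit` maximizes the Bernoulli log-likelihood with Newton iterations
(equivalently, iteratively reweighted least squares):

- **Convergence**: relative log-likelihood change below 1e-8, at most 100
  iterations. Each Newton step is backtracked (up to 40 halvings) so the
  log-likelihood never decreases; if no uphill step exists the current point
  is a maximum and the fit is reported converged.
- **Quasi-separation**: when stripe borders are sharp, fitted probabilities
  reach 0 or 1 to machine precision and coefficient magnitudes are not
  identified (only the decision boundary is). This is normal for
  noise-free targets, so it raises no error: the fit is flagged
  (`separation_flag`) and the achieved likelihood is kept.
- **Rank deficiency**: collinear design columns are detected with a pivoted
  QR factorization; surplus columns are dropped with a `RuntimeWarning`
  naming them, and their coefficients are reported as zero with undefined
  (NaN) covariance entries.
- **Uncertainty**: the observed-information covariance inv(XᵀWX) with
  W = diag(p(1−p)), which yields standard Wald intervals. Coverage of these
  intervals is verified by simulation (50 Bernoulli replicates at 6000
  nuclei; each coefficient's 95% interval covers the truth in ≥90% of
  replicates — see `tests/test_acceptance.py`).
- **Degenerate response** (all-ON or all-OFF training rows) is an error:
  no boundary exists to estimate.

The fitter is cross-checked in the test suite against `statsmodels` GLM
(binomial family) on noisy problems and against an exhaustive grid-search
oracle on small problems.

## Data model and atlas format

An `ExpressionAtlas` holds per-nucleus coordinates (x = anteroposterior,
z = dorsoventral in the lateral view), a symmetric neighbor graph, and
named expression channels `gene__cohort`. Channels for Bcd, Hb, Kr and Gt
are protein measurements; the rest are mRNA. When both exist for a gene,
protein is preferred for these four (protein is what binds the enhancer)
unless a kind is requested explicitly. Files are plain CSV with a
`neighbors` column of semicolon-delimited nucleus ids; column names can be
remapped with a YAML `ColumnMap`.

The candidate-regulator set for a pair-rule target excludes the target
itself and the other pair-rule genes (ftz, odd, h, prd), since downstream
genes would trivially "predict" the pattern.

## Stripe labeling and training sets

The target channel is binarized at 0.2 (strictly greater). Stripes are
connected components of the ON-induced subgraph of the neighbor graph,
ordered anterior to posterior; components below 5 nuclei are set aside as
speckle noise. For each stripe, ring 1 is its adjacent OFF nuclei and ring
2 the OFF nuclei exactly two graph steps away.

A training set for target stripes S takes those stripes' nuclei as the ON
class and all OFF nuclei as the OFF class, minus ring 1 of every
*non-target* stripe (border nuclei of other stripes are ambiguous under a
different enhancer's control). ON nuclei of small components are excluded
entirely.

## Discovery

`discovery.score_all` fits every k-subset (default k = 4) of the candidate
regulators on identical training rows and scores each by its maximized
log-likelihood (AIC is stored alongside, since quadratic mode mixes
parameter counts). With 38 candidates and k = 4 that is C(38,4) = 73,815
fits. The summary is the pairwise-best matrix: entry (a,b) is the best
score among combinations containing both a and b. In quadratic mode,
members of a declared dual set receive squared terms when present in a
combination. A fit that fails numerically scores −inf with the reason
recorded; the sweep never aborts.

## Synthetic embryo

The generator (`synthetic`) builds a blastoderm-like test bed:

- **Geometry**: n nuclei (default 6078) on an ellipsoid with semi-axes
  202 × 77 × 77.5 μm, placed by a Fibonacci lattice with seeded tangent
  jitter (20% of mean spacing) and reprojection. The anteroposterior extent
  is then ~404 μm. Neighbors are the symmetrized 6 nearest neighbors; the
  graph is verified connected.
- **Patterns**: a small shape library (anterior exponential, sigmoid,
  Gaussian domain, two-domain, terminal, ventral, stripes), evaluated on
  the anteroposterior fraction (or dorsoventral position), with per-cohort
  seeded noise.
- **Default regulator fields** mimic the stripe-2 geometry: Hb sigmoid
  (activator), Bcd anterior exponential (dual), Gt anterior domain and Kr
  central domain (repressors), plus kni, tll, sna decoys.
- **Truth model**: beta_0 = −5, beta = (Hb 10, Bcd 20, Gt −24, Kr −24),
  quadratic Bcd −40 (crossover 0.25). These were calibrated once, at design
  time, from the 1-D analytic profile so that a single sharp stripe forms
  near 33% embryo length, and frozen before any acceptance measurement.
  A separate well-conditioned 5-parameter truth (`recovery_truth`) is used
  for Bernoulli parameter-recovery studies, because noise-free sharp-border
  targets are separable and do not identify coefficient magnitudes.
- **Target**: the truth model's probability field, stored either as a
  continuous channel (noise "none") or as seeded Bernoulli draws.

Scope: the generator produces single-time-point-style snapshots per cohort
with independent noise; it does not model nuclear division, movement, or
measurement registration error between cohorts.

## Perturbations

A perturbation is an ordered list of channel edits — never coordinate,
graph, or (unless a scenario retrains) coefficient edits. Null mutants and
binding-site removals zero a channel; misexpression adds another gene's
pattern normalized to peak 1 and scaled (default 0.2 per transgene copy);
regional edits use anteroposterior masks (anterior/posterior split at 50%,
posterior tail beyond 80%). Indirect effects are always explicit edits
declared by a scenario — e.g. the kni-null scenario adds a Hb gain shaped
like the *wild-type* kni pattern before zeroing kni. Negative intermediate
values are clamped to zero at the end. The damping transform is
½(1 − e^(−2x)) with a configurable prefactor.

`predict_under` applies the original model's coefficients to the edited
fields (the direct in-silico prediction); `retrain=True` refits on the
edited concentrations of the original training rows first, and
`intercept_shift` models reporter-construct basal-activity changes.

## Evaluation

The canonical accuracy surface is the neighbor-ring metric: the percentage
of nuclei with p > 0.5 inside the target stripes, in ring 1, and in ring 2,
always over the fixed category sizes; empty categories report None, never
0. Supporting tools: lateral-midline ribbon profiles, subsampled
cross-validation (averaged whole-embryo predictions from many small
training draws, single-class draws redrawn deterministically), a
flexibility test (fitting the same regulators to decoy stripe targets
should score worse than the true target), and a consistency suite (refits
on dorsoventral bands, stripe-plus-ring rows, dropped stripes, and the full
candidate set should agree with the full fit).

## Reproducibility

All stochastic steps take explicit integer seeds and use
`numpy.random.default_rng`; per-cohort streams are derived from
(seed, cohort) so channels are independent but reproducible. The CLI writes
a `manifest.json` (config hash, seed, package version) next to every
artifact; identical config + seed reruns are byte-identical
(`tests/test_cli.py`).

## Limitations

- Logistic regression on concentrations is a phenomenological input
  function: coefficients are not binding affinities, and under
  quasi-separation only their ratios (the boundary) are meaningful.
- The accuracy metric depends on the neighbor graph; ring percentages are
  comparable only between models evaluated on the same atlas.
- The synthetic embryo is a geometric stand-in: it reproduces counts,
  extents, and stripe topology, not real expression levels.
- Discovery scores are in-sample likelihoods; with ~3000 training rows and
  5–6 parameters overfitting is mild, but ranks between near-tied
  combinations should not be over-interpreted.
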