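# Methods

## Model and assumptions

A governing equation is written in implicit form,

    sum_{i=1..K} f_i(u, u_x, u_xx, ..., u_t, ...) = 0,

and each term is evaluated pointwise over the N discretisation points of the
domain, giving an N x K matrix: the equation-space representation. Each
`TermSpec` carries a sign convention (+1/-1) that moves the term to the
left-hand side, so "the rows sum to ~0" is a universal, testable invariant
(`residual_report`). A **dominant balance regime** is a region where a subset
of p < K terms approximately satisfies the equation on its own; its points lie
near the axis-aligned subspace spanned by those p coordinates, with only
noise-level spread in the other K − p directions.

The identification pipeline assumes:

- the governing equation (the term list) is known — there is no term
  discovery;
- term values are finite on the points used (non-finite rows are masked, not
  errored, because boundary stencils routinely produce a few artifacts);
- clusters of equation-space points are adequately separated for a Gaussian
  mixture to isolate them. The data are *not* assumed actually Gaussian: the
  mixture deliberately over-segments and the merge step repairs the
  redundancy.

## Pipeline

1. **Clustering.** A full-covariance Gaussian mixture
   (`sklearn.mixture.GaussianMixture`, diagonal regularisation 1e-6, best of
   `n_init = 5` EM restarts, explicit seed) is fitted to the masked-in rows.
   The mixture size is user-set or chosen by BIC over 1..12 (ties toward
   fewer components). Because clusters sharing a sparsity pattern are merged
   later, overestimation is benign; BIC's occasional overcount is expected
   and harmless.
2. **Sparse directions.** For each cluster (hard-assigned by maximum
   responsibility), the leading direction of the **uncentered second moment**
   is sparsified with an l1 penalty (`sklearn.decomposition.SparsePCA`,
   one component). Nonzero loadings (|loading| > 1e-8 after unit
   normalisation) name the cluster's active terms.
3. **Merging.** Clusters with identical active-term sets become one balance
   model; labels follow the lexicographic order of the active sets, so output
   is reproducible across runs.
4. **Segmentation.** Every masked-in point takes the balance label of its
   most-responsible cluster; the uncertainty is 1 minus the summed posterior
   responsibility of the assigned regime's clusters (masked-out points:
   label −1, uncertainty 1). New data are assigned by posterior evaluation
   only — no refit.

### Why uncentered second moments

The covariance of a cluster measures variation about its own mean, but the
geometric definition of a balance is alignment with a subspace **through the
origin**: a negligible term has small *values*, not merely small variance. A
term that is large and nearly constant within a region (e.g. the constant
forcing in the boundary-layer fixture's outer regime, or a steady applied
current) is physically active yet invisible to a centered principal
component. The sparse direction is therefore computed from E[f f^T] rather
than Cov[f]. For the l1 solver, which centers internally, the cluster is
symmetrised with its negation ([X; −X]): the symmetrised cloud has exactly
zero mean and the same second moment. For zero-mean clusters the choice is a
no-op.

### Numerical choices

- **alpha (l1 penalty).** Defined *per sample*: the solver's penalty is
  `alpha x sample count` on RMS-normalised cluster data, so one grid spans
  clusters of any size or magnitude (the raw sklearn penalty does not scale
  with n, which silently unsparsifies large clusters). Default grid
  `logspace(-5, -1, 9)`. When `alpha=None`, each cluster takes the largest
  grid value whose sparse direction retains at least `1 − eta` (eta = 0.05)
  of the dense leading direction's second moment; if none qualifies the
  cluster is flagged as having no dominant balance and gets the smallest
  alpha.
- **Minimum active-set size 2**, enforced by halving alpha and refitting: an
  implicit-form equation cannot be satisfied by a single non-negligible term.
  The alpha = 0 (dense) direction of a full-rank cluster has K nonzero
  entries, so the loop terminates; for degenerate exactly-on-axis data the
  largest-magnitude loadings are kept, with a logged warning.
- **Feature scaling off by default.** The method's premise is the local,
  *relative* magnitude of terms; per-column standardisation erases exactly
  that information. `scale_columns=True` exists but is documented as changing
  the semantics of the analysis.
- **Tie-breaks.** Equal responsibilities resolve toward the lower cluster
  index (argmax); balance labels are lexicographic in the active sets.
- **Degenerate inputs.** All-zero rows are assigned (with a logged
  near-degenerate warning) and carry high uncertainty; rank-deficient
  clusters are handled by covariance regularisation, never by failure.
- **Complex-valued terms** (experimental, off by default): a row is rotated
  by the unit conjugate phase of its largest term and the real part kept.
  This preserves the dominant magnitude but discards relative phase.

## Diagnostics

- **Brute-force oracle.** For one row, enumerate all term subsets of size
  >= 2 in increasing cardinality and accept S when the *neglected* terms
  nearly cancel: |sum_{i not in S} f_i| <= delta x max_i |f_i|. All accepted
  sets of minimal cardinality are returned; delta defaults to 0.1 (neglected
  terms contribute at most 10% of the dominant magnitude — the equation gives
  no canonical threshold, so delta is surfaced in config and swept in tests).
  Cost 2^K, capped at K <= 16. Single-term subsets are excluded, mirroring
  the pipeline's minimum balance size.
- **Balance quality.** Per-model mean neglected ratio and retained-magnitude
  fraction, benchmarked against 100 random equal-size term sets (seeded); an
  informative balance must beat the random median.
- **Recovery metrics.** Exact pattern-set match, label accuracy under optimal
  (Hungarian) pattern matching, and adjusted Rand index against planted
  truth.
- **Spurious-term probe.** Append a noise column scaled to the median term
  magnitude, rerun the pipeline, and report whether it enters any active set.
  A column collinear with a genuine term *will* be selected; the probe flags
  this caveat rather than hiding it.

A note on the oracle-agreement statistic: with the default planted
conditions (noise 0.01, delta = 0.1), points whose free active coordinate is
close to zero genuinely have no minimal 2-term description — the neglected
noise exceeds 10% of a near-zero dominant term — so agreement saturates
around 90%, not 100%. That is a property of the definitions, not an
estimation error; smaller noise raises the ceiling.

## Bundled systems

- **Planted generator.** For each requested pattern, free active coordinates
  are drawn from a zero-mean anisotropic Gaussian of unit overall scale
  (per-coordinate spreads linearly spaced 1.25 down to 0.75) and the last
  active coordinate is set to minus their sum, enforcing exact closure
  without rejection sampling; isotropic noise of standard deviation
  `noise_sigma` is then added to all K coordinates. Defaults used throughout
  the tests: 3 patterns in K = 6, 2000 points per pattern, sigma = 0.01.
- **Boundary-layer fixture.** eps y'' + y' − 1 = 0, y(0) = y(1) = 0, with the
  closed-form solution evaluated on a grid log-spaced toward x = 0. Truth
  labels mark a point "inner" when |eps y''| exceeds 10% of the point's
  largest term magnitude; the inner/outer crossover sits near
  x* = eps ln(1/(0.1 eps)), between eps and 10 eps ln(1/eps) for the eps
  used here.
- **Conductance-based neuron.** C_M dV/dt = −sum_j I_j + I_stim with
  I_j = g_j (gating product) (V − E_j); gates relax to voltage-dependent
  steady states; an optional calcium pool drives calcium-activated
  conductances. The capacitive term is recorded from the integrator's
  right-hand side (LSODA, rtol = atol = 1e-8), so the signed term arrays
  close exactly. Two presets: the classic three-current squid axon, and a
  five-current calcium-mediated burster in the style of reduced R15
  *Aplysia* models (fast Na and delayed-rectifier K mapped through the
  affine voltage change Vs = (127 V + 8265)/105; slow inward gate with a
  235 ms time constant; calcium pool rate 3e-4 per ms). The burster is a
  representative parameterisation chosen to produce parabolic bursting
  (~10 s period, ~0.3 s intraburst spike intervals); it is not a transcription
  of any particular published ten-current model.
- **Detonation analog.** u_t + u u_x = q(1 − lambda) omega(u) + eps xi(u),
  lambda_t = (1 − lambda) omega(u) − beta(u) lambda on a periodic domain,
  with omega(u) = exp((u − u_c)/a_k) (kinetics), xi(u) = −u² (exhaust
  dissipation; the sign makes eps >= 0 a genuine loss coefficient) and
  beta(u) = s u_p / (1 + exp(r(u − u_p))) (injection recovery with a cutoff).
  Numerics: Godunov finite-volume advection with SSP-RK2 under CFL 0.5;
  u_t and lambda_t on snapshots come from the semi-discrete right-hand side,
  so snapshot term arrays close exactly. Defaults (q = 1, eps = 0.15,
  u_c = 1.1, a_k = 0.3, u_p = 0.5, s = 7, r = 5, L = 2 pi, M = 256) sit
  robustly in the two-wave mode-locked regime from a two-pulse initial
  condition; the first 100 time units (wave nucleation) are discarded before
  balance analysis. All submodels are config-injectable.

## What the synthetic data do and do not show

The planted generator reproduces the geometric premise exactly — axis-aligned
subspaces plus isotropic noise — so recovery there validates the machinery,
not the premise. The simulators provide non-Gaussian, strongly multiscale
clouds (spike currents span four orders of magnitude against quiescent
currents) and test the method under redundant clustering and merging. None of
the bundled data exhibit measurement noise correlated across terms, strongly
non-stationary noise levels, or terms evaluated by noisy finite differences
of experimental fields; passing tests therefore say nothing about robustness
to those real-data complications. Weak but dynamically important terms that
never dominate local variance are known to be missed by this class of method;
no weak-signal detector is included, deliberately.

## Problem sizes

The default test and reproduction runs use 6000 planted points, a 400-point
analytic fixture, 40 s of the burster sampled at 2 ms, and a 256-cell,
301-snapshot detonation run analysed over its last 50 time units
(~26k points). These sizes give stable statistics for every reported metric
while keeping a full reproduction run in the minutes range on one core.

## Known limitations

- The boundary-layer growth scaling of a transitional turbulent boundary
  layer (exponent ~0.8 for the inertial-sublayer thickness) is the classic
  external validation of this method; it requires a large external DNS
  dataset and is out of scope here. The pipeline accepts such data through
  the generic HDF5/CSV readers.
- The Gaussian-mixture stage can miss terms whose influence is real but never
  locally dominant (weak cumulative effects).
- Only full-covariance GMM clustering is provided — no k-means/spectral
  alternatives — and derivatives are second-order finite differences on
  uniform grids; no spectral or irregular-mesh operators.
- The complex-term reduction is experimental and discards relative phase.
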