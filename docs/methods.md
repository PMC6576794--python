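# Methods

This note documents the models, numerical choices and design decisions
behind `landscape-kinetics`, and what the synthetic-data tests do and do
not establish about real data.

## Surprisal decomposition

The kinetic expression matrix X (genes × timepoints, strictly positive
after an optional pseudocount of 1e-3 × the smallest nonzero value) is
factorized by SVD of ln X: pattern columns G_:,j are the left singular
vectors and each singular value is absorbed into the amplitude series
λ_j(t) = −s_j v_j(t), so patterns are time-independent and amplitudes
carry all time dependence.  ln X is **not** centered before the SVD: the
dominant component itself plays the role of the global steady state
(−λ₀ G_i0 ≈ the time-mean ln-expression), which is why λ₀(t) is expected
and observed to be nearly constant.

SVD signs are arbitrary, so a deterministic convention is fixed: the
baseline component is oriented so that mean λ₀(t) > 0 (for a matrix whose
geometric-mean expression exceeds 1 this makes G_i0 predominantly
negative and the reconstructed baseline positive); each constraint is
oriented so the gene with the largest |G_ij| has a positive loading.
Repeated fits of identical input are bit-identical.

Automatic selection of the number of retained constraints keeps the
leading components whose amplitude range (max − min over time) exceeds
5× the median range of the trailing half of the spectrum, which
estimates the noise floor.  There is no principled universal rule here;
the threshold is exposed through the `J` argument and every reported run
records the retained count.

Gene prefiltering keeps genes with row mean > 0.5 (FPKM-like units) and
sample coefficient of variation > 0.15 (ddof = 1).

The free-energy-like potential uses expression weights at the same
timepoint as the amplitudes: F(t) = Σ_j λ_j(t) Σ_i X_i(t) G_ij.  The
steady-state expression strips the retained constraint factors from the
measured level, X_i0(t) = X_i(t) · exp(+Σ_j λ_j(t) G_ij) under the sign
convention above.  For landscape comparison F is min–max rescaled
(max-abs scaling is also available); only slope signs between states are
ever compared across methods.

## Reaction coordinate and densities

The principal curve is fitted to the pooled events of all timepoints by a
local-averaging projection–expectation iteration: starting from the first
principal-component line, events are projected onto the current polyline,
each of 100 vertices is replaced by the box-kernel average of events
whose projections fall within a window of `span` × the coordinate range,
and the loop stops when the mean squared projection distance changes by
< 1e-6 or after 10 iterations.  The default span is 0.15: on quarter-arc
test geometry wider windows visibly shrink the curve toward its chord
(span 0.3 recovered only ~2/3 of the true arc length), while span ≤ 0.05
overfits; downstream potentials are verified to be stable under ±20%
span changes.  Arc length 0 is anchored at the curve end nearest the
centroid of the earliest timepoint (the melanocytic end).  Projection
ties between segments resolve to the lower arc length.

The arc-length coordinate has a conventional origin (the curve starts at
the data edge, not at any absolute zero); recovery tests therefore
compare planted and recovered coordinates after removing the constant
offset.  The unit q is the unit length of the log-fluorescence marker
axes, inherited by arc length, so the diffusivity is reported in q²/day.

Densities are Gaussian KDEs per timepoint on a fixed uniform grid
(default 256 points spanning the pooled data range padded 5%),
renormalized to integrate to 1 by the trapezoid rule; the bandwidth
default is Silverman's rule per timepoint, overridable in q.

## Kinetic solver

Both the plain drift–diffusion equation for p(x, t) and the
self-sourcing variant for the unnormalized P(x, t) are discretized by a
vertex-centered conservative finite-volume stencil (central interface
fluxes; boundary cells of half width, so the conserved discrete mass is
exactly the trapezoid integral) with reflecting boundaries — cells cannot
leave marker space — and Crank–Nicolson time stepping.  The default step
is dt = min(0.02 day, 0.4 Δx/max|μ|).  The growth term is applied by
Strang splitting as an exact pointwise exponential before and after each
CN step; consequently a spatially uniform growth rate factors out of the
normalized solution exactly (to float roundoff), not merely to O(dt²),
and the normalized dynamics are exactly invariant to a constant shift
α(x) + c.  Negative values below 1e-9 of the density maximum are treated
as roundoff and zeroed; anything larger raises a solver error rather
than being clipped silently.

Drift, potential and stationary density are linked by the zero-flux
stationarity condition μ = D · d ln p∞/dx.  Reported potentials use the
Gibbs convention U = −(D/2) ln p∞ (equivalently U = −½∫μ dx), under
which μ = −2 dU/dx; the alternative U = −∫μ dx is available via a flag.
The two conventions differ by an exact factor of 2 in the y-scale and
never affect shapes or slopes, which are all that is compared.  Before
logarithms, densities are floored at 1e-12 of their maximum (KDE tails
reach numerical zero).

## Parameter estimation

**Diffusivity.**  For each candidate D, the drift is Gibbs-inverted from
the measured unsorted steady state (making it stationary at any D — so
the relaxation *rate* of the gated subpopulation, not the late-time
shape, carries the information about D), the gated t = 0 density is
forward-solved, and the fit is scored by the unweighted sum of squared
density differences over the later timepoints.  A coarse search over 30
log-spaced candidates in [0.01, 3] q²/day is refined by bounded scalar
minimization between the neighbors of the grid minimum.  A flat profile,
multiple interior minima, or a minimum at the grid edge triggers a
warning and returns the raw grid minimum.

**State cutoffs.**  The two region boundaries are the interior local
minima of an observed density in which all three subpopulations coexist
(plateau minima resolve to the plateau midpoint; with more than two
minima, the two separating the three largest-mass modes are chosen).
Null-growth recovery experiments show the fitted growth rates are
sensitive to misplaced boundaries, so automatic detection is preferred
over hand-set values.

**Landscape fit.**  Free parameters are the drift values at 20 uniformly
spaced knots (natural cubic spline in between) plus the two growth rates
(α₁ neural-crest, α₂ mesenchymal; melanocytic anchored at 0, which is
only a gauge choice).  The loss is L = Σ_i ∫ (p_pred − p_exp)² dx by
trapezoid quadrature, all timepoints weighted equally, with p_pred the
normalized forward solution from the measured day-0 density.  The
optimizer is plain gradient descent with forward-difference gradients
(relative step 1e-3 per parameter scale), a diagonal scale
preconditioner (drift scale 1 q/day, growth scale 0.25/day), and
backtracking Armijo line search; convergence is declared after relative
loss improvements below 1e-6 for 10 consecutive iterations.
Initialization is α₁ = α₂ = 0 with a weak linear restoring drift
−0.5 (x − x̄); additional starts (default 5 in the library; 2 in the
shipped acceptance runs, which profiling showed sufficient for the
planted scenarios) are seeded Gaussian perturbations of it, and the best
loss is kept.  Landscape recovery is assessed on the region the data
actually visit (density above 1e-3 of the series maximum): outside the
data support the drift is unidentifiable and the spline tails are
meaningless.

**Growth rates.**  N(t) = N₀ · 2^(α t) is fitted per time window
(default windows day 0–21 and day 21–78) by least squares on log₂ counts;
α is reported in doublings/day, whereas the kinetic model's α(x) is a
natural exponential rate (factor ln 2 between the two).

## Synthetic data: what it emulates and what it does not

The generator plants exactly the structure the two analyses assume, plus
realistic noise:

* **Transcriptome** (default 10⁴ genes × 7 timepoints, days
  {0, 3, 11, 17, 21, 46, 73}): ln-baseline ~ N(1.5, 1.5²) (FPKM-like
  after exponentiation), three constraints — a monotone mesenchymal
  rise, a transient neural-crest bump, a day-3 spike — with amplitude
  scales (90, 70, 55)·√(n/10⁴) (per-gene fold-changes independent of
  gene count) and additive N(0, 0.1²) noise on ln-expression
  (multiplicative lognormal on expression).  Amplitude series are
  centered and mutually orthogonalized and patterns are orthonormal and
  orthogonal to the baseline, making the planted decomposition exactly
  identifiable; the neural-crest pattern loads on abundant genes with a
  negative expression-weighted mean, which places the F(t) minimum at
  the intermediate timepoints, the configuration observed in the real
  system.  Real transcriptomes have no exactly orthogonal modules, gene–
  gene correlation structure, or count noise; recovery results bound
  estimation error under the model's own assumptions, not annotation or
  normalization artifacts.

* **Single-cell landscape** (x ∈ [0, 6] q, 256-point grid): three
  Gaussian wells at x ≈ 1, 3, 5 under a weak confining parabola, the
  neural-crest well deepest (the attractor), with net growth
  (0, 0.08, 0.4)/day over regions split at x = 2, 4 and D = 0.35 q²/day.
  These defaults give neural-crest enrichment around days 11–17 and a
  stable ~⅔ mesenchymal majority beyond day ~30, matching the study
  timeline; day 0 is a narrow melanocytic Gaussian.  Cells are
  inverse-CDF draws from the trapezoid-integrated solver density, mapped
  to (log MART-1, log NGFR) space along a quarter-arc parameterized by
  arc length, with radial transverse noise (sd 0.15 q) and 10⁴ cells per
  timepoint (the typical number of live events collected per flow
  sample).  The independent test oracle simulates the same dynamics by
  (branching) Euler–Maruyama particles so the two routes share no
  mechanism.  Real cytometry adds spectral spillover, gating artifacts
  and non-arc trajectories that are not modeled.

* **Drug-naive scenario** for sorting-relaxation: a bimodal steady state
  (mixture 0.62·N(2.3, 0.30²) + 0.38·N(3.9, 0.35²)), no growth; gating
  the upper mode and relaxing for 10 days at D = 0.35 q²/day gives
  roughly one relaxation time of re-equilibration, which is what makes
  the diffusivity identifiable to a few percent.

* **Cell counts**: exponential growth with mean-one lognormal noise
  (default CV 5%).

## Problem sizes in shipped runs

Forward solves in fitting loops run on 96–128-point grids resampled from
the 256-point measurement grid (the fitted potentials on the two grids
correlate > 0.99); recovery experiments use horizons of 10–20 days, 5–8
timepoints, and gradient-descent caps of 150–400 iterations with 1–2
starts, which profiling showed reach the reported tolerances on the
planted scenarios.  All randomness flows from a single integer seed per
run; identical seeds give bit-identical outputs, including manifests.

## Known limitations

* The drift is unidentifiable where the density series has no support;
  spline behavior there is regularized only by the natural boundary
  conditions.
* The three-state piecewise-constant growth ansatz is assumed, not
  selected; no model comparison across step counts is performed.
* Uncertainty is reported only as multi-start spread; no standard errors
  for U or α.
* Diffusivity is assumed constant in x and unchanged by drug treatment;
  the drug-treated fits reuse the drug-naive estimate.
* FCS files are not read; flow data enter as CSV event tables.
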