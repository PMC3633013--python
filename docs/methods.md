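# Methods

## Model

A cell is simulated as a point particle cycling between a stationary pause
of length `t_pause` ≥ 0 minutes and a straight free run of length
`t_free` > 0 minutes at speed `v_free` ≥ 0 μm/min.  At the start of each
cycle a new run direction is drawn; directions of successive runs are
independent (no turning-angle persistence).  Cells do not interact and feel
no boundaries, volume exclusion or imaging noise; space is unbounded and
homogeneous, and any directional bias is spatially and temporally uniform.
Units are fixed to minutes and micrometres with no conversion layer.

One cycle takes `t_run = t_free + t_pause` and displaces the cell by a
vector uniform on the sphere of radius `r = v_free·t_free`.  Each Cartesian
component of such a vector is uniform on `[−r, r]` (the spherical-cap
property) with variance `r²/3`, and components are pairwise uncorrelated,
so the walk decouples into three identical one-dimensional random walks and
its Brownian scaling limit has per-dimension motility coefficient
`M = r²/(6·t_run)`.  All square-displacement formulas are per observed
dimension; multi-dimensional views multiply by the number of observed
dimensions (`dims`, default 1).

## Sampling

Unit directions use the normalized-Gaussian-triple construction (exactly
uniform; a resampling guard covers the measure-zero near-zero triple).  The
topotaxis axial component `x = ⟨b, d⟩` with density `(1 + p·x)/2` is drawn
by inverse transform — the root of `p·x² + 2x + (2 − p − 4u) = 0` in
`[−1, 1]` — so the draw count per direction is fixed and streams are
reproducible; the perpendicular part is uniform on the circle of radius
`√(1 − x²)` in the plane normal to `b`.  All randomness flows through
injected `numpy.random.Generator` objects; ensembles derive one child
stream per track from a master `SeedSequence`, making results independent
of execution order.

## Simulation

Tracks are built event-by-event as piecewise-linear paths (pause segments
carry zero velocity, or the drift `p·v_free·b` in simple mode; run segments
carry `speed·direction`).  Observation times are exact multiples of
`sample_dt` evaluated directly on the breakpoint polyline, so there is no
interpolation or accumulation error; cycle events need not align with
sample times.  Cycles are drawn in vectorized batches sized by the
remaining simulation time.  Degenerate zero-length runs (klinotaxis with
`p = 1` and `⟨b, d⟩ = −1`) and zero-pause cycles are ordinary events; a
guard of 10⁹ events per track raises instead of hanging (unreachable in
practice since `t_free > 0`).

Phase initialization: `synchronized` starts every cell at the beginning of
a pause, which exposes the pulsed single-cell square-displacement curve
(flat during pauses, quadratic during runs, envelope `2Mt`).  `stationary`
drops the cell into the equilibrium state of its renewal cycle.  For every
mode with fixed cycle length this is the uniform offset `τ0 ∈ [0, t_run)`
that underlies the smooth population MSD: if `τ0 < t_pause` the cell
finishes the remaining pause, otherwise it is mid-run with `t_run − τ0`
remaining in a freshly drawn direction.  Klinotaxis has direction-dependent
cycle lengths, so its equilibrium state is length-biased: the initial
cycle's direction is accepted with probability proportional to the cycle
duration (rejection against the maximal cycle) and the age within the
cycle is uniform.  This was a genuinely open design point: a plain uniform
offset systematically under-samples long bias-aligned runs, and we measured
a ~3% deficit in mean drift at one hour (291.5 μm vs the exact `‖C‖·t` =
300 μm at n = 4·10⁴) — an inspection-paradox artifact, not a property of
the model.  With the equilibrium start the increment process is stationary
and the simulated drift matches `‖C‖·t` exactly (300.3 ± 0.5 μm).

## Closed forms and reconstructions

The ensemble MSD per dimension is `2Mt − 2M·t_free·g(t/t_free)` with
`g(u) = u³/3 − u² + u` below `u = 1` and `g = 1/3` above; it starts at zero
with zero slope and is exactly the line `αt + β`, `α = 2M`,
`β = −2M·t_free/3`, for `t ≥ t_free`.  Since `β/α = −t_free/3`, the
population MSD has only two degrees of freedom — `t_pause` and `v_free`
are not separately identifiable from it, only mean displacement separates
them.

The zero-pause squared confinement ratio is implemented as
`E[C²(t)] = (3·max(t, t_free) − min(t, t_free))·t_free/(3·max(t, t_free))²`.
This expression was reconstructed from the ensemble MSD (the primary
sources render it ambiguously) and is pinned down by four independent
checks: the `t → 0` limit 1/3, the branch-point value 2/9 at `t = t_free`,
the normalized form `t·C²(t) = t_free(3t − t_free)/(9t) → t_free/3`, and
Monte-Carlo agreement within 3 SE at n = 10⁵.  The simple-mode convection
speed `p·v_free·t_pause/t_run` is likewise a dimensional reconstruction
(displacement `p·v_free·t_pause` per cycle of length `t_run`) validated by
simulation.  `sq_confinement` refuses `t_pause ≠ 0` unless an override flag
is passed, in which case the same MSD ratio is evaluated as an explicit
extrapolation (the path-length denominator then overcounts pausing time).

One published motility value resists the closed form: the fourth-ranked
triplet (1.5, 1.5, 26.1) is quoted as 92.89 μm²/min where the formula gives
85.15; all other quoted values reproduce to two decimals, so the package
follows the formula and treats that row as a typographical outlier.

Bias strength is restricted to `p ∈ [0, 1]` as the taxis modes define it.
Under this restriction the simple mode cannot exceed
`v_free·t_pause/t_run` (3.76 μm/min at the best-fitting triplet), so
experiments targeting a 5 μm/min drift use the three semi-mechanistic
modes, whose common speed formula inverts to `p ≈ 0.997` there.

## Estimators

Track statistics operate on zero-aligned sets sharing one observation grid.
Heterogeneous imported grids are binned to the nearest multiple of the
sampling interval (tolerance `dt/2`, out-of-range points dropped and
logged).  Standard errors are per-point sample SEs across tracks; no
time-lag pooling or overlapping-window MSD is used, so neighbouring points
of one curve are correlated but each point's SE is unbiased.  The squared
confinement estimator defaults to the 1-D view (its 1/3 small-time limit
presumes one observed dimension); the `t = 0` point is 0/0 and omitted.
Displacement covariance at a fixed time uses delete-one jackknife SEs via
rank-1 downdates of the scatter matrix.

Linear MSD fits are weighted least squares (weights `1/SE²` when SEs are
present) with `M̂ = α̂/(2·dims)` and `t̂_free = −3β̂/α̂`; a positive
intercept yields `t̂_free = 0` with a warning.  The default fit window
iterates once on the `t_free` guess (the line only holds beyond `t_free`).
Fürth fits use bounded multistart nonlinear least squares.  Grid ranking
simulates each candidate triplet (default 10⁴ tracks per point — a desk
scale chosen so the full suite of cross-validations runs in minutes; the
count is a parameter), scores uniform-weight SSR on the reference grid, and
normalizes to the best fit.

## What the generator does and does not emulate

Simulated ensembles are the package's own fixtures: they realize exactly
the model stated above, at the published best-fitting parameters unless a
test says otherwise.  Passing tests therefore demonstrate internal
consistency between simulator, closed forms and estimators — they do not
show that real lymphocytes follow the model.  Real two-photon data adds
finite imaging volumes (tracks lost at boundaries), localization noise,
heterogeneous per-cell parameters and cell–cell interactions, none of which
are modelled; fitting machinery here is validated on self-generated
references only.

## Numerical choices and limitations

- Bit-exact CSV round trips (shortest-repr floats; round-trip parser).
- Degenerate fits: `P = 0` Fürth is the memoryless limit `2Mt`; WLS falls
  back to OLS when any SE is zero.
- `dot = −1` with `p = 1` gives zero speed (orthotaxis) or zero duration
  (klinotaxis) and is processed without special-casing.
- The analytical mean displacement of the model is unknown; mean
  displacement is available only as an estimator on simulated tracks.
- Anisotropic motility under taxis (the 3×3 motility matrix) is exposed
  only empirically through `displacement_covariance`.
- No spatially or temporally varying bias fields, and no 2-D projection
  machinery beyond coordinate selection in the estimators.
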