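# Methods

This note documents the model implemented by `sociowalk`, the choices made
where the design was genuinely open, the numerical conventions, what the
synthetic fixtures and scaled-down protocols do and do not show, and the
known limitations.

## Model definition

The system is `N` agents on an unbounded 1D integer lattice with discrete
time.  Agent `k` carries a position `x_k ∈ ℤ`, a social rank `S_k ≥ 0`, a
polynomial belief `Ŝ_k(x)` and a potential centre `x*_k ∈ ℤ`.  One time
step executes three phases in a fixed order — move, interact, sense — so
that contests act on post-move co-locations and beliefs are computed from
post-contest ranks.  The phase order is a fixed convention of this
implementation (the dynamics are not sensitive to it at the event rates
used; sensing is 100× rarer than moving).

**Movement.**  A ±1 proposal with equal probability, rejected when it
leaves the open box `|x − x*| < L` (infinite-wall potential; `2L − 1`
permitted sites).  Rejection at an infinite wall is the standard treatment;
an optional lazy-walk probability `stay_prob` exists and defaults to 0.
Within a step agents are updated in index order; since multiple occupancy
is allowed, no movement conflicts exist and the update order is
observationally irrelevant.

**Dominance contests.**  Co-located agents interact subject to a hard gate
`|S_j − S_k| < ΔS_max` (strict: the boundary does not interact, i.e. the
gating step function is 0 at 0).  The higher rank always wins; equal ranks
are a fair coin.  Winner/loser updates are `+δ⁺ / −δ⁻` with defaults
`(1, 0)` and a floor at zero.  The rank difference of an isolated pair is
therefore a reflected random walk on `{0, …, ΔS_max}` that absorbs at the
threshold, after which the pair never interacts again — the mechanism that
bounds local rank gradients.

*Pairing*: by default **all** unordered pairs at a multiply-occupied site
are resolved once per step, in random order, with the gate re-evaluated
against running ranks (`pair_mode="all"`).  A single uniformly drawn pair
per site per step is available as `pair_mode="single"`.  The all-pairs
reading treats "co-located agents interact" as a property of each pair.  We
measured the alternative: under the scaled transient protocol below,
single-pair rank growth is too slow for the population to differentiate
socially within the horizon (ensemble `C(t)` stalls around −0.4 and the
dependence on `k_h` is noise-dominated), while all-pairs yields clean
convergence and the expected ordering in `k_h`.

**Sensing and beliefs.**  With per-step probability `r` an agent reads
`(x_j, S_j)` of all neighbours within the closed ball `|x_j − x_k| ≤ h`
(itself excluded) and fits a second-order weighted least-squares polynomial.
If the fit measures a minimum (`β₂ > 0`) it refits at first order with the
same weights, so retained beliefs always have a single maximum.  The
sufficiency rule is: at least 4 neighbours at ≥ 3 distinct positions, and a
numerically sane design (below); anything less resets the belief to zero
(`Ŝ_k ≡ 0`) and leaves `x*` untouched.  Model fidelity is the unweighted
coefficient of determination `Φ = 1 − SS_res/SS_tot` over the sensed data;
when the sensed ranks have zero variance `Φ` is 1 for a zero-residual fit
and −∞ otherwise (ordered below every finite value, so it falls through the
low-fidelity branch downstream).

*Weights*: uniform by default; a tricube distance-decay kernel
`w = (1 − (|Δx|/h)³)³` is available (`weights="tricube"`).  Note a
structural consequence: a uniform-weight least-squares fit with an
intercept always has `Φ ≥ 0`, so with the default weights the two-stage
retention rule below can never trigger; only distance-decay weights make
`Φ < 0` reachable (the fit then hugs near neighbours and the unweighted
residuals at far ones can exceed the total variance).  The scaled transient
protocol converges correctly under uniform weights, so the default is kept
minimal.

*Two-stage retention*: before the waiting time `t_c`, a new belief with
`Φ < 0` is discarded wholesale (previous belief and centre kept).  After
`t_c` every sufficient measurement is adopted.  `t_c` defaults to 3×10⁶
steps, the value appropriate for full-horizon (10⁹-step) runs; shorter runs
should scale `t_c` proportionally — this is deliberate and not automatic
(`desk_sweep_spec` does it for the sweep presets).

**Potential-centre update.**  An adopted belief moves the centre to the
lattice point minimising `|S_k − Ŝ_k(x)|`.  For a concave quadratic this is
the root of `Ŝ_k(x) = S_k` nearer the agent when `S_k` is below the belief
maximum (exact root ties broken uniformly at random) and the vertex
otherwise; for a linear belief, the exact inversion.  The continuous
minimiser is rounded half-away-from-zero.  A flat belief (|slope| below
1e−12) yields no centre update.

*Domain of the argmin* (`center_rule`): by default the minimisation is
restricted to the sensed window `[x_k − h, x_k + h]` (`"window"`); the
belief is an extrapolating polynomial and is only trusted over the region
it was fitted on.  The restricted minimiser is found exactly by evaluating
the clipped roots, clipped vertex and window endpoints (the polynomial is
piecewise monotone).  Two alternatives are implemented and were measured at
the Fig-2-style cell (`k_L = 1`, `k_h ∈ [0.3, 1]`, `T = 2×10⁶`):

* `"clamp"` — global argmin, stranded agents clamped into the relocated
  box.  Rare degenerate fits (near-flat slope) then produce centre jumps of
  10⁴–10⁵ sites (measured p99.9 ≈ 3×10³, max ≈ 5×10⁴ against `h = 600`);
  the jumped agent is isolated, its belief resets, and it is permanently
  lost, so the group evaporates agent by agent (`Δ` grows to 10³–10⁵).
* `"frozen"` — global argmin, no re-admission; a stranded agent's walk
  freezes until it can re-enter.  Agents stranded far away freeze forever
  and the sorting dynamics stall (`C ≈ 0`).

Only the windowed rule maintains the cohesive sorted states the model is
built to produce, so it is the default.

**Initialisation.**  Positions i.i.d. uniform on `(−A₀/2, A₀/2)` with
`A₀ = N/ρ₀`, rounded to the nearest site (halves away from zero); ranks 0,
beliefs zero, `x*(0) = x(0)`.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| `N` | agents | 100 | |
| `ρ₀` | initial density (agents/site) | 0.05 | sets `A₀ = N/ρ₀ = 2000` |
| `k_h` | sensory radius scaling | — | `h = k_h N/ρ₀`; `k_h = 1`: a central agent initially senses everyone |
| `k_L` | box radius scaling | — | `L = k_L/ρ₀`; `k_L = 1`: full expected initial overlap of neighbour boxes |
| `ΔS_max` | interaction gate threshold (rank units) | 100 | bounds the local rank gradient |
| `δ⁺, δ⁻` | contest rank updates | 1, 0 | no relaxation toward zero |
| `r` | sensing probability /agent/step | 0.01 | makes sensing asynchronous |
| `t_c` | retention waiting time (steps) | 3×10⁶ | scale with `T` for short runs |
| `T` | horizon (steps) | 10⁶ | full-horizon protocol uses 10⁹ |

Radii are rounded half-away-from-zero to integers with a floor of 1.  Both
parameterisations (radii or scalings) are accepted and cross-checked.

## Order parameters and fits

* `Δ(t)`: mean over agents of the distance to the nearest other agent.
  Ensemble averaging is applied to per-realisation values, never to pooled
  positions.
* `n_s(t)`: fraction of ordered pairs within `h` (boundary inclusive).
* `C(t)`: Spearman correlation (average-rank tie correction, i.e. Pearson
  on ranked data) between `|x_k − x̄|` and `S_k`; undefined (NaN) while all
  ranks are equal — ensemble curves average the defined realisations and
  report the count.
* Shape fit: nonlinear least squares of `F(x; α, m, K)` on the recentred
  pooled configuration.  `F` is evaluated in log-sum-exp form (no overflow
  for `α|x|` up to 10⁶).  Initialisation profiles `(m, K)` out linearly on
  a 57-point geometric `α` grid spanning 1e−4–1e3; among grid points within
  1% of the best misfit the smallest `α` is preferred (the smoothest shape
  consistent with the data — this resolves the flat `α/m` trade-off of
  near-quadratic profiles), followed by a Levenberg–Marquardt polish in
  log-parameters (positivity by construction; log-parameters clipped to
  ±50).  `J = Kα/m − ln 4` is always recomputed from the fitted triple.
* Stationarity: `Δ` is stationary at `t` when the means over the trailing
  half-decade windows `(t/10, t/√10]` and `(t/√10, t]` differ by less than
  5% (relative); both windows must hold ≥ 3 snapshots.  Window and
  tolerance are explicit arguments.
* Regimes: Unstable if not stationary or `2h/Δ < 6`; Full Sensing if
  `n_s ≥ 0.999` (slightly below 1 to tolerate single-snapshot fluctuation);
  Partial Sensing otherwise.

## Numerical conventions

Polynomial fits are performed in sensor-centred coordinates scaled to
`[−1, 1]`, and coefficients are re-expanded to absolute lattice coordinates
for storage.  The normal equations are solved by an explicit symmetric
2×2/3×3 adjugate inverse; fit quality is gated on a 1-norm condition
estimate of the scaled Gram matrix below 10¹⁶ (equivalent to a design
matrix condition of about 10⁸).  This hand-rolled solve is deliberate: the
pure-Python reference stepper and the compiled (numba) production loop
share the exact same routine and the exact same RNG call sequence —
uniform integers are drawn as `⌊rng.random()·n⌋` — so the two
implementations produce bit-identical trajectories, which the suite asserts
directly.  Fits agree with an independent `lstsq` oracle to 1e−8 relative
on random data.

Per-realisation seeds are spawned as
`SeedSequence(base_seed, spawn_key=(cell…, replicate))`, making sweep cells
independent, reproducible and parallelisable; cached sweep cells re-emit
byte-identical result tables.

## Synthetic fixture

`make_annular_fixture` builds an idealised converged state: equispaced
sites recentred on zero with ranks `F(|x|; α, m, K)` plus optional Gaussian
rank noise and position jitter (the even profile is evaluated on `|x|` so
symmetric pairs tie bit-exactly and the noiseless socio-spatial correlation
is −1 exactly).  It emulates the *end state* only: no contest history, no
belief states, no dynamics.  Metric tests on the fixture validate the
estimators, not the simulator; the simulator-level claims are tested by
running the model.

## Scaled-down protocols: what they show

The full-horizon protocol (`T = 10⁹`, 10 replicates per cell, the complete
`L` and `h` grids) is cluster-scale; it ships as `paper_sweep_spec()` but
is not run in the test-suite.  The suite instead runs a scaled transient
protocol — `N = 100`, `ρ₀ = 0.05`, `k_L = 1`, `k_h ∈ {0.3, 1}`,
`T = 2×10⁶`, `t_c = 10⁴`, 10 replicates — which reproduces the qualitative
transient claims: the ensemble socio-spatial correlation decreases toward
−1 for both radii and the larger `k_h` crosses `C = −0.5` roughly 40×
earlier (measured crossings ≈ 1.5×10⁴ vs ≈ 5.8×10⁵ steps).  Short horizons
cannot validate the long-time regime *boundaries* (which move with `T`),
the sharpness of the Full/Partial Sensing transition, or the asymptotic
`Δ(t)` plateaus of the full protocol.

## Known limitations

* 1D only; no 2D or continuous-space variant, no velocity alignment.
* The box potential is the only confinement implemented (by design; it
  suppresses rare complete-mixing events that a soft potential admits).
* The weighting scheme, sufficiency thresholds and argmin domain are
  reconstructions of under-specified components; all are exposed as
  configuration (`weights`, `center_rule`, `pair_mode`) so their influence
  can be probed, and the defaults are the combination validated against the
  transient protocol above.
* With uniform weights the two-stage `t_c` rule is inert (`Φ ≥ 0` always);
  it becomes active with tricube weights.
* Agent loss is possible in the non-default `center_rule` variants; the
  default windowed rule bounds a single centre update by `h`.
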