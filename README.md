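# sociowalk

Cohesive collective motion of rank-coupled random walkers on a 1D unbounded
lattice.

`sociowalk` is a simulation and analysis package for a sociogenesis model of
collective movement: `N` agents perform discrete random walks in unbounded
space while acquiring a social rank `S_k ≥ 0` through pairwise dominance
contests, and each agent anchors its own motion to where its *belief* about
the local rank landscape says an agent of its rank belongs.  The coupling
between a self-generated internal variable (rank) and movement produces
spatial self-sorting into a **concave annular state** — high ranks in the
group centre, low ranks at the periphery — which acts as a group-relative
coordinate system and stabilises the swarm against diffusion in unbounded
space, without any attractive force.

It is aimed at researchers in collective behaviour, movement ecology and
swarm robotics who want a fast, reproducible reference implementation of the
model and of the order parameters used to analyse it.

## The model

Each time step has three phases:

1. **Move.**  Every agent proposes `x → x ± 1` with equal probability,
   subject to an individual box potential `V(x; x*, L)` that is 0 for
   `|x − x*| < L` and ∞ otherwise (rejection at the walls; the permitted
   region holds `2L − 1` sites).
2. **Interact.**  Co-located agents hold dominance contests.  A pair
   interacts only while `|S_j − S_k| < ΔS_max` (hard gate, strict at the
   boundary); the higher-ranked agent always wins, ties are a fair coin; the
   winner gains `δ⁺ = 1`, the loser loses `δ⁻ = 0` (no relaxation of ranks).
3. **Sense.**  With probability `r = 0.01` an agent reads the positions and
   ranks of all neighbours within its sensory radius `h` and summarises them
   by a weighted polynomial regression belief
   `Ŝ_k(x) = β₀ + β₁x + β₂x²`, falling back to first order whenever the
   quadratic measures a minimum (`β₂ > 0`).  The belief carries a model
   fidelity `Φ_k = 1 − SS_res/SS_tot ∈ (−∞, 1]`.  The agent then moves its
   potential centre to
   `x* = argmin_x |S_k − Ŝ_k(x)|`
   (solved over the sensed window, rounded to the nearest site).  Before a
   waiting time `t_c`, measurements with `Φ_k < 0` are discarded (two-stage
   dynamics).

Spatial scales are set relative to the initial density `ρ₀` via
`h = k_h N/ρ₀` and `L = k_L/ρ₀`; agents start uniformly on an interval of
width `A₀ = N/ρ₀` with `S_k = 0` and `x* = x(0)`.

The analysis layer provides the mean nearest-neighbour distance `Δ(t)`, the
proportion of sensed neighbour pairs `n_s(t) ∈ [0, 1]`, the socio-spatial
correlation `C(t)` (tie-corrected Spearman correlation between `|x_k − x̄|`
and `S_k`; `C = −1` is perfect annular sorting), and a macroscopic fit of
the rank profile by the integrated-sigmoid shape function

```
F(x; α, m, K) = −(2m/α) ln(1 + e^(−αx)) − m x + K,   J = Kα/m − ln 4,
```

which interpolates between a quadratic (`J ≈ 0`) and the tent `K − m|x|`
(large `J`).  Long-time states are classified as Full Sensing
(`n_s ≈ 1`), Partial Sensing (`n_s` strictly between 0.2 and 1) or Unstable
(dispersal; estimated mean sensed neighbours `2h/Δ < 6`).

## Worked example

```python
from sociowalk import SimParams, run
from sociowalk.metrics import fit_shape

p = SimParams(N=100, rho0=0.05, k_h=1.0, k_L=1.0, T=2_000_000, t_c=10_000)
res = run(p, seed=1)
s = res.series
for i in (0, 15, 35, len(s.ts) - 1):
    print(f"t={s.ts[i]:>9d}  delta={s.delta[i]:8.2f}  "
          f"ns={s.ns[i]:.3f}  ssc={s.ssc[i]:.3f}")
st = res.final_state
fit = fit_shape(st.x, st.S)
print(f"shape fit: J={fit.J:.1f}   2h/delta={2 * p.h / s.delta[-1]:.1f}")
```

prints

```
t=        0  delta=    9.30  ns=1.000  ssc=nan
t=       65  delta=   23.81  ns=0.849  ssc=0.155
t=     8943  delta=   68.03  ns=0.464  ssc=-0.942
t=  2000000  delta=   94.62  ns=0.328  ssc=-0.932
```

with a fitted shape parameter `J ≈ 356` and `2h/Δ ≈ 42`.  Reading: the group
starts fully mixed (all ranks zero, `ssc` undefined), expands from its
initial spacing `Δ ≈ 9` to a self-selected spacing `Δ ≈ 95`, and socially
sorts into the concave annular state (`C → −0.93`).  The final sensed
fraction `n_s ≈ 0.33` and the large `J` (tent-like rank profile) are the
signature of the Partial Sensing regime: the system trades density for a
near-constant mean number of sensed neighbours.

The same machinery is scriptable from the shell:

```bash
sociowalk run --config params.toml --seed 1 --out-dir out/
sociowalk metrics --snapshots out/snapshots.tsv --h 2000
sociowalk fitshape --input profile.tsv
sociowalk sweep --spec sweep.toml --out-dir sweep_out/ --resume
```

Ensemble drivers live in `sociowalk.experiments`: `transient_experiment`
(convergence curves `C(t)` across sensory radii), `run_sweep` (the
`(k_L, k_h)` state-space map with regime classification) and
`make_annular_fixture` (synthetic converged configurations for testing the
metrics without simulation).  `paper_sweep_spec()` returns the full-horizon
protocol (`T = 10⁹`, `t_c = 3×10⁶`, the complete radius grids); it is
cluster-scale and ships as a preset, while `desk_sweep_spec()` gives a
scaled-down version with `t_c` reduced proportionally.

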