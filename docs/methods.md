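# Methods

## Model and assumptions

The package implements a percolation-based optimization closure of the
Budyko water balance. Its physical ingredients:

1. **Water and energy budgets.** Long-term averages with storage change
   neglected: `P = ET + Qsurf + Qsub`, `ET0 = R/L = ET + H/L`. The
   aridity index `AI = ET0/P` separates energy-limited (`AI < 1`) from
   water-limited (`AI > 1`) regimes, with the Budyko bounds
   `ET/P ≤ 1` and `ET/P ≤ AI` enforced everywhere.
2. **Transport-limited soil production.** Advective solute transport in
   3D percolation networks scales as `t ∝ x^1.87`; production at depth
   `x` is `Rs = (Qsub/(1.87·φ))·(x/x0)^−0.87` and balancing it against a
   denudation rate `D` gives the steady-state depth
   `x = x0·[Qsub/(1.87·φ·D)]^1.15`. The `1/1.87` bracket factor comes
   from differentiating `x(t) ∝ t^(1/1.87)`; a convention that matches
   time scales instead (`t_x = t_D`) omits it, and both are exposed via
   `include_transport_factor`. The bracket is dimensionless, so `Qsub`
   and `D` must be supplied in the same units; `SoilSystem` records the
   declared unit and 1 m/Myr = 1e-3 mm/yr is provided as a constant.
3. **NPP optimization.** `NPP ∝ x^p · ET^df` with `df` the root
   mass-fractal dimension and `p` the depth-factor power (1 humid,
   `3 − df` arid). Transpiration is approximated by ET inside the
   optimization. With constant `D` the maximizer is
   `ET* = df/(df+β)·(available water)`, `β = depth_power·p`. With the
   flux-proportional denudation `D = a·Qsub + b·Qsurf` the optimum is
   found numerically; for `b ≫ a` the two-term expansion
   `ET = (2/3)(P−Qsurf) + (2/27)(P−Qsurf)²/Qsurf·(a/b)` (approximated
   exponents 2 and 1) is provided and verified to converge
   quadratically in `a/b` against the numeric optimizer.
4. **Interception** is water that never reaches the soil: the
   optimization applies to `P − I_t` and `I_t` is added back to ET,
   `ET = 0.623(P − Qsurf) + 0.377·I_t`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `Db` | 1.87 | 3D backbone transport exponent (universal) |
| `depth_power` | 1.15 ("printed") / 1/0.87 ("exact") | `1/(Db−1)` |
| `df` | 1.9 humid / 2.5 arid | root mass-fractal dimension |
| `arid_coefficient` | 0.187 (preset 0.183) | run-off share of vegetated-area P, water-limited branch |
| `crossover_AI` | 1.8 | jump to the non-steady-soil branch |
| total run-off fraction | 0.377 | `1 − 0.623`, used by the fixed ("table") surface-run-off mode |
| interception | 0.214 ± 0.115 of P (pooled) or 0.30 ± 0.18 (range midpoint) | canopy interception fraction |
| `f_sub` | 0.4–0.8, midpoint 0.6 | subsurface share of total run-off |

**Printed vs exact coefficient modes.** "printed" carries the rounded
published constants (1.15, 0.87, 0.623, 0.377) so tabulated values
reproduce digit for digit; "exact" computes them (1/0.87,
1.9/(1.9+1.15) = 0.622951…). Note that in printed mode the depth and
rate laws are inverse only to `1.15×0.87 = 1.0005`, so the
production-at-steady-state-depth identity (`Rs(x*) = D` to 1e-9
relative) holds in exact mode; printed mode leaves a ~0.05 % power
residual by construction.

**0.183 vs 0.187.** The arid branch is quoted both as
`1 − 0.183·P/ET0` and, via `1 − 0.813`, as 0.187. The derived value
0.187 is the default; a `paper_fidelity` preset selects 0.183. The
bare-soil evaporation share `(1 − 1/AI)/(1 − c/AI)` is flagged
unreliable below 0.4; by direct inversion that threshold sits at
AI ≈ 1.55 (c = 0.183), slightly below the published 1.575 — both the
formula and the flag are exposed, neither threshold is asserted.

**Surface run-off in table mode.** Published tabulations are
reproduced by the *fixed* form `Qsurf = (1−f_sub)·0.377·P` (this
yields 0.642 and 0.610); the self-consistent alternative
`Qsurf = (1−f_sub)(P−ET)` is solved in closed form in
`et_partition_selfconsistent` and gives slightly different values.

**Non-steady arid branch.** Above `AI ≈ 1.8` soils are typically still
deepening and depth responds to the flux roughly as a square root; no
closed form is published. It is implemented as the closed-form optimum
with the depth exponent halved inside `β`
(`β = (1.15/2)·(3−2.5) = 0.2875`, vegetated ET fraction 0.897), as the
package's interpretation, behind `enable_nonsteady_branch`. The
resulting upward jump at the crossover is intentional and asserted
only for its sign, not its size.

## Uncertainty propagation

At fixed surface run-off the partition is linear in interception with
sensitivity `∂ET/∂I_t = 0.377`, so an interception half-range of 0.18
maps to an ET/P variability of 0.068 and the pooled sd 0.115 to 0.043
(published rounding: 0.045). Spread semantics (half-range vs sd) are
explicit because published variabilities mix the two. Variance shares
across sources use `s_i²/Σs_j²`, valid only for uncorrelated Gaussian
inputs; for the quoted spread triple (0.06, 0.08, 0.16) the formula
gives (0.101, 0.180, 0.719) — the shares published alongside it
(0.08/0.15/0.76) do not follow from the formula for any quoted spread
triple, so the package reports the computed shares and documents the
discrepancy rather than matching the printed ones. The seeded Monte
Carlo (`monte_carlo_et`) samples interception (truncated normal via
inverse CDF on [0, 1] — exact, in place of rejection sampling), the
run-off split (uniform) and optionally the root dimension, with an
optional Gaussian-copula correlation between interception and the
split (no estimate exists; default 0). Its sd converges to the linear
propagation as spreads shrink (checked against the delta method).

## Synthetic basins and what they show

`generate_basins` emulates the *structure* of multi-decadal basin
compilations: log-uniform aridity indices on [0.2, 5], a
precipitation/irradiance phase class (uniform over the three classes;
an optional signed phase offset on ET/P, default off, mirrors the
qualitative in-phase/out-of-phase asymmetry), interception
0.214 ± 0.115, run-off split uniform on [0.4, 0.8], root dimension
truncated-normal 1.9 ± 0.3 on (1, 3) — the measured forb/grass
compilation scatters widely and publishes no sd, so 0.3 is this
package's one-time choice — and Gaussian observation noise with sd
0.02 on ET/P (no noise model is published; 0.02 is of the order of the
inter-study spread of global means). The observed ET/P is the model's
own curve (humid branch evaluated with the basin's root dimension)
plus noise, clamped to the Budyko bounds. These records are synthetic:
they carry no spatial covariance, no measurement-era heterogeneity and
no storage-change violations, so passing the recovery loop shows the
pipeline is self-consistent and correctly seeded — not that the model
fits real basins. `recover_parameters` re-estimates the interception
moments, split bounds and the humid-branch base ET fraction (mean
observed ET/P over `0.7 ≤ AI < 1`, where the branch is neither
energy-clamped nor water-limited); with n = 5000 and noise sd 0.02 the
generating 0.623 is recovered within ±0.01.

## Numerical choices

- Optimization: coarse 512-point pre-scan to bracket the (unimodal —
  verified by a 10⁵-point grid oracle in the tests) maximum, then
  bounded Brent to `1e-12·P`. Degenerate feasible intervals
  (`P − I_t ≤ Qsurf`) return the all-run-off partition with a
  `degenerate-interval` flag and a warning.
- Every `PartitionResult` closes `P = ET + Qsurf + Qsub` to `1e-12·P`
  by construction and validates non-negativity.
- The Damköhler ratio is a user input classified by a strict rule
  (>1 transport-limited, <1 kinetics-limited, exact tie → crossover);
  computing it from mineral kinetics is out of scope.
- Scaling laws reject depths below the network scale `x0` where the
  percolation asymptotics do not apply.
- CSV I/O is comma-separated UTF-8 with shortest-round-trip float
  serialization (`float_precision="round_trip"` on read), so
  write∘read is the identity on numeric columns.
- Time-scale problem sizes in tests and the acceptance script are
  desk-scale (single evaluations, n ≤ 10⁴ Monte Carlo, n = 5000
  basins), chosen to keep the full suite in seconds.

## Known limitations

- The phase classes are carried but no quantitative phase correction is
  applied (only a qualitative mechanism is described in the source
  literature); the generator's optional offset is a placeholder for it.
- Interception and the surface/subsurface split are external inputs,
  not predicted.
- The arid bare-evaporation split degenerates at `AI = 1` and is
  flagged unreliable below a 0.4 share.
- Observed-basin scatter (the real compilations) is not redistributed
  here; all distributional defaults are declared choices, not fits.
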