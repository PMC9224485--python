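# Methods

## Model and assumptions

`nanoperm` treats passive nanoparticle transport through a layered barrier
as free Brownian diffusion retarded by adsorption onto the barrier's
internal surfaces.

**Free diffusion.** A particle of diameter `d` in a fluid of viscosity
`μ` at temperature `T` diffuses with the Stokes–Einstein coefficient
`D = k_B·T/(6π·μ·d)` (`k_B = 1.380649e-23 J/K`). The particle is assumed
spherical, dilute and non-aggregating; diffusivity is concentration-
independent. Sedimentation is screened out explicitly: the Stokes
settling distance `u0·t` with `u0 = d²·g·(ρ_s − ρ_c)/(18μ)`
(`g = 9.81 m/s²`) over a 12 h run is ~13–27 μm for 9–12 nm metal
particles — less than a single membrane layer — so settling never carries
a particle across the barriers considered.

**Surface parameter.** The barrier's capacity to capture particles is a
single dimensionless number `Y`: total solid surface available for
deposition divided by the reference cross-section `A_F` (default 1 cm²;
`Y` is invariant to this choice). For woven meshes, threads are counted
across a square of side `h = √A_F`: every `d_f + l_h` in the plain
direction, and three threads per `3d_f + 2l_h` in the alternating
double-splice direction; threads are full cylinders of length `h`, with
no correction for crossing overlaps. For the brick-wall stratum corneum,
one layer of square bricks (side `w`, thickness `x_k`, cement gap `x_c`)
contributes `Y_layer = n·A_S/A_F` with `n = (h/(w+x_c))²` bricks of total
face area `A_S = 2w² + 4w·x_k`. Counts stay real-valued; the integer
"hand tally" variant (nearest integer in the plain direction, truncation
of the incomplete triplet in the double-splice direction) exists only for
cross-checking counted values. `Y` and thickness `L` add over layers.

**Retention law.** Adsorption removes a Langmuir-type fraction of the
diffusive flux: the surviving fraction (retardation coefficient) is
`a = D_ef/D = 1/(1 + kY)`, with one constant `k ≥ 0` per wettability
class of the surface (hydrophilic vs hydrophobic). `k` subsumes the
particle–surface affinity; it does not depend on the medium's viscosity,
which enters only through `D`.

**Quasi-steady permeation.** From a donor of volume `V` and initial
concentration `c0` across area `A` for time `t`, the permeated mass is
the closed form `m_p = D_ef·c0 / (L/(A·t) + D_ef/V)`, the steady Fick
flux combined with the mass balance `m_p = c_p·V`. It is evaluated once
per scenario — no time stepping, no back-diffusion, no convective terms.
Consequently `0 ≤ m_p < m0 = c0·V`, and the acceptor concentration map
`c_p(D_ef)` and its inverse `D_ef(c_p)` are exact algebraic inverses
(round-trip identity is tested to 1e-10 relative). An observed
`c_p ≥ c0` violates the steady-state premise and raises an error rather
than being clamped; a derived `D_ef > D` (i.e. `a > 1`) is physically
suspect but can arise from noise, so it warns instead of failing.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `d` | 9 nm | particle diameter (silver reference particle; copper is 12 nm) |
| `ρ_s` | 7874 / 8950 kg/m³ | solid density used for silver / copper in the packaged fixtures |
| `T` | 293.15 K | measurement temperature |
| `μ` | 0.001 Pa·s | water / intercellular-cement viscosity; sweep knob up to 0.05 Pa·s |
| membrane cell | A = 3.14 cm², V = 10 mL, t = 12 h, c0 = 400 mg/L | diffusion-cell operating point behind the retention table |
| skin scenario | A = 1 cm², V = 0.2 cm³, t = 12 h, c0 = 10 g/L | a 2 mm film of 10 g/L suspension on 1 cm² of skin |
| brick geometry | w = 35 μm, x_k = 1 μm, x_c = 0.05 μm | corneocyte size and cement gap; layer pitch 1.05 μm, `Y_layer = 2.108` |
| `k` | 0.3884 (hydrophilic), 1.6016 (hydrophobic) | constants fitted from the packaged retention table |
| threshold | 0.005 | `m_p/m0` below which permeation is considered to have stopped |

The skin scenario's particle diameter defaults to 9 nm (the silver
reference particle): with it, the default conditions give penetration
limits of 344 layers at μ = 0.001 Pa·s and 48 at 0.05 Pa·s. Depth is
discretized in whole layers; continuous-depth queries interpolate
`Y(L) = L/(x_k + x_c) · Y_layer` linearly.

## Fitting k

`fit_model_constant` minimizes the unweighted sum of squared residuals in
`a`-space, `Σ(a_i − 1/(1+k·Y_i))²`, with `scipy.optimize.least_squares`
(trust-region reflective, bound `k ≥ 0`, xtol/ftol/gtol 1e-14, ≤200
evaluations), initialized at the median of the single-point estimates
`(1/a − 1)/Y`. The objective is unimodal in `k` for `a ∈ (0,1]`, so no
multistart is needed; the test suite verifies every fit against an
exhaustive grid search (step 1e-5). Noisy observations with `a > 1` are
kept in the fit but flagged. The hydrophilic fit set is the seven
hydrophilic configurations × two particle types (14 points, giving
`k = 0.3885`); the hydrophobic set is the three pure hydrophobic stacks
× two types (6 points, `k = 1.6020`). The two mixed-wettability stacks
belong to neither class and are excluded from both fits, though they
remain available (`group="mixed"`) for alternative pooling.

## Synthetic data

The generator mirrors the measured campaign: twelve filter
configurations, four replicate acceptor-concentration readings each (two
chambers × two runs). For each stack the forward model produces the true
`c_p`; replicates observe `c_p·(1+ε)` with `ε ~ N(0, σ_rel)`
(multiplicative noise, because conductometric concentration errors scale
roughly with signal; an additive floor is available). The default
`σ_rel = 0.05` is a plausible stand-in chosen once — the source
measurements report averages of four samples but not their dispersion.
Negative draws truncate to zero (flagged; a small bias at extreme noise,
accepted for simplicity over resampling). Randomness uses one root seed
with an independent `SeedSequence` substream per (stack, replicate), so
identical seeds give bit-identical tables and extending the design never
replays existing draws.

What passing recovery tests show: the inversion chain
(`c_p → D_ef → a → k`) is consistent and approximately unbiased under
multiplicative Gaussian noise (median `k̂` within 5% of truth at 5%
noise). What they do not show: robustness to aggregation, calibration
drift, adsorption kinetics or any structured error a real conductometric
measurement may carry — none of these are simulated.

## Numerical choices

* SI units internally; concentration in g/m³ (≡ mg/L) and mass in grams.
  Interface layers (packaged CSVs, scenario configs) carry human units in
  their column/key names and convert at the boundary.
* Penetration limit = the **last** layer count with `m_p/m0 ≥ threshold`,
  found by ascending scan (valid because `m_p` is strictly decreasing in
  `N`); 0 when even one layer is below threshold. Thresholds up to and
  including 1 are accepted; `threshold = 1` yields 0 since a barrier of
  finite thickness always passes less than `m0`.
* Depth sweeps are vectorized over layer counts; the limit scan runs in
  chunks of 4096 layers with a 1e6-layer safety cap.
* Problem sizes in the test and acceptance runs: recovery studies use
  60–500 synthetic campaigns of 12–48 observations each — enough for the
  Monte-Carlo bounds asserted while keeping the full suite in the tens of
  seconds.

## Known limitations

* The quasi-steady closed form ignores transient build-up and acceptor
  back-diffusion; it is an end-of-run mass estimate, not a kinetic curve.
* Under the default skin scenario the model's size sweep reproduces the
  characteristic `N_L ∝ √(1/d)` and `N_L ∝ √(1/μ)` ratios (e.g.
  1 nm vs 15 nm limits in ratio ≈ √15), and the two viscosity limits
  (344, 48) exactly; absolute limits for other published size sweeps
  depend on the exact exposure conditions assumed and are exposed as
  scenario parameters rather than hard-coded.
* One `k` per wettability class: mixed-wettability stacks have no
  composite law; the brick-wall skin uses the hydrophilic constant by
  default.
* The brick-wall geometry ignores brick offset (staggering), lateral
  tortuosity and any distinct viable-epidermis or dermis compartments;
  appendageal and intracellular routes are out of scope.
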