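"""Predict nanoparticle penetration through stratum-corneum layers.

Uses the brick-wall skin model (35 x 35 x 1 um corneocytes, 0.05 um
intercellular cement) with the hydrophilic adsorption constant to
compute the permeated-mass depth profile and the penetration limit —
the layer count at which the dimensionless mass m_p/m_0 falls below
0.005 and transport effectively stops.
"""

from nanoperm import MediumSpec, penetration_limit, profile, stratum_corneum_scenario

scenario = stratum_corneum_scenario()  # 9 nm particles, cement mu = 1 mPa.s
table = profile(scenario, 400).table

print("Depth profile (9 nm particles, cement viscosity 0.001 Pa.s):")
for N in (1, 10, 50, 100, 200, 344):
    row = table[table["N"] == N].iloc[0]
    print(
        f"  N={N:4d}  depth {row.L_m*1e6:6.1f} um  Y={row.Y:7.1f}"
        f"  a={row.a:.4f}  m_p/m_0={row.m_ratio:.4f}"
    )

print("\nPenetration limits (largest N with m_p/m_0 >= 0.005):")
for mu in (0.001, 0.05):
    medium = MediumSpec(T=scenario.medium.T, mu=mu, rho_c=scenario.medium.rho_c)
    n_l = penetration_limit(scenario.with_(medium=medium))
    print(f"  cement viscosity {mu:.3f} Pa.s -> N_L = {n_l} layers"
          f" (~{n_l * scenario.geometry.layer_pitch * 1e6:.0f} um)")

print(
    "\nMore viscous cement slows free diffusion (Stokes-Einstein), so the"
    "\nsame mass threshold is reached after far fewer cell layers."
)
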