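"""Surface parameters of woven mesh filters and filter stacks.

Builds the packaged filter library, counts threads across a 1 cm
reference square, and shows how thickness L and the dimensionless
surface parameter Y add up over stacked layers.
"""

from nanoperm import datasets, mesh_surface_parameter, stack_properties, thread_counts

filters = datasets.load_filters()

print("Single filters (thread counts over 1 cm, surface parameter Y):")
for label, spec in filters.items():
    n_x, n_y = thread_counts(spec, h=1e-2)
    Y = mesh_surface_parameter(spec)
    print(
        f"  {label:5s} mesh {spec.l_h*1e6:6.1f} um, thread {spec.d_f*1e6:5.2f} um"
        f" -> n_x={n_x:6.2f}, n_y={n_y:6.2f}, Y={Y:.3f}"
    )

print("\nStacked barriers (L and Y are sums over layers):")
for label in ("F118+F63", "F118+F63+F1", "F9*+F9*+F9*"):
    L, Y = stack_properties(datasets.stack_from_label(label))
    print(f"  {label:12s} L = {L*1e6:6.1f} um, Y = {Y:6.2f}")

print(
    "\nY is the total thread surface per unit barrier cross-section: the"
    "\nlarger it is, the more area nanoparticles can adsorb onto, and the"
    "\nstronger the retardation of their diffusion."
)
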