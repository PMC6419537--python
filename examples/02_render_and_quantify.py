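"""Render one synthetic cell and quantify it against its own ground truth.

The cell carries 5% of its reporter in the cilium; the pipeline should read
that back as a Manders' coefficient near 0.05, and the surface-to-total
ratios should match the true membrane fractions.
"""

from ciliaflow import (
    CellGeometry,
    CompartmentState,
    ImagingParams,
    QuantSettings,
    RegionSet,
    quantify_cell,
    render_stack,
)

state = CompartmentState(
    time=1.5, er=0.12, apical_pm=0.33, basolateral_pm=0.30, cilium=0.05, internalized=0.20
)
geometry = CellGeometry()
stack, truth = render_stack(geometry, state, ImagingParams(seed=7))

regions = RegionSet(
    background={"neighbors": truth.background_region()},
    cell_mask=truth.cell_mask,
)
result = quantify_cell(stack, regions, QuantSettings(apical_z_um=truth.apical_z_um()))

print(f"stack: {stack.data.shape} voxels, channels {stack.channel_names}")
print(f"estimated backgrounds: "
      f"{ {k: round(v, 1) for k, v in result.provenance['background_counts'].items()} }")
print(f"cilium segmented: {result.provenance['cilium_core_voxels']} voxels, "
      f"QC pass = {result.provenance['qc_pass']}")
for rec in result.records:
    true_frac = truth.surface_fraction(rec.side)
    print(f"  {rec.side:12s} surface/total = {rec.surface_ratio:.3f} "
          f"(ground truth {true_frac:.3f})")
print(f"  MCC = {result.records[0].mcc:.4f} (ground-truth ciliary fraction "
      f"{state.cilium:.2f})")
print("\nThe MCC reads out the fraction of total reporter in the cilium;")
print("values near 0.05 match the simulated saturation level.")
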