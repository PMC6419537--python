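"""Per-cell slope analysis: does ciliary arrival track the apical surface pool?

Three simulated replicates of 25 cells at 1 h release.  Cells vary in their
apical/basolateral sorting split, so cells with more apical reporter also
put more into the cilium (positive slope) while more basolateral reporter
means less (negative slope); a paired two-tailed t-test compares the sides.
"""

from ciliaflow import (
    ImagingParams,
    QuantSettings,
    RegionSet,
    compare_slopes,
    fit_mcc_vs_surface,
    generate_population,
    quantify_cell,
)

imaging = ImagingParams(voxel_size=(0.3, 0.25, 0.25))
ap_fits, bl_fits = [], []
for rep in range(3):
    records = []
    pop = generate_population(
        25, time=1.0, seed=700 + rep, imaging=imaging, replicate_id=f"r{rep}"
    )
    for stack, truth in pop:
        regions = RegionSet(
            background={"neighbors": truth.background_region()},
            cell_mask=truth.cell_mask,
        )
        settings = QuantSettings(apical_z_um=truth.apical_z_um())
        records.extend(quantify_cell(stack, regions, settings).records)
    ap_fits.append(fit_mcc_vs_surface(records, "apical", f"r{rep}"))
    bl_fits.append(fit_mcc_vs_surface(records, "basolateral", f"r{rep}"))

for ap, bl in zip(ap_fits, bl_fits):
    print(f"{ap.replicate_id}: apical slope {ap.slope:+.4f} "
          f"(n={ap.n_cells}), basolateral slope {bl.slope:+.4f}")

result = compare_slopes(ap_fits, bl_fits)
print(f"\npaired two-tailed t-test: t = {result.t_statistic:.2f}, "
      f"p = {result.p_value:.4f} (n = {result.n_replicates} replicates)")
print("\nPositive apical and negative basolateral slopes support ciliary import")
print("by lateral transport along the apical membrane.")
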