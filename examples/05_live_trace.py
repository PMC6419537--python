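"""Live-cell imaging analog: trace reporter accumulation at the cilium.

A single-plane time lapse (one frame every 10 min for 2 h) is rendered from
the calibrated kinetics; per frame, the ciliary-marker channel outlines the
cilium and the reporter signal inside the outline is summed.
"""

from ciliaflow import (
    CellGeometry,
    ImagingParams,
    KineticParams,
    render_timelapse,
    simulate_trafficking,
    trace_ciliary_intensity,
)

times_min = list(range(0, 121, 10))
states = simulate_trafficking(KineticParams(), [t / 60.0 for t in times_min])
imaging = ImagingParams(voxel_size=(0.3, 0.2, 0.2), seed=5)
frames, background = render_timelapse(CellGeometry(), states, imaging)

trace = trace_ciliary_intensity(frames, background)
print("time(min)  ciliary reporter (counts)  mask(voxels)")
for t, v, m in zip(trace.times_min, trace.intensity, trace.mask_voxels):
    print(f"{t:8.0f}  {v:18.0f}  {m:12d}")

print(f"\nonset (>10% of final): {trace.onset_time(0.1):.0f} min")
print(f"plateau (>90% of final): {trace.plateau_time(0.9):.0f} min")
print("\nThe trace mirrors the fixed-cell MCC kinetics: ciliary arrival starts")
print("within the first half hour and saturates around one hour after release.")
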