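"""Simulate the synchronized trafficking wave and locate its landmarks.

After release from the ER, the reporter reaches the basolateral membrane
first (sorting favors it ~2:1), the apical membrane (which includes the
ciliary membrane) peaks later, and the ciliary pool saturates at ~5% of the
total reporter.
"""

import numpy as np

from ciliaflow import KineticParams, simulate_trafficking

params = KineticParams()
grid = [0.0, 0.5, 1.0, 1.5, 2.0]
states = simulate_trafficking(params, grid)

print("time(h)  ER     apical  basolat cilium  internal  apical_signal")
for s in states:
    print(
        f"{s.time:5.1f}  {s.er:6.3f}  {s.apical_pm:6.3f}  {s.basolateral_pm:6.3f}"
        f"  {s.cilium:6.3f}  {s.internalized:6.3f}    {s.apical_surface:6.3f}"
    )

fine = np.arange(0.0, 2.0001, 0.001)
fine_states = simulate_trafficking(params, fine)
bl = np.array([s.basolateral_pm for s in fine_states])
ap = np.array([s.apical_surface for s in fine_states])
print(f"\nbasolateral peak at {fine[bl.argmax()]:.2f} h, "
      f"apical signal peak at {fine[ap.argmax()]:.2f} h")
print(f"ciliary fraction at 1.5 h: {fine_states[1500].cilium:.4f} "
      f"(capacity {params.cilium_capacity})")
print("\nThe basolateral-before-apical peak order and the ~0.05 ciliary")
print("plateau are the hallmarks the rest of the pipeline measures back.")
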