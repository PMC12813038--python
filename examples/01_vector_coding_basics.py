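"""Coupling angles, coordination patterns and circular means on toy data.

The coupling angle γ is the direction of the (distal, proximal) angular
velocity vector: values near 0°/180° mean the distal joint dominates, near
90°/270° the proximal joint dominates; first/third quadrants are in-phase
(both joints rotating the same way).
"""

import numpy as np

from circoord import circular_mean, classify_pattern, coupling_angle, dominancy_percent

# Simultaneous knee (proximal) and ankle (distal) angular velocities, deg/s,
# from a knee-dominated flexion movement
knee = np.array([120.0, 150.0, 90.0, 40.0, 160.0])
ankle = np.array([60.0, 50.0, 45.0, 25.0, 60.0])

gamma, undefined = coupling_angle(knee, ankle)
print("coupling angles (deg):", np.round(gamma, 1))
for g in gamma:
    distal, proximal = dominancy_percent(float(g))
    print(
        f"  γ = {g:6.1f}°  →  {classify_pattern(float(g)).value:18s}"
        f"  D{distal:.0f}–P{proximal:.0f}"
    )

mean, resultant = circular_mean(gamma)
print(f"circular mean = {mean:.1f}°, resultant length = {resultant:.3f}")
print("(resultant near 1 ⇒ the coordination pattern is consistent over time)")

# Opposite rotation directions land in the anti-phase half of the circle;
# a motionless sample has no defined coupling direction and is excluded
# from circular means.
g_anti, _ = coupling_angle(80.0, -40.0)
print(f"\nknee +80, ankle −40 deg/s → γ = {float(g_anti):.1f}° "
      f"(an anti-phase bin: joints rotate in opposite directions)")
_, undef = coupling_angle(0.0, 0.0)
print("both joints motionless → coupling angle undefined:", bool(undef))
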