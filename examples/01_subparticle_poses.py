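"""Sub-particle pose bookkeeping.

Expand a table of whole-complex particle orientations into sub-particle
records for a subunit sitting on the threefold axes of an icosahedral
complex, and show what each record carries.
"""
import numpy as np
import pandas as pd

from locrec import FilterOptions, SubunitVector, expand_star, point_group

rng = np.random.default_rng(1)
n = 100
particles = pd.DataFrame({
    "rlnAngleRot": rng.uniform(-180, 180, n),
    "rlnAngleTilt": np.degrees(np.arccos(rng.uniform(-1, 1, n))),
    "rlnAnglePsi": rng.uniform(-180, 180, n),
    "rlnOriginX": rng.uniform(-2, 2, n),
    "rlnOriginY": rng.uniform(-2, 2, n),
    "rlnDefocusU": rng.uniform(10000, 30000, n),
    "rlnDefocusV": rng.uniform(10000, 30000, n),
})

group = point_group("I")
vector = SubunitVector(direction=(1, 1, 1), length=100.0)  # threefold axis
sub = expand_star(particles, group, vector, FilterOptions(seed=5),
                  pixel_size=1.35, src_box=480)

print(f"group order {len(group)}, distinct sites per particle "
      f"{sub.attrs['n_sites']} (= 60 / 3 for a threefold-axis vector)")
print(f"{n} particles -> {len(sub)} sub-particle records")
print("\nfirst record:")
r = sub.iloc[0]
print(f"  pose (rot, tilt, psi) = ({r.rlnAngleRot:.2f}, {r.rlnAngleTilt:.2f}, "
      f"{r.rlnAnglePsi:.2f}) deg")
print(f"  extraction pixel ({int(r.rlnCoordinateX)}, {int(r.rlnCoordinateY)}), "
      f"sub-pixel origin ({r.rlnOriginX:+.3f}, {r.rlnOriginY:+.3f}) px")
print(f"  height above image plane {r.lrZHeightPx:+.1f} px -> defocus "
      f"{r.rlnDefocusU:.0f} A (parent {particles.rlnDefocusU[0]:.0f} A)")
print("\nThe three degenerate orientations on the threefold axis are drawn "
      "evenly:")
print(sub["lrOrientIndex"].value_counts().sort_index().to_string())
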