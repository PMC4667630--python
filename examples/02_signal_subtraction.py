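"""Bulk-complex signal subtraction.

Simulate particle images of a symmetric shell carrying a sub-stoichiometric
subunit, project the shell-only map in each particle's orientation and
defocus, subtract it, and measure how much of each image's energy the
subtraction removed — what remains is dominated by the subunit signal.
"""
import numpy as np

from locrec import (PhantomSpec, make_phantom, particles_from_star,
                    simulate_particles, subtract_stack)

spec = PhantomSpec()  # icosahedral shell, subunit on threefold axes, 60% occ.
box, apix = 64, 2.0
stack, star, manifest = simulate_particles(spec, 20, box, apix, seed=2)
full, shell_only, subunit_only, _ = make_phantom(spec, box, apix)

particles = particles_from_star(star, pixel_size=apix)
residual = subtract_stack(stack, shell_only, particles, scale=False)

kept = np.linalg.norm(residual) / np.linalg.norm(stack)
shell_norm = np.linalg.norm(stack - residual) / np.linalg.norm(stack)
print(f"simulated {len(stack)} noise-free particles, box {box} px at {apix} A/px")
print(f"norm of what the subtraction removed (the shell): {100 * shell_norm:.0f}% "
      f"of the image norm; {100 * kept:.0f}% remains and is subunit signal")
occ = np.mean([m["occupied"] for m in manifest])
print(f"true site occupancy in this draw: {100 * occ:.0f}%")
print("the residual images now feed sub-particle extraction and classification")
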