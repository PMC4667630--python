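"""Localized reconstruction and map metrics.

Run the full workflow on simulated data: subtract the shell, expand and score
the sites, assign the degenerate orientation per sub-particle, reconstruct the
subunit as an independent particle, and assess the map with half-set FSC,
resolution at the 0.143 threshold and a Guinier B-factor.
"""
import numpy as np

from locrec import (FilterOptions, PhantomSpec, assign_orientations,
                    estimate_bfactor, expand_star, fsc, lowpass, make_phantom,
                    particles_from_star, point_group, reconstruct,
                    reconstruct_halves, resolution_at, simulate_particles,
                    subtract_stack, subunit_axis_average_map,
                    subunit_reference_map, unmix_occupancy)

spec = PhantomSpec()
box, apix, subbox = 64, 2.0, 32
stack, star, manifest = simulate_particles(spec, 60, box, apix, seed=4)
_, shell, _, _ = make_phantom(spec, box, apix)
residual = subtract_stack(stack, shell, particles_from_star(star, pixel_size=apix),
                          scale=False)
sub = expand_star(star, point_group("I"), spec.vector, FilterOptions(seed=6),
                  pixel_size=apix, src_box=box)

ref_avg = subunit_axis_average_map(spec, box, apix)
scores, flags, occupancy, windows = unmix_occupancy(residual, sub, ref_avg,
                                                    apix, box, window_box=subbox)
sel = np.flatnonzero(flags)
print(f"{len(sub)} sub-particles, {len(sel)} flagged occupied "
      f"(occupancy {100 * occupancy:.0f}%)")

ref = subunit_reference_map(spec, subbox, apix)
best, updated = assign_orientations(windows[sel], sub.iloc[sel].reset_index(drop=True),
                                    ref, point_group("I"), spec.vector, apix)
vol = reconstruct(windows[sel], updated, apix)
h1, h2 = reconstruct_halves(windows[sel], updated, apix)
curve = fsc(h1, h2)
res = resolution_at(curve, 0.143)
b = estimate_bfactor(vol, fit_range=(16.0, 6.0))

truth = lowpass(ref, 5 * apix)
recon = lowpass(vol, 5 * apix)
a = recon.data.ravel() - recon.data.mean()
t = truth.data.ravel() - truth.data.mean()
corr = a @ t / np.sqrt((a @ a) * (t @ t))

print(f"half-set FSC=0.143 resolution: {res:.1f} A (box Nyquist {2 * apix:.0f} A)")
print(f"Guinier B-factor of the map: {b:.0f} A^2")
print(f"correlation with the ground-truth subunit (10 A low-pass): {corr:.3f}")
print("the asymmetric subunit is recovered even though each particle only "
      "shows it at 60% of its symmetry-related sites")
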