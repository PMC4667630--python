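import numpy as np
import pandas as pd
import pytest

from locrec.geometry import SubunitVector, point_group
from locrec.io import particles_from_star
from locrec.simulate import PhantomSpec, make_phantom, simulate_particles
from locrec.subparticles import FilterOptions, expand_star
from locrec.subtraction import subtract_stack


def random_particle_table(n, rng):
    """A STAR-style table of uniformly distributed particle orientations."""
    return pd.DataFrame({
        "rlnAngleRot": rng.uniform(-180, 180, n),
        "rlnAngleTilt": np.degrees(np.arccos(rng.uniform(-1, 1, n))),
        "rlnAnglePsi": rng.uniform(-180, 180, n),
        "rlnOriginX": rng.uniform(-2, 2, n),
        "rlnOriginY": rng.uniform(-2, 2, n),
        "rlnDefocusU": rng.uniform(10000, 30000, n),
        "rlnDefocusV": rng.uniform(10000, 30000, n),
    })


@pytest.fixture(scope="session")
def study():
    """The small noise-free simulated study shared by the pipeline tests.

    40 particles of the default icosahedral phantom (subunit on the threefold
    axes, 60% occupancy), box 64 px at 2 Å/px, with the bulk shell signal
    subtracted and the sub-particle table expanded.
    """
    spec = PhantomSpec()
    box, apix = 64, 2.0
    stack, star, manifest = simulate_particles(spec, 40, box, apix,
                                               noise_sigma=0.0, seed=11)
    full, shell, subunit, _ = make_phantom(spec, box, apix)
    parts = particles_from_star(star, pixel_size=apix)
    subtracted = subtract_stack(stack, shell, parts, scale=False)
    sub = expand_star(star, point_group(spec.symmetry), spec.vector,
                      FilterOptions(seed=5), pixel_size=apix, src_box=box)
    return dict(spec=spec, box=box, apix=apix, stack=stack, star=star,
                manifest=manifest, full=full, shell=shell, subunit=subunit,
                particles=parts, subtracted=subtracted, sub=sub)


def site_truth(sub, manifest, key):
    """Ground-truth per-record values aligned with a sub-particle table."""
    return np.array([manifest[p][key][s]
                     for p, s in zip(sub["lrParentIndex"], sub["lrSiteIndex"])])
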