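# Methods

## Pose algebra and conventions

All orientation handling is pinned to one set of conventions, enforced by a
projection oracle in the test suite (a blob placed in a phantom must land in a
rendered projection exactly where the algebra predicts, to well under half a
pixel):

* **Euler angles** (rot, tilt, psi) are Relion/XMIPP ZYZ. The matrix
  `A = Rz(psi)·Ry(tilt)·Rz(rot)` is built from passive elemental rotations and
  maps map-frame coordinates to image-frame coordinates; a map point `p`
  appears in the image at the first two components of `A·p` (in Å; divide by
  the pixel size for pixels). Inverting a matrix at gimbal lock
  (tilt = 0/180°) returns rot = 0 with the whole in-plane angle in psi; the
  matrix round-trips exactly, the angle triplet is unique only away from lock.
* **Point groups** Cn, Dn, T, O, I are served by
  `scipy.spatial.transform.Rotation.create_group`, whose settings match the
  single-particle ecosystem's defaults: icosahedral with twofold axes on
  x, y, z (the "I2" setting, threefold on (1,1,1)), octahedral with fourfolds
  on the axes, Dn with the dihedral twofold on x. Group closure, inverses and
  orbit–stabilizer counts are asserted in tests for C1–C12, D2–D7, T, O, I.
  Reproducing numerically identical Euler values from tools that use a
  different icosahedral setting may require re-expressing the vector in this
  setting.
* **Subunit vector to matrix**: the minimal rotation about `[0,0,1] × v̂`; the
  anti-parallel case is a 180° rotation about x. The free azimuth is thereby
  fixed; any consistent choice works because the same matrix is used for
  expansion, extraction and reconstruction.
* **Composition**: `M_sub = A · G · M_vec`, subunit offset `A · G · (ℓ v̂)`.
  Offset components 1–2 are the in-plane displacement from the particle
  center, component 3 the height above the image plane along the beam.
* **Origins** are shifts in pixels that, applied to the image, center the
  reference projection; image centers sit at `floor(N/2)` (0-based). The
  sub-particle extraction coordinate is the offset rounded half-away-from-zero
  and the residual `int − coord` is stored as the origin, so |origin| ≤ 0.5
  and shifting the extracted window by the origin re-centers it exactly.
* **Defocus**: positive defocus is underfocus. A sub-particle at height
  `z` px above the image plane gets `defocus − z·apix`; the sign is
  exposed (`sign=+1`) since different packages disagree, and at typical box
  sizes it only matters at sub-Ångström CTF fidelity.

## CTF model

`CTF(s, θ) = −[√(1−A²)·sin χ + A·cos χ]` with
`χ = π λ Δz(θ) s² − (π/2) Cs λ³ s⁴`, astigmatic
`Δz(θ) = (Δu+Δv)/2 + (Δu−Δv)/2 · cos 2(θ−θ₀)` and the relativistic electron
wavelength from the acceleration voltage. "Full" correction multiplies the
transform by the CTF; phase flipping multiplies by its sign (amplitudes
preserved — asserted away from the Nyquist row/column of even grids, where an
astigmatic sign field has no Hermitian-consistent definition).

## Projection and reconstruction

The projector extracts central slices from the FFT of the 2×-zero-padded map
with cubic-spline interpolation (the spline prefilter is applied once per
map); origins become phase ramps. A real-space rotate-and-sum projector is
kept in the package as an independent cross-check; the two agree to better
than 1e−3 relative RMS on band-limited phantoms over random poses, and at the
identity pose the Fourier path is exact.

Reconstruction is direct Fourier inversion: each image's origin-corrected,
CTF-premultiplied transform is spread onto the 3D grid with trilinear weights
at its pose, CTF² weights are accumulated, and the map is the inverse
transform of the Wiener-regularized quotient (constant: 1e−3 × mean weight,
exposed). Half-set reconstruction splits the stack randomly in two for FSC.

Metrics: FSC per one-voxel shell; resolution is the first linear-interpolated
crossing of the threshold (0.143 default), Nyquist if never crossed. The
B-factor is a Guinier fit (ln spherically-averaged amplitude vs 1/d²,
B = −4·slope) between 10 Å and 2.5× pixel size by default; sharpening applies
`exp(+B/4·s²)`. The estimator measures only the map's amplitude decay — no
detector MTF model. Low-pass filtering uses a cosine edge (2 Fourier px) and
preserves DC exactly.

## Bulk-signal subtraction

A spherical mask (optionally cosine-softened; binary by default in the CLI)
placed at the subunit vector's endpoint is symmetrized by voxelwise maximum
over the group (idempotent up to interpolation error). Masked voxels of the
whole-complex map are set to the background level — the mean of unmasked
voxels outside a generous particle radius (0.45 box default; a global-mean
option exists) — so no density step is introduced at the mask edge. The
masked map is projected per particle in its pose and origin, modulated by the
*particle-level* CTF (heights vary across the whole image, so the
height-adjusted defocus is reserved for the sub-particles), optionally scaled
by a single least-squares factor, and subtracted.

The least-squares scale is on by default for real data, where the reference
map's absolute greyscale is arbitrary; on synthetic data it is biased by
whatever signal the masked map does *not* contain (the subunits themselves)
and should be disabled — the oracle tests do.

## Occupancy and degenerate orientations

The original workflow delegated occupied/empty and 0°/120°/240° decisions to
maximum-likelihood 3D classification, which is out of scope. Two estimators
stand in:

* `score_occupancy`: mean intensity of the phase-flip-corrected window inside
  a centered disc, thresholded by Otsu. Valid when sites are well separated
  in projection; on crowded complexes neighbouring sites bleed into the disc.
* `unmix_occupancy`: per particle, the subtracted image is modelled as a
  linear combination of the reference projection placed at *every* candidate
  site; the fitted amplitudes are the scores. Joint fitting handles
  overlapping neighbours and antipodal sites that project onto each other; a
  ridge term (0.05 × mean Gram diagonal) stabilizes the nearly collinear
  pairs. Because the per-site orientation is unknown at this stage, the
  template is the orientation-invariant axis-average of the subunit
  (satellite smeared into a ring). The occupancy *fraction* is the weight of
  the upper component of a two-Gaussian mixture on the scores — the analogue
  of reading occupancy off class sizes — which stays accurate even where
  individual site calls are uncertain.

Degenerate orientations are then assigned per sub-particle by correlating its
neighbour-cleaned window with the CTF-modulated reference projection in each
of the n candidate poses (`M_sub(j) = M_sub · M_vecᵀ G_chosenᵀ G_j M_vec`).
A single projection cannot always break this degeneracy — orientations whose
satellite positions mirror across the projection of the symmetry axis are
genuinely indistinguishable in one view — so per-record assignment plateaus
below 100% even without noise (~90% on the default phantom). The aggregate
reconstruction tolerates the residual misassignments.

## Synthetic model

`PhantomSpec` describes a Gaussian-blob phantom: a shell of unit-amplitude
blobs (σ 5 Å) on the 60-point generic orbit of the icosahedral group at
44 Å radius, and an asymmetric subunit — a main blob (σ 4.5 Å, amplitude 2.5)
on each threefold axis at 32 Å plus a smaller satellite (σ 3 Å, amplitude
1.8) 8 Å off-axis so the three degenerate orientations are distinguishable —
present at 60% of the 20 sites, with the orientation drawn uniformly per
occupied site. The default study uses 64 px particles at 2 Å/px with 32 px
sub-particle windows, defocus 1.0–3.0 µm at 300 kV, and white Gaussian noise
set for a per-pixel SNR (clean-image variance over noise variance) of 0.1.
These sizes keep a 300-particle end-to-end validation within minutes on one
CPU while preserving the geometry of the problem (crowded, partially
overlapping sites; antipodal superposition in projection).

Clean images are rendered *analytically* — a 3D Gaussian projects to a
closed-form 2D Gaussian — so the simulator shares no code with the
Fourier-slice projector it validates. The noise stream is separate from the
structural draws, so different noise levels see identical particles.

What the phantom does not emulate: structural noise that symmetric averaging
cannot capture (e.g. packaged genome — exactly the component the subtraction
approach cannot remove from real images), conformational heterogeneity,
detector MTF, beam-induced motion, and orientation/origin errors from the
upstream refinement (simulated poses are exact). Passing tests therefore
validate the geometry, bookkeeping and signal-processing chain, not
robustness to misalignment.

## Design choices and limitations

* Overlap filtering defines pairwise overlap as `box − center distance` and
  removes *both* members of an offending pair by default (order-independent);
  a greedy keep-first mode exists. Side-view selection keeps records whose
  rotated vector lies within the given angle of the image plane; top-view
  exclusion removes records within that angle of the beam axis.
* Unique-position merging tolerance defaults to 1 px.
* CMM markers are read in Å relative to voxel (0,0,0) with the map center at
  `apix·floor(N/2)` per axis (overridable); the marker radius is ignored.
* The STAR writer emits the legacy dialect deliberately; floats carry six
  decimals.
* MRC I/O supports mode 2 (32-bit float) only.
* No gold-standard mask-bias correction (phase randomization) and no local
  resolution estimation; the FSC here assesses synthetic reconstructions.
* Re-refinement of sub-particle orientations is out of scope; poses come from
  the whole-complex refinement by construction.
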