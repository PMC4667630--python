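"""Bulk-complex signal subtraction.

To leave a sub-particle dominated by the subunit of interest, the rest of the
complex is removed from each particle image: a mask covering the subunit (and
its symmetry mates) is cut out of the whole-complex reconstruction, the voxels
under the mask are set to background, and the resulting "everything but the
subunit" map is projected in each particle's orientation, CTF-modulated with
the particle's defocus, optionally intensity-scaled, and subtracted from the
image.

The projector extracts central slices from the Fourier transform of the
2×-oversampled map (trilinear interpolation); a real-space rotate-and-sum
implementation is kept as an independent cross-check.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import PointGroup, SubunitVector, euler_to_matrix
from .io import CtfParams, DensityMap, MaskMap, ParticleRecord

__all__ = [
    "make_spherical_mask",
    "symmetrize_mask",
    "mask_to_background",
    "FourierProjector",
    "project",
    "project_real_space",
    "electron_wavelength",
    "ctf_evaluate",
    "ctf_image",
    "apply_ctf",
    "subtract_projection",
    "subtract_stack",
]


def _centered_radius_grid(n: int):
    c = n // 2
    z, y, x = np.ogrid[0:n, 0:n, 0:n]
    return x - c, y - c, z - c


def make_spherical_mask(center_vector: SubunitVector, diameter: float,
                        box_size: int, apix: float,
                        soft_edge_px: float = 0.0) -> MaskMap:
    """Spherical mask at the subunit vector's endpoint.

    ``diameter`` in Å; with ``soft_edge_px > 0`` the mask falls from 1 to 0
    over a cosine ramp of that width outside the nominal radius.
    """
    r_px = 0.5 * diameter / apix
    ctr = box_size // 2 + center_vector.cartesian / apix  # (x, y, z) voxel coords
    if np.any(ctr - r_px < 0) or np.any(ctr + r_px > box_size - 1):
        raise ValueError("sphere does not fit inside the grid")
    x, y, z = _centered_radius_grid(box_size)
    rho = np.sqrt((x - (ctr[0] - box_size // 2)) ** 2
                  + (y - (ctr[1] - box_size // 2)) ** 2
                  + (z - (ctr[2] - box_size // 2)) ** 2)
    if soft_edge_px > 0:
        vals = np.clip((r_px + soft_edge_px - rho) / soft_edge_px, 0.0, 1.0)
        vals = np.where(rho <= r_px, 1.0, 0.5 - 0.5 * np.cos(np.pi * vals))
    else:
        vals = (rho <= r_px).astype(float)
    return MaskMap(data=vals.astype(np.float32), apix=apix)


def _rotate_volume(data: np.ndarray, rot: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample so that out(x) = in(rot⁻¹ x), rotating about the center voxel."""
    n = data.shape[0]
    c = np.full(3, n // 2, dtype=float)
    p = np.eye(3)[::-1]                      # (z,y,x) index <-> (x,y,z) coords
    m = p @ rot.T @ p                        # index-space matrix for rot⁻¹
    return ndimage.affine_transform(data, m, offset=c - m @ c, order=order,
                                    mode="constant", cval=0.0, prefilter=order > 1)


def symmetrize_mask(mask: MaskMap, group: PointGroup) -> MaskMap:
    """Voxelwise maximum of the mask over every rotation of the point group."""
    out = np.array(mask.data, dtype=np.float32)
    for g in group.matrices:
        if np.allclose(g, np.eye(3)):
            continue
        np.maximum(out, _rotate_volume(mask.data, g), out=out)
    return MaskMap(data=np.clip(out, 0.0, 1.0), apix=mask.apix)


def mask_to_background(dmap: DensityMap, mask: MaskMap,
                       particle_radius_px: float | None = None,
                       background: str = "solvent") -> DensityMap:
    """Replace masked voxels by the background level.

    Background is the mean of unmasked voxels outside a generous particle
    radius (default 0.45 × box, the solvent region) or, with
    ``background="global"``, the mean of all unmasked voxels. Soft mask values
    blend linearly between map and background.
    """
    if dmap.data.shape != mask.data.shape:
        raise ValueError("map and mask grids differ")
    m = mask.data
    if float(m.min()) >= 0.5:
        raise ValueError("mask covers the entire grid; nothing left to keep")
    n = dmap.data.shape[0]
    if background == "global":
        sel = m < 0.5
    else:
        r = particle_radius_px if particle_radius_px is not None else 0.45 * n
        x, y, z = _centered_radius_grid(n)
        solvent = (x * x + y * y + z * z) > r * r
        sel = solvent & (m < 0.5)
        if not sel.any():
            sel = m < 0.5
    bg = float(dmap.data[sel].mean())
    out = dmap.data * (1.0 - m) + bg * m
    return dmap.copy_with(out.astype(np.float32))


# ---------------------------------------------------------------------------
# projection


class FourierProjector:
    """Central-slice projector for one map (precomputes the oversampled FFT).

    ``project(euler, origin)`` returns the orthographic line integral of the
    map along the beam after rotating it by the pose, displaced by −origin —
    i.e. the projection exactly as it appears in a particle image whose STAR
    origin is ``origin``.
    """

    def __init__(self, dmap: DensityMap, pad: int = 2, order: int = 3):
        data = np.asarray(dmap.data, dtype=np.float64)
        n = data.shape[0]
        if data.shape != (n, n, n):
            raise ValueError("projector requires a cubic map")
        self.n = n
        self.pad = pad
        self.order = order
        self.apix = dmap.apix
        np_ = n * pad
        padded = np.zeros((np_, np_, np_))
        lo = (np_ - n) // 2
        padded[lo:lo + n, lo:lo + n, lo:lo + n] = data
        fvol = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
        if order > 1:  # prefilter once, not per projection
            self._fre = ndimage.spline_filter(fvol.real, order=order)
            self._fim = ndimage.spline_filter(fvol.imag, order=order)
        else:
            self._fre, self._fim = fvol.real, fvol.imag
        self._cp = np_ // 2
        k = np.fft.fftshift(np.fft.fftfreq(n)) * n     # centered integer freq
        self._ky, self._kx = np.meshgrid(k, k, indexing="ij")

    def project(self, euler, origin=(0.0, 0.0)) -> np.ndarray:
        a = euler_to_matrix(np.asarray(euler, dtype=float))
        # slice coords: Aᵀ (kx, ky, 0), in padded-frequency index units
        kx, ky = self._kx, self._ky
        pts = (a[0][:, None, None] * kx + a[1][:, None, None] * ky)  # (3, n, n) = Aᵀ·k
        coords = self._cp + self.pad * pts[::-1]       # index order (z, y, x)
        fsl = (ndimage.map_coordinates(self._fre, coords, order=self.order, prefilter=False)
               + 1j * ndimage.map_coordinates(self._fim, coords, order=self.order,
                                              prefilter=False))
        ox, oy = origin
        phase = np.exp(2j * np.pi * (kx * ox + ky * oy) / self.n)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(fsl * phase)))
        return np.ascontiguousarray(img.real)


def project(dmap: DensityMap, euler, origin=(0.0, 0.0), pad: int = 2) -> np.ndarray:
    """One projection of a map (see :class:`FourierProjector`)."""
    return FourierProjector(dmap, pad=pad).project(euler, origin)


def project_real_space(dmap: DensityMap, euler, origin=(0.0, 0.0),
                       order: int = 3) -> np.ndarray:
    """Rotate-and-sum reference projector (independent of the Fourier path)."""
    a = euler_to_matrix(np.asarray(euler, dtype=float))
    # image(w) = sum_t V(Aᵀ (w, t)): resample V at Aᵀ·grid then sum over z
    rotated = _rotate_volume(np.asarray(dmap.data, float), a, order=order)
    img = rotated.sum(axis=0)
    if origin != (0.0, 0.0):
        img = ndimage.shift(img, (-origin[1], -origin[0]), order=order)
    return img


# ---------------------------------------------------------------------------
# CTF


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for a voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def ctf_evaluate(ctf: CtfParams, spatial_freq, azimuth=0.0):
    """CTF value(s) at spatial frequency s (1/Å) and azimuth (degrees).

    CTF(s, θ) = −[√(1−A²)·sin χ + A·cos χ] with
    χ = π λ Δz(θ) s² − (π/2) Cs λ³ s⁴ and the astigmatic defocus
    Δz(θ) = (Δu+Δv)/2 + (Δu−Δv)/2 · cos 2(θ−θ_astig). Positive defocus
    (underfocus) makes protein dark at low resolution.
    """
    s = np.asarray(spatial_freq, dtype=float)
    theta = np.deg2rad(np.asarray(azimuth, dtype=float))
    lam = electron_wavelength(ctf.voltage)
    dz = (0.5 * (ctf.defocus_u + ctf.defocus_v)
          + 0.5 * (ctf.defocus_u - ctf.defocus_v)
          * np.cos(2.0 * (theta - np.deg2rad(ctf.astig_angle))))
    cs = ctf.cs * 1e7  # mm -> Å
    chi = np.pi * lam * dz * s ** 2 - 0.5 * np.pi * cs * lam ** 3 * s ** 4
    a = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_image(ctf: CtfParams, n: int, apix: float) -> np.ndarray:
    """The CTF sampled on the centered 2D frequency grid of an n×n image."""
    k = np.fft.fftshift(np.fft.fftfreq(n, d=apix))
    ky, kx = np.meshgrid(k, k, indexing="ij")
    s = np.hypot(kx, ky)
    az = np.degrees(np.arctan2(ky, kx))
    return ctf_evaluate(ctf, s, az)


def apply_ctf(image: np.ndarray, ctf: CtfParams, apix: float,
              mode: str = "full") -> np.ndarray:
    """Modulate an image by the CTF ("full") or by its sign ("phase_flip")."""
    if mode not in ("full", "phase_flip"):
        raise ValueError(f"unknown CTF mode {mode!r}")
    h = ctf_image(ctf, image.shape[0], apix)
    if mode == "phase_flip":
        h = np.sign(h)
        h[h == 0] = 1.0
    f = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))
    out = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(f * h)))
    return out.real


# ---------------------------------------------------------------------------
# subtraction


def subtract_projection(particle_image: np.ndarray, masked_map: DensityMap,
                        p: ParticleRecord, scale: bool = True,
                        projector: FourierProjector | None = None) -> np.ndarray:
    """Particle image minus the CTF-modulated projection of the masked map.

    The projection uses the particle's pose, origin and (particle-level)
    defocus. With ``scale=True`` a single least-squares intensity scalar
    between projection and image is applied before subtracting.
    """
    if abs(p.pixel_size - masked_map.apix) > 1e-6:
        raise ValueError(
            f"pixel size mismatch: particle {p.pixel_size} Å vs map {masked_map.apix} Å")
    proj = (projector or FourierProjector(masked_map)).project(p.euler, p.origin)
    if p.ctf is not None:
        proj = apply_ctf(proj, p.ctf, p.pixel_size, mode="full")
    if scale:
        denom = float(np.vdot(proj, proj).real)
        a = float(np.vdot(proj, particle_image).real) / denom if denom > 0 else 0.0
    else:
        a = 1.0
    return particle_image - a * proj


def subtract_stack(images: np.ndarray, masked_map: DensityMap,
                   particles: list[ParticleRecord], scale: bool = True) -> np.ndarray:
    """Apply :func:`subtract_projection` to a whole stack, reusing one projector."""
    projector = FourierProjector(masked_map)
    out = np.empty_like(np.asarray(images, dtype=np.float32))
    for i, p in enumerate(particles):
        out[i] = subtract_projection(images[i], masked_map, p, scale=scale,
                                     projector=projector)
    return out
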