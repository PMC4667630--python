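"""Synthetic ground-truth phantoms and simulated particle data.

The generator emulates the situation localized reconstruction targets: a
symmetric shell (Gaussian blobs on a symmetry orbit) carrying an asymmetric
subunit at only a fraction of its symmetry-related sites (sub-stoichiometric
occupancy), each occupied site holding the subunit in one of its degenerate
orientations chosen at random. Clean particle images are rendered
analytically — the orthographic projection of a Gaussian blob is a
closed-form 2D Gaussian — so the simulator is independent of the package's
Fourier-slice projector and can serve as its oracle. Voxel phantoms of the
same blob model are rendered for all map-space operations.

The subunit is a two-blob cluster (main blob plus a smaller satellite off the
vector axis) so that its degenerate orientations on a symmetry axis are
distinguishable, as they must be for orientation assignment to mean anything.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation as _Rotation

from .geometry import (SubunitVector, euler_to_matrix, matrix_to_euler,
                       point_group, vector_to_matrix)
from .io import CtfParams, DensityMap
from .subtraction import FourierProjector, apply_ctf
from .subparticles import site_cosets

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "subunit_reference_map",
    "simulate_particles",
    "score_occupancy",
    "unmix_occupancy",
    "subunit_axis_average_map",
    "assign_orientations",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Blob model of a symmetric shell with a sub-stoichiometric subunit.

    Lengths in Å. Defaults describe the study conditions used throughout the
    package's validation: an icosahedral shell with the asymmetric subunit on
    the threefold axes at 60% occupancy — a scaled-down stand-in for a
    polymerase inside a dodecahedral capsid.
    """

    symmetry: str = "I"
    shell_radius: float = 44.0
    shell_sigma: float = 5.0
    shell_amp: float = 1.0
    vector: SubunitVector = field(
        default_factory=lambda: SubunitVector(direction=(1.0, 1.0, 1.0), length=32.0))
    subunit_sigma: float = 4.5
    subunit_amp: float = 2.5
    satellite_offset: float = 8.0
    satellite_sigma: float = 3.0
    satellite_amp: float = 1.8
    occupancy: float = 0.6
    degenerate_marker: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


# fixed generic direction whose orbit forms the shell
_SHELL_DIR = np.array([0.31, 0.57, 0.76]) / np.linalg.norm([0.31, 0.57, 0.76])


def _shell_centers(spec: PhantomSpec) -> np.ndarray:
    group = point_group(spec.symmetry)
    return group.orbit(_SHELL_DIR * spec.shell_radius, tol=1e-6)


def _subunit_local_blobs(spec: PhantomSpec):
    """Blob centers/sigmas/amps of the subunit in its own frame (z = vector)."""
    centers = [np.zeros(3)]
    sigmas = [spec.subunit_sigma]
    amps = [spec.subunit_amp]
    if spec.degenerate_marker:
        centers.append(np.array([spec.satellite_offset, 0.0, 0.0]))
        sigmas.append(spec.satellite_sigma)
        amps.append(spec.satellite_amp)
    return np.asarray(centers), np.asarray(sigmas), np.asarray(amps)


def _site_blobs(spec: PhantomSpec, occupied, orient_idx) -> tuple[np.ndarray, ...]:
    """Blob parameters (map frame) for the occupied subunit copies."""
    group = point_group(spec.symmetry)
    cosets = site_cosets(group, spec.vector, tol_ang=1.0)
    m_vec = vector_to_matrix(spec.vector)
    q, sig, amp = _subunit_local_blobs(spec)
    p0 = spec.vector.cartesian
    centers, sigmas, amps = [], [], []
    for s, (occ, j) in enumerate(zip(occupied, orient_idx)):
        if not occ:
            continue
        g = group.matrices[cosets[s][j % len(cosets[s])]]
        placed = (g @ ((m_vec @ q.T).T + p0).T).T
        centers.extend(placed)
        sigmas.extend(sig)
        amps.extend(amp)
    if not centers:
        return np.empty((0, 3)), np.empty(0), np.empty(0)
    return np.asarray(centers), np.asarray(sigmas), np.asarray(amps)


def render_blobs(box: int, apix: float, centers, sigmas, amps) -> np.ndarray:
    """Sum of isotropic 3D Gaussians on a voxel grid (separable evaluation)."""
    centers = np.asarray(centers, float).reshape(-1, 3)
    sigmas = np.broadcast_to(np.asarray(sigmas, float), (len(centers),))
    amps = np.broadcast_to(np.asarray(amps, float), (len(centers),))
    if len(centers) == 0:
        return np.zeros((box, box, box), dtype=np.float32)
    lim = (np.abs(centers).max(axis=1) + 4.0 * sigmas) / apix
    if np.any(lim > box // 2):
        raise ValueError("blobs exceed the grid")
    ax = (np.arange(box) - box // 2) * apix
    g = [np.exp(-0.5 * ((ax[None, :] - centers[:, i:i + 1]) / sigmas[:, None]) ** 2)
         for i in range(3)]  # (nblob, box) per axis x, y, z
    vol = np.einsum("b,bz,by,bx->zyx", amps, g[2], g[1], g[0])
    return vol.astype(np.float32)


def render_blob_projection(box: int, apix: float, centers, sigmas, amps,
                           pose_matrix: np.ndarray, origin=(0.0, 0.0)) -> np.ndarray:
    """Exact orthographic projection of a Gaussian-blob model.

    Each 3D blob projects to a 2D Gaussian of the same σ with integrated
    amplitude ``amp · σ √(2π) / apix`` (the voxel-sum convention), centered at
    the image-frame position of the blob shifted by −origin.
    """
    centers = np.asarray(centers, float).reshape(-1, 3)
    if len(centers) == 0:
        return np.zeros((box, box), dtype=np.float64)
    sigmas = np.broadcast_to(np.asarray(sigmas, float), (len(centers),))
    amps = np.broadcast_to(np.asarray(amps, float), (len(centers),))
    proj = (pose_matrix @ centers.T).T[:, :2] / apix  # px from image center
    c = box // 2
    cx = c + proj[:, 0] - origin[0]
    cy = c + proj[:, 1] - origin[1]
    s_px = sigmas / apix
    a2d = amps * sigmas * np.sqrt(2.0 * np.pi) / apix
    ax = np.arange(box)
    gx = np.exp(-0.5 * ((ax[None, :] - cx[:, None]) / s_px[:, None]) ** 2)
    gy = np.exp(-0.5 * ((ax[None, :] - cy[:, None]) / s_px[:, None]) ** 2)
    return np.einsum("b,by,bx->yx", a2d, gy, gx)


def make_phantom(spec: PhantomSpec, box: int, apix: float,
                 rng: np.random.Generator | None = None):
    """One realization of the phantom.

    Returns ``(full, shell_only, subunit_only, manifest)`` maps plus a
    manifest dict recording, per site, the occupied flag and the degenerate
    orientation index drawn.
    """
    rng = rng or np.random.default_rng(spec.seed)
    group = point_group(spec.symmetry)
    cosets = site_cosets(group, spec.vector, tol_ang=1.0)
    n_sites = len(cosets)
    occupied = rng.random(n_sites) < spec.occupancy
    orient = np.array([rng.integers(0, len(c)) for c in cosets])

    sc = _shell_centers(spec)
    shell = render_blobs(box, apix, sc, spec.shell_sigma, spec.shell_amp)
    bc, bs, ba = _site_blobs(spec, occupied, orient)
    subunit = render_blobs(box, apix, bc, bs, ba) if len(bc) else np.zeros_like(shell)
    manifest = {
        "n_sites": n_sites,
        "occupied": occupied.tolist(),
        "orientation": orient.tolist(),
        "stabilizer_order": len(cosets[0]),
    }
    return (DensityMap(shell + subunit, apix), DensityMap(shell, apix),
            DensityMap(subunit, apix), manifest)


def subunit_reference_map(spec: PhantomSpec, box: int, apix: float) -> DensityMap:
    """The subunit cluster alone, centered, in its own (sub-particle) frame."""
    q, sig, amp = _subunit_local_blobs(spec)
    return DensityMap(render_blobs(box, apix, q, sig, amp), apix)


def subunit_axis_average_map(spec: PhantomSpec, box: int, apix: float,
                             n_steps: int = 24) -> DensityMap:
    """The subunit reference averaged over rotation about the symmetry axis.

    Because the degenerate orientation of each copy is unknown before
    classification, occupancy detection uses this orientation-invariant
    template: the on-axis main blob plus the satellite smeared into a ring.
    """
    ang = np.linspace(0.0, 2.0 * np.pi, n_steps, endpoint=False)
    centers = [np.zeros(3)]
    sigmas = [spec.subunit_sigma]
    amps = [spec.subunit_amp]
    if spec.degenerate_marker:
        centers += [np.array([spec.satellite_offset * np.cos(a),
                              spec.satellite_offset * np.sin(a), 0.0]) for a in ang]
        sigmas += [spec.satellite_sigma] * n_steps
        amps += [spec.satellite_amp / n_steps] * n_steps
    return DensityMap(render_blobs(box, apix, centers, sigmas, amps), apix)


def simulate_particles(spec: PhantomSpec, n: int, box: int, apix: float,
                       noise_sigma: float = 0.0,
                       defocus_range: tuple[float, float] = (10000.0, 30000.0),
                       seed: int = 0, poses=None, origin_max: float = 2.0,
                       ctf_ref: CtfParams | None = None):
    """Simulate a dataset of whole-complex particle images.

    Per particle: a pose sampled uniformly over SO(3) (or taken from
    ``poses``), a per-site occupancy/orientation draw, a defocus drawn from
    ``defocus_range`` (Å), an origin drawn uniformly in ±``origin_max`` px.
    The clean image is the analytic projection of the particle's own blob
    phantom, CTF-modulated, plus white Gaussian noise of σ ``noise_sigma``.

    Returns ``(stack, star, manifest)``: the image stack (n, box, box), a
    Relion-style STAR table with the true poses and CTFs, and a manifest list
    with per-particle ground truth (pose, origin, occupancy, orientations).
    """
    if n < 1:
        raise ValueError("need at least one particle")
    # separate stream for noise so the structural draws (poses, occupancy,
    # orientations, defoci) are identical across noise levels
    rng, noise_rng = np.random.default_rng(seed).spawn(2)
    group = point_group(spec.symmetry)
    cosets = site_cosets(group, spec.vector, tol_ang=1.0)
    n_sites = len(cosets)
    sc = _shell_centers(spec)
    base = ctf_ref or CtfParams(defocus_u=0.0, defocus_v=0.0)

    stack = np.empty((n, box, box), dtype=np.float32)
    rows, manifest = [], []
    for i in range(n):
        if poses is not None:
            euler = np.asarray(poses[i], float)
            a = euler_to_matrix(euler)
        else:
            quat = rng.normal(size=4)
            a = _Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            euler = np.asarray(matrix_to_euler(a), float)
        origin = rng.uniform(-origin_max, origin_max, size=2) if origin_max > 0 else np.zeros(2)
        occupied = rng.random(n_sites) < spec.occupancy
        orient = np.array([rng.integers(0, len(c)) for c in cosets])

        bc, bs, ba = _site_blobs(spec, occupied, orient)
        centers = np.vstack([sc, bc]) if len(bc) else sc
        sigmas = np.concatenate([np.full(len(sc), spec.shell_sigma), bs])
        amps = np.concatenate([np.full(len(sc), spec.shell_amp), ba])
        img = render_blob_projection(box, apix, centers, sigmas, amps, a, origin)

        dfoc = float(rng.uniform(*defocus_range))
        ctf = CtfParams(defocus_u=dfoc, defocus_v=dfoc,
                        astig_angle=0.0, voltage=base.voltage, cs=base.cs,
                        amplitude_contrast=base.amplitude_contrast)
        img = apply_ctf(img, ctf, apix, mode="full")
        if noise_sigma > 0:
            img = img + noise_rng.normal(0.0, noise_sigma, size=img.shape)
        stack[i] = img.astype(np.float32)

        rows.append({
            "rlnImageName": f"{i + 1}@simulated.mrcs",
            "rlnCoordinateX": box // 2, "rlnCoordinateY": box // 2,
            "rlnAngleRot": euler[0], "rlnAngleTilt": euler[1], "rlnAnglePsi": euler[2],
            "rlnOriginX": origin[0], "rlnOriginY": origin[1],
            "rlnDefocusU": dfoc, "rlnDefocusV": dfoc, "rlnDefocusAngle": 0.0,
            "rlnVoltage": base.voltage, "rlnSphericalAberration": base.cs,
            "rlnAmplitudeContrast": base.amplitude_contrast,
            "rlnMagnification": 10000.0, "rlnDetectorPixelSize": apix,
        })
        manifest.append({
            "euler": euler.tolist(), "origin": origin.tolist(),
            "defocus": dfoc,
            "occupied": occupied.tolist(), "orientation": orient.tolist(),
        })
    return stack, pd.DataFrame(rows), manifest


def _records_ctfs(records: pd.DataFrame):
    if "rlnDefocusU" not in records.columns:
        return None
    return [CtfParams(defocus_u=float(r["rlnDefocusU"]),
                      defocus_v=float(r.get("rlnDefocusV", r["rlnDefocusU"])),
                      astig_angle=float(r.get("rlnDefocusAngle", 0.0)),
                      voltage=float(r.get("rlnVoltage", 300.0)),
                      cs=float(r.get("rlnSphericalAberration", 2.7)),
                      amplitude_contrast=float(r.get("rlnAmplitudeContrast", 0.1)))
            for _, r in records.iterrows()]


def _record_template(projector: FourierProjector, row, apix: float, src_box: int,
                     ctf: CtfParams | None) -> np.ndarray:
    """CTF-modulated projection of a centered reference placed at one record's
    site in its parent particle image (as the image would show it)."""
    dx = float(row["rlnCoordinateX"]) - float(row.get("rlnOriginX", 0.0)) - src_box // 2
    dy = float(row["rlnCoordinateY"]) - float(row.get("rlnOriginY", 0.0)) - src_box // 2
    t = projector.project((row["rlnAngleRot"], row["rlnAngleTilt"], row["rlnAnglePsi"]),
                          (-dx, -dy))
    if ctf is not None:
        t = apply_ctf(t, ctf, apix, mode="full")
    return t


def unmix_occupancy(images: np.ndarray, records: pd.DataFrame,
                    reference: DensityMap, apix: float, src_box: int,
                    ridge: float = 0.05, window_box: int | None = None,
                    random_state: int = 0):
    """Per-site subunit amplitudes by joint least squares, and the occupancy.

    For each particle, the (bulk-subtracted) image is modelled as a linear
    combination of the CTF-modulated reference projections at every candidate
    site; the fitted amplitudes are the occupancy scores. Fitting all sites
    jointly is what makes overlapping neighbours (and antipodal sites that
    project onto each other) tractable; a small ridge term (``ridge`` × mean
    Gram diagonal) stabilizes nearly collinear site pairs. The occupancy
    fraction is the weight of the high-amplitude component of a two-Gaussian
    mixture fitted to the scores — the analogue of reading occupancy off
    classification class sizes — and per-record flags are the component
    posteriors. ``reference`` should be orientation-invariant (see
    :func:`subunit_axis_average_map`).

    Returns ``(scores, occupied_flags, occupancy_fraction, cleaned)`` where
    ``cleaned[i]`` is record i's window (``window_box`` px) cut from its
    particle image after subtracting the fitted contributions of all *other*
    sites — the input orientation assignment wants.
    """
    from sklearn.mixture import GaussianMixture

    records = records.reset_index(drop=True)
    ctfs = _records_ctfs(records)
    projector = FourierProjector(reference)
    wb = window_box or src_box // 2
    half = wb // 2
    scores = np.zeros(len(records))
    cleaned = np.zeros((len(records), wb, wb), dtype=np.float32)
    for pid, rows in records.groupby("lrParentIndex"):
        idx = rows.index.to_numpy()
        templates = np.array([
            _record_template(projector, rows.loc[i], apix, src_box,
                             ctfs[i] if ctfs is not None else None)
            for i in idx])
        b = templates.reshape(len(idx), -1).T
        gram = b.T @ b
        lam = ridge * float(np.mean(np.diag(gram)))
        beta = np.linalg.solve(gram + lam * np.eye(len(idx)),
                               b.T @ np.asarray(images[pid], float).ravel())
        scores[idx] = beta
        fitted = np.tensordot(beta, templates, axes=1)
        for j, i in enumerate(idx):
            resid = images[pid] - (fitted - beta[j] * templates[j])
            x0 = int(rows.loc[i, "rlnCoordinateX"]) - half
            y0 = int(rows.loc[i, "rlnCoordinateY"]) - half
            # clip to the image; out-of-bounds parts of the window stay zero
            sx = slice(max(x0, 0), min(x0 + wb, src_box))
            sy = slice(max(y0, 0), min(y0 + wb, src_box))
            if sx.start < sx.stop and sy.start < sy.stop:
                cleaned[i, sy.start - y0:sy.stop - y0,
                        sx.start - x0:sx.stop - x0] = resid[sy, sx]

    gm = GaussianMixture(2, random_state=random_state).fit(scores.reshape(-1, 1))
    hi = int(np.argmax(gm.means_.ravel()))
    occupancy = float(gm.weights_[hi])
    flags = gm.predict_proba(scores.reshape(-1, 1))[:, hi] > 0.5
    return scores, flags, occupancy, cleaned


def score_occupancy(substack: np.ndarray, records: pd.DataFrame, apix: float,
                    footprint_radius_px: float, threshold: float | None = None):
    """Per-sub-particle occupancy score and a two-class labelling.

    The score is the mean intensity of the phase-flip CTF-corrected
    sub-particle image inside a centered disc covering the subunit footprint
    (protein is positive after correction). Unless an explicit ``threshold``
    is given the occupied/empty split is Otsu's two-class threshold on the
    score histogram. Returns ``(scores, occupied_flags)``.
    """
    from skimage.filters import threshold_otsu
    box = substack.shape[-1]
    yy, xx = np.mgrid[0:box, 0:box]
    disc = np.hypot(yy - box // 2, xx - box // 2) <= footprint_radius_px
    ctfs = _records_ctfs(records)
    scores = np.empty(len(substack))
    for i in range(len(substack)):
        img = substack[i]
        if ctfs is not None:
            img = apply_ctf(img, ctfs[i], apix, mode="phase_flip")
        scores[i] = img[disc].mean()
    thr = threshold_otsu(scores) if threshold is None else threshold
    return scores, scores > thr


def assign_orientations(substack: np.ndarray, records: pd.DataFrame,
                        reference: DensityMap, group, vector: SubunitVector,
                        pixel_size: float, merge_tol_px: float = 1.0):
    """Pick the best of the degenerate orientations for each sub-particle.

    For a subunit on an n-fold axis the expansion stored one of n equivalent
    poses; this compares each sub-particle image against the CTF-modulated
    reference projection in all n candidate poses (correlation) and returns
    the winning orientation index per record plus a copy of ``records`` with
    the Euler angles rotated accordingly — the stand-in for the paper-era
    3D classification step that separated the 0°/120°/240° classes.
    """
    cosets = site_cosets(group, vector, tol_ang=merge_tol_px * pixel_size)
    m_vec = vector_to_matrix(vector)
    projector = FourierProjector(reference)
    ctfs = _records_ctfs(records)
    euler = records[["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]].to_numpy(float)
    origin = records.reindex(columns=["rlnOriginX", "rlnOriginY"],
                             fill_value=0.0).to_numpy(float)
    sites = records["lrSiteIndex"].to_numpy(int)
    chosen = records["lrOrientIndex"].to_numpy(int)

    best = np.zeros(len(records), dtype=int)
    new_euler = euler.copy()
    for i in range(len(records)):
        cs = cosets[sites[i]]
        m_chosen = euler_to_matrix(euler[i])
        # M_sub(j) = M_sub(chosen) · M_vecᵀ G_chosenᵀ G_j M_vec
        g_ch = group.matrices[cs[chosen[i]]]
        scores = np.empty(len(cs))
        cands = []
        for j, gj in enumerate(group.matrices[cs]):
            mj = m_chosen @ m_vec.T @ g_ch.T @ gj @ m_vec
            ej = np.asarray(matrix_to_euler(mj), float)
            cands.append(ej)
            proj = projector.project(ej, origin[i])
            if ctfs is not None:
                proj = apply_ctf(proj, ctfs[i], pixel_size, mode="full")
            num = float(np.vdot(proj, substack[i]).real)
            den = float(np.linalg.norm(proj) * np.linalg.norm(substack[i]))
            scores[j] = num / den if den > 0 else 0.0
        best[i] = int(np.argmax(scores))
        new_euler[i] = cands[best[i]]
    out = records.copy()
    out[["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]] = new_euler
    out["lrAssignedOrient"] = best
    return best, out
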