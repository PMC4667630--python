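"""Sub-particle generation, filtering and extraction.

A sub-particle is a window of a particle image centered on one subunit of the
complex, thereafter treated as an independent single particle. For every
particle pose and every symmetry-distinct position of the subunit vector this
module computes the sub-particle's Euler angles, its integer extraction
coordinates, the sub-pixel residual stored as the origin, and a defocus
adjusted for the subunit's height along the beam.

When the subunit sits on an n-fold symmetry axis, n group elements map it to
the same position while rotating it in place; these are the degenerate
orientations. One is chosen uniformly at random per sub-particle (seeded) so
that downstream classification is not biased toward any of them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (EulerTriplet, PointGroup, SubunitVector,
                       euler_to_matrix, matrix_to_euler, vector_to_matrix)
from .io import CtfParams, ParticleRecord

__all__ = [
    "SubParticleRecord",
    "FilterOptions",
    "site_cosets",
    "expand_symmetry",
    "expand_star",
    "degenerate_eulers",
    "adjust_defocus",
    "split_subpixel",
    "filter_side_views",
    "filter_overlaps",
    "extract_subparticles",
    "occupancy_summary",
]


@dataclass(frozen=True)
class SubParticleRecord:
    """One sub-particle: derived pose, extraction coordinates, adjusted CTF."""

    parent_id: int
    site_index: int
    euler: EulerTriplet
    origin: tuple[float, float]          # sub-pixel residual, px, each in [-0.5, 0.5]
    extract_coord: tuple[int, int]       # integer px in the source image
    z_height: float                      # px, signed, along the beam
    ctf: CtfParams | None
    offset_px: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation_index: int = 0           # which degenerate orientation was chosen
    edge_clipped: bool = False


@dataclass(frozen=True)
class FilterOptions:
    """User-facing knobs for sub-particle generation and filtering."""

    side_max_angle: float | None = None   # degrees from the image plane
    exclude_top_views: bool = False
    max_overlap: float | None = None      # px
    unique_merge_tolerance: float = 1.0   # px
    seed: int = 0

    def __post_init__(self):
        if self.side_max_angle is not None and not 0 <= self.side_max_angle <= 90:
            raise ValueError("side_max_angle must be in [0, 90] degrees")
        if self.unique_merge_tolerance < 0:
            raise ValueError("unique_merge_tolerance must be >= 0")


def site_cosets(group: PointGroup, v: SubunitVector, tol_ang: float) -> list[np.ndarray]:
    """Group the symmetry elements by the position they send the subunit to.

    Returns, per symmetry-distinct position (within ``tol_ang`` Å), the array
    of indices into ``group.matrices`` that land there — the coset of the
    vector's stabilizer. All cosets have equal size |stabilizer|.
    """
    pts = group.matrices @ v.cartesian
    cosets: list[list[int]] = []
    centers: list[np.ndarray] = []
    for i, p in enumerate(pts):
        for j, c in enumerate(centers):
            if np.linalg.norm(p - c) <= tol_ang:
                cosets[j].append(i)
                break
        else:
            centers.append(p)
            cosets.append([i])
    return [np.asarray(c, dtype=int) for c in cosets]


def split_subpixel(coord):
    """Split a coordinate into its nearest integer and the residual origin.

    Rounds half away from zero so that ``origin = int - coord`` always lies in
    [-0.5, 0.5]; shifting the window extracted at the integer position by the
    origin re-centers the true coordinate exactly.
    """
    c = np.asarray(coord, dtype=float)
    i = np.where(c >= 0, np.floor(c + 0.5), np.ceil(c - 0.5))
    origin = i - c
    if np.isscalar(coord) or c.ndim == 0:
        return int(i), float(origin)
    return i.astype(int), origin


def adjust_defocus(ctf: CtfParams, z_height: float, pixel_size: float,
                   sign: float = -1.0) -> CtfParams:
    """Defocus corrected for the subunit's height along the beam.

    A sub-particle above the particle center (z > 0, toward the electron
    source) is farther from focus on the underfocus side by ``z * pixel_size``
    less, i.e. both defocus values shift by ``-z * pixel_size`` by default.
    Pass ``sign=+1`` to invert the convention. The astigmatism angle is
    unchanged; the shift is linear (additive) in z.
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    return ctf.shifted(sign * z_height * pixel_size)


def _expand_arrays(euler: np.ndarray, origin: np.ndarray, group: PointGroup,
                   v: SubunitVector, opts: FilterOptions, pixel_size: float,
                   src_box: int | None, rng: np.random.Generator):
    """Vectorized core: sub-particle pose/position arrays for N particles.

    Returns a dict of flat arrays of length N * n_sites, particle-major.
    """
    n = len(euler)
    cosets = site_cosets(group, v, opts.unique_merge_tolerance * pixel_size)
    n_sites = len(cosets)
    m_vec = vector_to_matrix(v)
    a_part = euler_to_matrix(euler)                       # (n, 3, 3)

    # per (particle, site): random coset member = degenerate orientation
    gsel = np.empty((n, n_sites), dtype=int)
    oidx = np.empty((n, n_sites), dtype=int)
    for s, cs in enumerate(cosets):
        k = rng.integers(0, len(cs), size=n)
        oidx[:, s] = k
        gsel[:, s] = cs[k]
    g_mats = group.matrices[gsel]                          # (n, n_sites, 3, 3)
    m_sub = np.einsum("nij,nsjk,kl->nsil", a_part, g_mats, m_vec)
    sub_euler = matrix_to_euler(m_sub)                     # (n, n_sites, 3)

    # positions: same for every coset member — use the first
    reps = np.array([cs[0] for cs in cosets])
    pos_map = group.matrices[reps] @ v.cartesian           # (n_sites, 3) Å
    offset = np.einsum("nij,sj->nsi", a_part, pos_map) / pixel_size  # px

    center = (src_box // 2) if src_box is not None else 0
    cx = center + offset[..., 0] - origin[:, None, 0]
    cy = center + offset[..., 1] - origin[:, None, 1]
    ix, ox = split_subpixel(cx)
    iy, oy = split_subpixel(cy)

    flat = lambda a: a.reshape(n * n_sites, *a.shape[2:])
    return {
        "parent": np.repeat(np.arange(n), n_sites),
        "site": np.tile(np.arange(n_sites), n),
        "orient": flat(oidx),
        "euler": flat(sub_euler),
        "coord": np.stack([flat(ix), flat(iy)], axis=-1),
        "origin": np.stack([flat(ox), flat(oy)], axis=-1),
        "offset": flat(offset),
        "z": flat(offset[..., 2]),
        "n_sites": n_sites,
        "cosets": cosets,
    }


def expand_symmetry(p: ParticleRecord, group: PointGroup, v: SubunitVector,
                    opts: FilterOptions = FilterOptions(),
                    src_box: int | None = None,
                    rng: np.random.Generator | None = None) -> list[SubParticleRecord]:
    """All sub-particles of one particle: one record per symmetry-distinct
    position of the subunit vector, with a seeded random representative among
    the degenerate orientations.

    ``src_box`` is the particle image box size; when given, extraction
    coordinates are absolute 0-based pixels in that image (center floor(N/2)),
    otherwise they are relative to the particle center.
    """
    rng = rng or np.random.default_rng(opts.seed)
    arr = _expand_arrays(np.asarray([p.euler], float), np.asarray([p.origin], float),
                         group, v, opts, p.pixel_size, src_box, rng)
    records = []
    for r in range(arr["n_sites"]):
        z = float(arr["z"][r])
        ctf = adjust_defocus(p.ctf, z, p.pixel_size) if p.ctf is not None else None
        records.append(SubParticleRecord(
            parent_id=0,
            site_index=int(arr["site"][r]),
            euler=EulerTriplet(*arr["euler"][r]),
            origin=tuple(arr["origin"][r]),
            extract_coord=tuple(int(x) for x in arr["coord"][r]),
            z_height=z,
            ctf=ctf,
            offset_px=tuple(arr["offset"][r]),
            orientation_index=int(arr["orient"][r]),
        ))
    return records


_SUB_COLS = {
    "rlnAngleRot": ("euler", 0), "rlnAngleTilt": ("euler", 1), "rlnAnglePsi": ("euler", 2),
    "rlnOriginX": ("origin", 0), "rlnOriginY": ("origin", 1),
    "rlnCoordinateX": ("coord", 0), "rlnCoordinateY": ("coord", 1),
}


def expand_star(df: pd.DataFrame, group: PointGroup, v: SubunitVector,
                opts: FilterOptions = FilterOptions(),
                pixel_size: float | None = None,
                src_box: int | None = None) -> pd.DataFrame:
    """Sub-particle STAR table from a particle STAR table (vectorized).

    Output columns: the derived pose and origin, integer extraction
    coordinates, height-adjusted defocus (when CTF columns are present) and
    the bookkeeping columns ``lrParentIndex``, ``lrSiteIndex``,
    ``lrOrientIndex``, ``lrZHeightPx``, ``lrOffsetX/Y/Z``.
    """
    from .io import pixel_size_from_star
    apix = pixel_size or pixel_size_from_star(df) or 1.0
    rng = np.random.default_rng(opts.seed)
    euler = df.reindex(columns=["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"],
                       fill_value=0.0).to_numpy(float)
    origin = df.reindex(columns=["rlnOriginX", "rlnOriginY"],
                        fill_value=0.0).to_numpy(float)
    arr = _expand_arrays(euler, origin, group, v, opts, apix, src_box, rng)

    out = pd.DataFrame({k: arr[src][..., i] if isinstance(i, int) else arr[src]
                        for k, (src, i) in _SUB_COLS.items()})
    out["lrParentIndex"] = arr["parent"]
    out["lrSiteIndex"] = arr["site"]
    out["lrOrientIndex"] = arr["orient"]
    out["lrZHeightPx"] = arr["z"]
    for i, ax in enumerate("XYZ"):
        out[f"lrOffset{ax}"] = arr["offset"][:, i]

    dz = -arr["z"] * apix
    for col in ("rlnDefocusU", "rlnDefocusV"):
        if col in df.columns:
            out[col] = df[col].to_numpy(float)[arr["parent"]] + dz
    for col in ("rlnDefocusAngle", "rlnVoltage", "rlnSphericalAberration",
                "rlnAmplitudeContrast", "rlnImageName", "rlnMagnification",
                "rlnDetectorPixelSize"):
        if col in df.columns:
            out[col] = df[col].to_numpy()[arr["parent"]]
    out.attrs["n_sites"] = arr["n_sites"]
    out.attrs["pixel_size"] = apix
    return out


def degenerate_eulers(particle_euler, group: PointGroup, v: SubunitVector,
                      site_index: int, tol_ang: float = 1.0) -> np.ndarray:
    """Euler triplets of all degenerate orientations of one site, in coset
    order (so ``lrOrientIndex`` indexes into this array)."""
    cosets = site_cosets(group, v, tol_ang)
    a = euler_to_matrix(np.asarray(particle_euler, float))
    m_vec = vector_to_matrix(v)
    mats = a @ group.matrices[cosets[site_index]] @ m_vec
    return matrix_to_euler(mats)


# ---------------------------------------------------------------------------
# filters


def _elevation_sin(df_or_records):
    """|u_z| of the unit subunit direction in the image frame, per record."""
    if isinstance(df_or_records, pd.DataFrame):
        off = df_or_records[["lrOffsetX", "lrOffsetY", "lrOffsetZ"]].to_numpy(float)
    else:
        off = np.asarray([r.offset_px for r in df_or_records], dtype=float)
    norm = np.linalg.norm(off, axis=1)
    return np.abs(off[:, 2]) / np.where(norm > 0, norm, 1.0)


def filter_side_views(records, side_max_angle: float | None = None,
                      exclude_top_views: bool = False):
    """Keep sub-particles seen from the side and/or drop those seen from the top.

    The side criterion keeps records whose rotated subunit vector lies within
    ``side_max_angle`` of the image plane (elevation |90° − angle to beam| ≤
    side_max_angle). Top-view exclusion removes records whose vector is within
    ``side_max_angle`` of the beam axis (either direction).
    """
    if side_max_angle is None:
        return records
    uz = _elevation_sin(records)
    keep = np.ones(len(uz), dtype=bool)
    keep &= uz <= math.sin(math.radians(side_max_angle)) + 1e-12
    if exclude_top_views:
        keep &= uz <= math.cos(math.radians(side_max_angle)) + 1e-12
    if isinstance(records, pd.DataFrame):
        return records[keep].reset_index(drop=True)
    return [r for r, k in zip(records, keep) if k]


def filter_overlaps(records, max_overlap: float | None, box_size: int,
                    remove_both: bool = True):
    """Drop sub-particles of the same particle whose boxes overlap too much.

    The overlap of a pair is ``box_size − center distance`` (px along the
    center line); a pair with overlap > ``max_overlap`` is removed. By default
    both members go (symmetric, order-independent); with
    ``remove_both=False`` records are kept greedily in input order and only
    the later conflicting member is dropped.
    """
    if max_overlap is None:
        return records
    is_df = isinstance(records, pd.DataFrame)
    if is_df:
        coords = records[["rlnCoordinateX", "rlnCoordinateY"]].to_numpy(float)
        parents = records["lrParentIndex"].to_numpy()
    else:
        coords = np.asarray([r.extract_coord for r in records], dtype=float)
        parents = np.asarray([r.parent_id for r in records])
    thresh = box_size - max_overlap
    keep = np.ones(len(coords), dtype=bool)
    for pid in np.unique(parents):
        idx = np.flatnonzero(parents == pid)
        d = np.linalg.norm(coords[idx, None, :] - coords[None, idx, :], axis=-1)
        close = d < thresh
        np.fill_diagonal(close, False)
        if remove_both:
            keep[idx[close.any(axis=1)]] = False
        else:
            kept: list[int] = []
            for j in range(len(idx)):
                if not any(close[j, k] for k in kept):
                    kept.append(j)
                else:
                    keep[idx[j]] = False
    if is_df:
        return records[keep].reset_index(drop=True)
    return [r for r, k in zip(records, keep) if k]


# ---------------------------------------------------------------------------
# extraction


def extract_subparticles(images: np.ndarray, records: pd.DataFrame, box_size: int,
                         normalize: bool = False,
                         image_index: np.ndarray | None = None):
    """Window the sub-particles out of their source images.

    ``images`` is a stack ``(n, H, W)``; each record's source image is
    ``lrParentIndex`` (or ``image_index`` when extraction coordinates refer to
    a different stack). Windows exceeding the image bounds are skipped and
    counted. Returns ``(substack, star_table, n_skipped)`` where the table is
    the surviving rows of ``records`` with ``rlnImageName`` renumbered.

    With ``normalize=True`` each window is shifted/scaled to zero mean and
    unit variance estimated over a background annulus (radius > 0.45 box).
    """
    if box_size % 2:
        raise ValueError("box_size must be even")
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    src = (records["lrParentIndex"].to_numpy() if image_index is None
           else np.asarray(image_index))
    cx = records["rlnCoordinateX"].to_numpy(int)
    cy = records["rlnCoordinateY"].to_numpy(int)
    h, w = images.shape[1:]
    half = box_size // 2
    yy, xx = np.mgrid[0:box_size, 0:box_size]
    annulus = np.hypot(yy - half, xx - half) > 0.45 * box_size

    boxes, kept_rows = [], []
    n_skipped = 0
    for i in range(len(records)):
        x0, y0 = cx[i] - half, cy[i] - half
        if x0 < 0 or y0 < 0 or x0 + box_size > w or y0 + box_size > h:
            n_skipped += 1
            continue
        win = images[src[i], y0:y0 + box_size, x0:x0 + box_size].astype(np.float32)
        if normalize:
            bg = win[annulus]
            sd = bg.std()
            win = (win - bg.mean()) / (sd if sd > 0 else 1.0)
        boxes.append(win)
        kept_rows.append(i)
    star = records.iloc[kept_rows].reset_index(drop=True)
    star["rlnImageName"] = [f"{j + 1}@subparticles.mrcs" for j in range(len(kept_rows))]
    stack = np.stack(boxes) if boxes else np.empty((0, box_size, box_size), np.float32)
    return stack, star, n_skipped


def occupancy_summary(class_counts, occupied_flags, sites_per_particle: int):
    """Site occupancy and copies per particle from classification counts.

    ``class_counts[i]`` sub-particles fell in class i; ``occupied_flags[i]``
    marks classes showing the subunit. Classes the caller wants excluded (e.g.
    junk classes) are simply omitted. Returns ``(percent, copies)`` where
    percent is the occupied fraction truncated to an integer percent and
    copies = round(percent/100 × sites_per_particle).
    """
    counts = np.asarray(class_counts, dtype=float)
    flags = np.asarray(occupied_flags, dtype=bool)
    if counts.shape != flags.shape:
        raise ValueError("class_counts and occupied_flags must have the same length")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("occupancy undefined: all class counts are zero")
    percent = int(math.floor(100.0 * counts[flags].sum() / total))
    copies = int(round(percent / 100.0 * sites_per_particle))
    return percent, copies
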