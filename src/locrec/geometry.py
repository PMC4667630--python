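"""Rotation algebra for sub-particle pose calculation.

Conventions (pinned once, used everywhere in the package):

* Euler angles (rot, tilt, psi) follow the Relion/XMIPP ZYZ convention.
  The orientation matrix is ``A = Rz(psi) @ Ry(tilt) @ Rz(rot)`` built from
  *passive* (coordinate-frame) elemental rotations; ``A`` maps a point given
  in the reference (map) frame to the particle image frame, so the image-plane
  location of a map point ``p`` is the first two components of ``A @ p``.
* Point-group matrices are *active* rotations acting on map coordinates.
  The icosahedral setting is I2 (two-fold axes on x, y, z — the Relion
  default); the octahedral group has its four-fold axes on x, y, z.
* A subunit vector points from the map center to the subunit center. Its
  rotation matrix is the minimal rotation carrying the reference direction
  [0, 0, 1] onto the vector.

The composition implemented by :func:`subparticle_pose` is

    M_sub = A_particle @ G_sym @ M_vec

with the subunit-center offset ``A_particle @ G_sym @ (length * direction)``:
components 1–2 are the in-plane displacement and component 3 the height of
the subunit above the image plane (along the beam).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

__all__ = [
    "EulerTriplet",
    "SubunitVector",
    "PointGroup",
    "InvalidRotationError",
    "UnsupportedSymmetryError",
    "euler_to_matrix",
    "matrix_to_euler",
    "point_group",
    "vector_to_matrix",
    "subparticle_pose",
]


class InvalidRotationError(ValueError):
    """Raised when a matrix is not a proper rotation."""


class UnsupportedSymmetryError(ValueError):
    """Raised for point-group labels outside Cn, Dn, T, O, I."""


class EulerTriplet(NamedTuple):
    """Relion-convention Euler angles in degrees (rot, tilt, psi)."""

    rot: float
    tilt: float
    psi: float


@dataclass(frozen=True)
class SubunitVector:
    """Direction (unit 3-vector) and length (Å) from complex center to subunit center."""

    direction: np.ndarray
    length: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("subunit vector has zero length")
        object.__setattr__(self, "direction", d / n)
        if not self.length > 0:
            raise ValueError(f"subunit vector length must be > 0, got {self.length}")

    @classmethod
    def from_cartesian(cls, xyz) -> "SubunitVector":
        xyz = np.asarray(xyz, dtype=float)
        return cls(direction=xyz, length=float(np.linalg.norm(xyz)))

    @property
    def cartesian(self) -> np.ndarray:
        """The vector in Å."""
        return self.length * self.direction


@dataclass(frozen=True)
class PointGroup:
    """A finite rotation group: its label and the full set of rotation matrices."""

    label: str
    matrices: np.ndarray  # (order, 3, 3)

    def __len__(self) -> int:
        return len(self.matrices)

    def orbit(self, xyz, tol: float = 1e-6) -> np.ndarray:
        """Distinct positions of a point under the group, merged within `tol`."""
        pts = self.matrices @ np.asarray(xyz, dtype=float)
        keep: list[np.ndarray] = []
        for p in pts:
            if not any(np.linalg.norm(p - q) <= tol for q in keep):
                keep.append(p)
        return np.asarray(keep)


def _wrap180(a: np.ndarray) -> np.ndarray:
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def euler_to_matrix(euler) -> np.ndarray:
    """Rotation matrix from Relion-convention Euler angles (degrees).

    Accepts an :class:`EulerTriplet` or any array-like of shape ``(..., 3)``;
    returns matrices of shape ``(..., 3, 3)``.
    """
    a = np.deg2rad(np.asarray(euler, dtype=float))
    rot, tilt, psi = a[..., 0], a[..., 1], a[..., 2]
    ca, sa = np.cos(rot), np.sin(rot)
    cb, sb = np.cos(tilt), np.sin(tilt)
    cg, sg = np.cos(psi), np.sin(psi)
    m = np.empty(a.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = cg * cb * ca - sg * sa
    m[..., 0, 1] = cg * cb * sa + sg * ca
    m[..., 0, 2] = -cg * sb
    m[..., 1, 0] = -sg * cb * ca - cg * sa
    m[..., 1, 1] = -sg * cb * sa + cg * ca
    m[..., 1, 2] = sg * sb
    m[..., 2, 0] = sb * ca
    m[..., 2, 1] = sb * sa
    m[..., 2, 2] = cb
    return m


def check_rotation(m: np.ndarray, atol: float = 1e-8) -> None:
    """Raise :class:`InvalidRotationError` unless `m` is a proper rotation."""
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise InvalidRotationError(f"expected (..., 3, 3) matrix, got shape {m.shape}")
    eye = np.broadcast_to(np.eye(3), m.shape)
    if not np.allclose(np.swapaxes(m, -1, -2) @ m, eye, atol=atol):
        raise InvalidRotationError("matrix is not orthonormal")
    if not np.allclose(np.linalg.det(m), 1.0, atol=atol):
        raise InvalidRotationError("matrix determinant is not +1 (improper rotation)")


def matrix_to_euler(m, gimbal_tol: float = 1e-8):
    """Relion-convention Euler angles (degrees) from rotation matrices.

    Inverse of :func:`euler_to_matrix` in the sense that the matrix
    round-trips exactly; the angle triplet itself is only unique away from
    gimbal lock. At tilt = 0 or 180 the convention is rot = 0 with the whole
    in-plane rotation carried by psi.

    A single (3, 3) input returns an :class:`EulerTriplet`; batched input of
    shape ``(..., 3, 3)`` returns an array of shape ``(..., 3)``.
    """
    m = np.asarray(m, dtype=float)
    check_rotation(m, atol=1e-6)
    single = m.ndim == 2
    mb = m.reshape(-1, 3, 3)

    cb = np.clip(mb[:, 2, 2], -1.0, 1.0)
    tilt = np.degrees(np.arccos(cb))
    sb = np.sqrt(np.maximum(0.0, 1.0 - cb * cb))

    rot = np.degrees(np.arctan2(mb[:, 2, 1], mb[:, 2, 0]))
    psi = np.degrees(np.arctan2(mb[:, 1, 2], -mb[:, 0, 2]))

    lock = sb < gimbal_tol
    if np.any(lock):
        top = cb[lock] > 0
        # tilt = 0: A = Rz(rot + psi); tilt = 180: A = Rz(psi - rot) @ Ry(180)
        psi_lock = np.where(
            top,
            np.degrees(np.arctan2(mb[lock, 0, 1], mb[lock, 0, 0])),
            np.degrees(np.arctan2(mb[lock, 0, 1], -mb[lock, 0, 0])),
        )
        rot[lock] = 0.0
        psi[lock] = psi_lock
        tilt[lock] = np.where(top, 0.0, 180.0)

    out = np.stack([_wrap180(rot), tilt, _wrap180(psi)], axis=-1)
    out = out.reshape(m.shape[:-2] + (3,))
    if single:
        return EulerTriplet(*out)
    return out


_CN_RE = re.compile(r"^([CD])(\d+)$")


def point_group(label: str) -> PointGroup:
    """The full rotation group for a point-group label (Cn, Dn, T, O, I).

    Settings: icosahedral I2 (two-folds on x, y, z), octahedral with
    four-folds on x, y, z, Dn with the dihedral two-fold on x.
    """
    lab = str(label).strip().upper()
    mats = None
    if lab in ("T", "O", "I"):
        mats = _Rotation.create_group(lab).as_matrix()
    else:
        m = _CN_RE.match(lab)
        if m:
            n = int(m.group(2))
            if n < 1 or (m.group(1) == "D" and n < 2):
                raise UnsupportedSymmetryError(f"invalid point-group order in {label!r}")
            mats = _Rotation.create_group(f"{m.group(1)}{n}").as_matrix()
    if mats is None:
        raise UnsupportedSymmetryError(
            f"unsupported symmetry {label!r}; expected Cn, Dn, T, O or I"
        )
    # canonical order: identity first
    idx = np.argsort([np.linalg.norm(g - np.eye(3)) for g in mats], kind="stable")
    return PointGroup(label=lab, matrices=np.ascontiguousarray(mats[idx]))


_Z = np.array([0.0, 0.0, 1.0])


def vector_to_matrix(v) -> np.ndarray:
    """Minimal (geodesic) rotation carrying the reference direction [0,0,1]
    onto the subunit direction, as an active matrix: ``M @ [0,0,1] = d``.

    The free azimuth is fixed by rotating about ``[0,0,1] × d``. For the
    anti-parallel direction the rotation is 180° about x (a stable,
    documented convention).
    """
    d = v.direction if isinstance(v, SubunitVector) else np.asarray(v, dtype=float)
    d = d / np.linalg.norm(d)
    c = float(d @ _Z)
    if c >= 1.0 - 1e-14:
        return np.eye(3)
    if c <= -1.0 + 1e-14:
        return np.diag([1.0, -1.0, -1.0])  # 180° about x
    axis = np.cross(_Z, d)
    axis /= np.linalg.norm(axis)
    return _Rotation.from_rotvec(axis * np.arccos(c)).as_matrix()


def subparticle_pose(particle_matrix: np.ndarray, sym_matrix: np.ndarray,
                     v: SubunitVector) -> tuple[np.ndarray, np.ndarray]:
    """Sub-particle orientation matrix and subunit-center offset.

    Returns ``(M_sub, offset)`` with ``M_sub = A_particle @ G_sym @ M_vec``
    and ``offset = A_particle @ G_sym @ (length * direction)`` in Å in the
    particle's image frame: offset[0:2] is the in-plane displacement of the
    subunit center from the particle center, offset[2] its height above the
    image plane along the beam.
    """
    pg = np.asarray(particle_matrix, dtype=float) @ np.asarray(sym_matrix, dtype=float)
    m_sub = pg @ vector_to_matrix(v)
    offset = pg @ v.cartesian
    return m_sub, offset
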