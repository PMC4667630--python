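"""File formats and metadata containers: STAR tables, CMM markers, MRC maps.

STAR tables are held as pandas DataFrames whose columns are the Relion labels
without the leading ``_`` (e.g. ``rlnAngleRot``). The writer emits the legacy
Relion 1.x dialect (a single ``data_`` block with one ``loop_``); the reader
also tolerates Relion ≥ 3.1 files with a ``data_optics`` block, merging optics
values onto the particle rows.

Coordinate conventions: particle image pixel coordinates are 0-based with the
image center at ``floor(N/2)``. The origin (``rlnOriginX/Y``) is the shift in
pixels that, applied to the image, centers the reference projection.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import EulerTriplet, SubunitVector

__all__ = [
    "CtfParams",
    "ParticleRecord",
    "DensityMap",
    "MaskMap",
    "StarParseError",
    "read_star",
    "read_star_blocks",
    "write_star",
    "particles_from_star",
    "read_cmm",
    "read_mrc",
    "write_mrc",
]


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class CtfParams:
    """Contrast-transfer-function parameters of one particle image.

    Positive defocus denotes underfocus. ``defocus_u``/``defocus_v`` in Å
    along the astigmatism major/minor axes, ``astig_angle`` in degrees,
    ``voltage`` in kV, spherical aberration ``cs`` in mm and the amplitude
    contrast as a fraction in [0, 1].
    """

    defocus_u: float
    defocus_v: float
    astig_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")
        if self.voltage <= 0:
            raise ValueError("voltage must be positive (kV)")

    def shifted(self, ddefocus: float) -> "CtfParams":
        """A copy with both defocus values shifted by ``ddefocus`` (Å)."""
        return replace(self, defocus_u=self.defocus_u + ddefocus,
                       defocus_v=self.defocus_v + ddefocus)


@dataclass(frozen=True)
class ParticleRecord:
    """One whole-complex particle: pose, origin, CTF and image reference."""

    euler: EulerTriplet
    origin: tuple[float, float] = (0.0, 0.0)  # px
    ctf: CtfParams | None = None
    pixel_size: float = 1.0  # Å/px
    image_index: int = 0
    image_path: str = ""
    micrograph_coord: tuple[float, float] = (0.0, 0.0)  # px

    def __post_init__(self):
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")


# ---------------------------------------------------------------------------
# STAR


class StarParseError(ValueError):
    pass


def _block_to_frame(block: "gemmi.cif.Block") -> pd.DataFrame:
    loop = None
    for item in block:
        if item.loop is not None:
            loop = item.loop
            break
    if loop is None:
        # key-value only block
        data = {}
        for item in block:
            if item.pair is not None:
                k, v = item.pair
                data[k.lstrip("_")] = [_coerce(v)]
        return pd.DataFrame(data)
    tags = [t.lstrip("_") for t in loop.tags]
    ncol = len(tags)
    vals = list(loop.values)
    rows = [vals[i:i + ncol] for i in range(0, len(vals), ncol)]
    df = pd.DataFrame(rows, columns=tags)
    for c in df.columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        if not converted.isna().any():
            df[c] = converted
    # attach any free key-value pairs alongside the loop
    for item in block:
        if item.pair is not None:
            k, v = item.pair
            df.attrs[k.lstrip("_")] = _coerce(v)
    return df


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except (TypeError, ValueError):
            continue
    return v


def read_star_blocks(path) -> dict[str, pd.DataFrame]:
    """All data blocks of a STAR file as ``{block_name: DataFrame}``."""
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as err:  # gemmi reports line numbers
        raise StarParseError(f"malformed STAR file {path}: {err}") from err
    return {b.name: _block_to_frame(b) for b in doc}


def read_star(path, block: str | None = None) -> pd.DataFrame:
    """The main data table of a STAR file as a DataFrame.

    If the file carries a Relion ≥ 3.1 ``optics`` block its per-group values
    are merged onto the particle rows so downstream code sees flat legacy-style
    columns.
    """
    blocks = read_star_blocks(path)
    if not blocks:
        raise StarParseError(f"no data blocks in {path}")
    if block is not None:
        return blocks[block]
    names = list(blocks)
    optics = next((n for n in names if n.lower() == "optics"), None)
    main = next((n for n in names if n.lower() != "optics"), names[0])
    df = blocks[main]
    if optics is not None and "rlnOpticsGroup" in df.columns:
        op = blocks[optics]
        df = df.merge(op, on="rlnOpticsGroup", how="left", suffixes=("", "_optics"))
    df.attrs["block_name"] = main
    return df


def write_star(df: pd.DataFrame, path, block_name: str = "") -> None:
    """Write a DataFrame as a legacy single-block Relion STAR file."""
    path = Path(path)
    lines = [f"data_{block_name}", "", "loop_"]
    for i, c in enumerate(df.columns, start=1):
        lines.append(f"_{c} #{i}")
    fdf = df.copy()
    for c in fdf.columns:
        if pd.api.types.is_float_dtype(fdf[c]):
            fdf[c] = fdf[c].map(lambda x: f"{x:.6f}")
        fdf[c] = fdf[c].astype(str)
    widths = {c: max(len(c), int(fdf[c].str.len().max()) if len(fdf) else 0)
              for c in fdf.columns}
    for _, row in fdf.iterrows():
        lines.append(" ".join(str(row[c]).rjust(widths[c]) for c in fdf.columns))
    lines.append("")
    path.write_text("\n".join(lines))


_EULER_COLS = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")


def pixel_size_from_star(df: pd.DataFrame) -> float | None:
    """Å/px from whichever convention the table carries."""
    if "rlnPixelSize" in df:
        return float(df["rlnPixelSize"].iloc[0])
    if "rlnImagePixelSize" in df:
        return float(df["rlnImagePixelSize"].iloc[0])
    if "rlnDetectorPixelSize" in df and "rlnMagnification" in df:
        return float(df["rlnDetectorPixelSize"].iloc[0] * 1e4 / df["rlnMagnification"].iloc[0])
    return None


def particles_from_star(df: pd.DataFrame, pixel_size: float | None = None) -> list[ParticleRecord]:
    """Typed particle records from a STAR particle table."""
    apix = pixel_size or pixel_size_from_star(df) or 1.0
    out = []
    for i, row in df.iterrows():
        euler = EulerTriplet(*(float(row.get(c, 0.0)) for c in _EULER_COLS))
        ctf = None
        if "rlnDefocusU" in df.columns:
            ctf = CtfParams(
                defocus_u=float(row["rlnDefocusU"]),
                defocus_v=float(row.get("rlnDefocusV", row["rlnDefocusU"])),
                astig_angle=float(row.get("rlnDefocusAngle", 0.0)),
                voltage=float(row.get("rlnVoltage", 300.0)),
                cs=float(row.get("rlnSphericalAberration", 2.7)),
                amplitude_contrast=float(row.get("rlnAmplitudeContrast", 0.1)),
            )
        idx, pth = _parse_image_name(row.get("rlnImageName", f"{i + 1}@"))
        out.append(ParticleRecord(
            euler=euler,
            origin=(float(row.get("rlnOriginX", 0.0)), float(row.get("rlnOriginY", 0.0))),
            ctf=ctf,
            pixel_size=apix,
            image_index=idx,
            image_path=pth,
            micrograph_coord=(float(row.get("rlnCoordinateX", 0.0)),
                              float(row.get("rlnCoordinateY", 0.0))),
        ))
    return out


def _parse_image_name(name) -> tuple[int, str]:
    s = str(name)
    if "@" in s:
        idx, pth = s.split("@", 1)
        return int(idx) - 1, pth  # STAR image indices are 1-based
    return 0, s


# ---------------------------------------------------------------------------
# CMM markers


def read_cmm(path, map_size_px: int, pixel_size: float,
             center: tuple[float, float, float] | None = None) -> SubunitVector:
    """Subunit vector from a Chimera marker (CMM) file.

    The single marker's coordinates are interpreted in Å in the map frame
    with origin at voxel (0,0,0); the vector runs from the map center
    (``pixel_size * floor(N/2)`` per axis, overridable via ``center``) to the
    marker. The marker radius field is ignored.
    """
    tree = ET.parse(str(path))
    markers = tree.getroot().findall(".//marker")
    if len(markers) != 1:
        raise ValueError(f"expected exactly 1 marker in {path}, found {len(markers)}")
    m = markers[0]
    xyz = np.array([float(m.get(k)) for k in ("x", "y", "z")])
    if not np.all(np.isfinite(xyz)):
        raise ValueError(f"non-finite marker coordinates in {path}")
    if center is None:
        center = np.full(3, pixel_size * (map_size_px // 2), dtype=float)
    vec = xyz - np.asarray(center, dtype=float)
    if np.linalg.norm(vec) == 0:
        raise ValueError("marker coincides with the map center (zero-length vector)")
    return SubunitVector.from_cartesian(vec)


# ---------------------------------------------------------------------------
# MRC maps / stacks


@dataclass
class DensityMap:
    """A 3D voxel grid (or 2D image stack) with its pixel size.

    ``data`` is indexed ``[z, y, x]`` (section, row, column — the MRC axis
    order); the map center voxel is ``floor(N/2)`` on each axis. For stacks
    (``is_stack=True``) the first axis indexes images.
    """

    data: np.ndarray
    apix: float = 1.0
    is_stack: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("DensityMap data must be 3D")
        if not self.apix > 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self):
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "DensityMap":
        return DensityMap(data=data, apix=self.apix, is_stack=self.is_stack)


class MaskMap(DensityMap):
    """A density-shaped grid of weights in [0, 1]."""

    def __post_init__(self):
        super().__post_init__()
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"mask values must lie in [0, 1], got [{lo}, {hi}]")
        np.clip(self.data, 0.0, 1.0, out=self.data)


_HDR = np.dtype([
    ("nx", "i4"), ("ny", "i4"), ("nz", "i4"), ("mode", "i4"),
    ("nxstart", "i4"), ("nystart", "i4"), ("nzstart", "i4"),
    ("mx", "i4"), ("my", "i4"), ("mz", "i4"),
    ("cella", "f4", 3), ("cellb", "f4", 3),
    ("mapc", "i4"), ("mapr", "i4"), ("maps", "i4"),
    ("dmin", "f4"), ("dmax", "f4"), ("dmean", "f4"),
    ("ispg", "i4"), ("nsymbt", "i4"),
    ("extra1", "V8"), ("exttyp", "S4"), ("nversion", "i4"),
    ("extra2", "V84"),
    ("origin", "f4", 3),
    ("map", "S4"), ("machst", "V4"), ("rms", "f4"), ("nlabl", "i4"),
    ("label", "S800"),
])
assert _HDR.itemsize == 1024


def read_mrc(path) -> DensityMap:
    """Read an MRC2014 mode-2 (32-bit float) map or image stack."""
    with open(path, "rb") as fh:
        raw = fh.read(1024)
        if len(raw) < 1024:
            raise ValueError(f"{path} is not an MRC file (truncated header)")
        hdr = np.frombuffer(raw, dtype=_HDR)[0]
        if hdr["mode"] != 2:
            raise ValueError(f"unsupported MRC mode {int(hdr['mode'])}; only mode 2 supported")
        if hdr["nsymbt"]:
            fh.seek(int(hdr["nsymbt"]), 1)
        nx, ny, nz = int(hdr["nx"]), int(hdr["ny"]), int(hdr["nz"])
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4").reshape(nz, ny, nx)
    mx = int(hdr["mx"]) or nx
    apix = float(hdr["cella"][0]) / mx if hdr["cella"][0] > 0 else 1.0
    is_stack = int(hdr["ispg"]) == 0 and nz > 1
    return DensityMap(data=data.copy(), apix=apix, is_stack=is_stack)


def write_mrc(obj: DensityMap | np.ndarray, path, apix: float | None = None,
              is_stack: bool | None = None) -> None:
    """Write a map or image stack as MRC2014 mode 2."""
    if isinstance(obj, DensityMap):
        data, apix = obj.data, apix or obj.apix
        is_stack = obj.is_stack if is_stack is None else is_stack
    else:
        data = np.asarray(obj, dtype=np.float32)
        if data.ndim == 2:
            data = data[None]
        apix = apix or 1.0
        is_stack = bool(is_stack)
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    hdr = np.zeros(1, dtype=_HDR)[0]
    hdr["nx"], hdr["ny"], hdr["nz"] = nx, ny, nz
    hdr["mode"] = 2
    hdr["mx"], hdr["my"] = nx, ny
    hdr["mz"] = 1 if is_stack else nz
    hdr["cella"] = (nx * apix, ny * apix, (1 if is_stack else nz) * apix)
    hdr["cellb"] = (90.0, 90.0, 90.0)
    hdr["mapc"], hdr["mapr"], hdr["maps"] = 1, 2, 3
    hdr["dmin"], hdr["dmax"], hdr["dmean"] = data.min(), data.max(), data.mean()
    hdr["rms"] = data.std()
    hdr["ispg"] = 0 if is_stack else 1
    hdr["nversion"] = 20140
    hdr["map"] = b"MAP "
    hdr["machst"] = np.frombuffer(bytes([0x44, 0x44, 0, 0]), dtype="V4")[0]
    with open(path, "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(data.tobytes())
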