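"""Micrograph containers and file I/O.

Images are exchanged in the MRC2014 format: a fixed 1024-byte header followed
by the pixel data. Only single 2-D images are handled here (mode 2 float32 on
write; integer modes 0/1/6 and mode 2 promoted to float on read). Axis
convention throughout the package: arrays are row-major with the first axis
slow (y) and the second fast (x).

CTF parameters arrive as a plain TSV table or a STAR data block using the
conventional ``rlnDefocusU``/``rlnDefocusV``/``rlnDefocusAngle`` tags.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ctf import CtfParams

logger = logging.getLogger("cryodenoise")

__all__ = [
    "Micrograph",
    "HalfPair",
    "CtfRecord",
    "MrcFormatError",
    "read_micrograph",
    "write_micrograph",
    "read_ctf_table",
    "write_ctf_table",
]


class MrcFormatError(ValueError):
    """Raised when a file is not a readable 2-D MRC2014 image."""


@dataclass
class Micrograph:
    """A single 2-D cryo-EM image.

    Parameters
    ----------
    pixels : ndarray
        2-D float array, first axis slow (y), second fast (x).
    pixel_size : float
        Physical pixel size in Å per pixel (isotropic).
    name : str
        Identifier used to match CTF records and output files.
    """

    pixels: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"micrograph must be 2-D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 32:
            raise ValueError(f"micrograph dimensions must be >= 32, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite pixel values")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, pixel_size: float | None = None) -> "Micrograph":
        return Micrograph(pixels, self.pixel_size if pixel_size is None else pixel_size, self.name)


@dataclass
class HalfPair:
    """Even/odd frame-sum micrographs sharing one signal.

    The two halves are assumed to carry the same underlying signal with noise
    that is statistically uncorrelated given that signal — the property the
    noise2noise objective and all cross-correlation estimators rely on.
    """

    even: Micrograph
    odd: Micrograph

    def __post_init__(self) -> None:
        if self.even.shape != self.odd.shape:
            raise ValueError(f"half shapes differ: {self.even.shape} vs {self.odd.shape}")
        if not math.isclose(self.even.pixel_size, self.odd.pixel_size, rel_tol=1e-6):
            raise ValueError("half pixel sizes differ")

    @property
    def pixel_size(self) -> float:
        return self.even.pixel_size

    @property
    def name(self) -> str:
        return self.even.name or self.odd.name


@dataclass
class CtfRecord:
    micrograph_name: str
    params: CtfParams


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_HEADER_SIZE = 1024
_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}


def read_micrograph(path: str | Path) -> Micrograph:
    """Read a single 2-D image from an MRC2014 file.

    Modes 0, 1 and 6 are promoted to float32; mode 2 is read as is. The pixel
    size is taken from the header cell dimensions divided by the grid size.
    3-D volumes and stacks are rejected.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_SIZE)
        if len(header) < _MRC_HEADER_SIZE:
            raise MrcFormatError(f"{path}: truncated header ({len(header)} bytes)")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        cella = struct.unpack("<3f", header[40:52])
        mapid = header[208:212]
        if mapid not in (b"MAP ", b"MAP\x00"):
            raise MrcFormatError(f"{path}: missing MAP identifier in header")
        if mode not in _MODE_DTYPES:
            raise MrcFormatError(f"{path}: unsupported MRC mode {mode}")
        if nz != 1:
            raise MrcFormatError(
                f"{path}: expected a single 2-D image, got nz={nz} (volumes/stacks unsupported)"
            )
        if nx <= 0 or ny <= 0:
            raise MrcFormatError(f"{path}: invalid dimensions nx={nx} ny={ny}")
        (nsymbt,) = struct.unpack("<i", header[92:96])
        if nsymbt < 0:
            raise MrcFormatError(f"{path}: negative extended header size")
        fh.seek(_MRC_HEADER_SIZE + nsymbt)
        dtype = _MODE_DTYPES[mode].newbyteorder("<")
        count = nx * ny
        data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype)
        if data.size != count:
            raise MrcFormatError(f"{path}: truncated data section")
    pixels = data.reshape(ny, nx)  # MRC rows are the slow axis for nz=1
    if mode != 2:
        pixels = pixels.astype(np.float32)
    else:
        pixels = pixels.copy()
    if cella[0] > 0 and nx > 0:
        pixel_size = cella[0] / nx
        py = cella[1] / ny if cella[1] > 0 else pixel_size
        if not math.isclose(pixel_size, py, rel_tol=1e-4):
            raise MrcFormatError(
                f"{path}: anisotropic pixel size in header ({pixel_size:.4g} vs {py:.4g})"
            )
    else:
        logger.warning("%s: header has no cell dimensions; assuming 1.0 A/px", path)
        pixel_size = 1.0
    return Micrograph(pixels, float(pixel_size), name=path.stem)


def write_micrograph(m: Micrograph, path: str | Path) -> None:
    """Write a micrograph as an MRC2014 mode-2 (float32) file.

    The header cell dimensions encode ``pixel_size`` and the min/max/mean
    statistics fields are populated from the data.
    """
    path = Path(path)
    data = np.ascontiguousarray(m.pixels, dtype="<f4")
    ny, nx = data.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)  # nx ny nz mode
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart...
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx my mz
    struct.pack_into(
        "<3f", header, 40, nx * m.pixel_size, ny * m.pixel_size, m.pixel_size
    )  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc mapr maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0)  # ispg: 0 = 2-D image
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# CTF tables
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "name",
    "defocus_u",
    "defocus_v",
    "astig_angle",
    "voltage",
    "cs",
    "amplitude_contrast",
    "phase_shift",
]

_STAR_TAGS = {
    "rlnMicrographName": "name",
    "rlnImageName": "name",
    "rlnDefocusU": "defocus_u",
    "rlnDefocusV": "defocus_v",
    "rlnDefocusAngle": "astig_angle",
    "rlnVoltage": "voltage",
    "rlnSphericalAberration": "cs",
    "rlnAmplitudeContrast": "amplitude_contrast",
    "rlnPhaseShift": "phase_shift",
}


def _record_from_row(row: dict[str, str], rownum: int) -> CtfRecord:
    vals: dict[str, float] = {}
    for col in _TSV_COLUMNS[1:]:
        raw = row[col]
        try:
            vals[col] = float(raw)
        except ValueError as exc:
            raise ValueError(f"row {rownum}: non-numeric value {raw!r} in column {col!r}") from exc
    params = CtfParams(
        defocus_u=vals["defocus_u"],
        defocus_v=vals["defocus_v"],
        astig_angle=math.radians(vals["astig_angle"]),
        voltage=vals["voltage"],
        cs=vals["cs"],
        amplitude_contrast=vals["amplitude_contrast"],
        phase_shift=math.radians(vals["phase_shift"]),
    )
    return CtfRecord(micrograph_name=row["name"], params=params)


def _parse_star(lines: list[str]) -> list[CtfRecord]:
    # minimal STAR loop_ parser: one data block, whitespace-delimited rows
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for line in lines:
        s = line.strip()
        if not s or s.startswith("#") or s.startswith("data_"):
            continue
        if s == "loop_":
            in_loop = True
            tags = []
            rows = []
            continue
        if s.startswith("_"):
            if not in_loop:
                continue  # key-value pairs outside loops are ignored
            tags.append(s.split()[0].lstrip("_").split("#")[0].strip())
            continue
        if in_loop and tags:
            rows.append(s.split())
    colmap = {i: _STAR_TAGS[t] for i, t in enumerate(tags) if t in _STAR_TAGS}
    needed = set(_TSV_COLUMNS)
    have = set(colmap.values())
    missing = needed - have
    if missing:
        raise ValueError(f"STAR table missing required tag(s) for: {sorted(missing)}")
    records = []
    for i, row in enumerate(rows, start=1):
        if len(row) < len(tags):
            raise ValueError(f"row {i}: expected {len(tags)} fields, got {len(row)}")
        d = {colmap[j]: row[j] for j in colmap}
        records.append(_record_from_row(d, i))
    return records


def read_ctf_table(path: str | Path) -> list[CtfRecord]:
    """Read per-micrograph CTF parameters from a TSV or STAR file.

    The TSV schema is ``name defocus_u defocus_v astig_angle voltage cs
    amplitude_contrast phase_shift`` with defocus in Å, angles in degrees,
    voltage in kV and Cs in mm. Angles are converted to radians internally.
    A STAR block with the conventional rln* tags is accepted equivalently.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    is_star = any(
        ln.strip() == "loop_" or ln.strip().startswith("data_") for ln in lines
    )
    if is_star:
        records = _parse_star(lines)
    else:
        rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
        if not rows:
            logger.warning("%s: empty CTF table", path)
            return []
        header = rows[0].split("\t") if "\t" in rows[0] else rows[0].split()
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"CTF table missing required column(s): {missing}")
        idx = {c: header.index(c) for c in _TSV_COLUMNS}
        records = []
        for i, ln in enumerate(rows[1:], start=1):
            fields = ln.split("\t") if "\t" in ln else ln.split()
            if len(fields) < len(header):
                raise ValueError(f"row {i}: expected {len(header)} fields, got {len(fields)}")
            d = {c: fields[idx[c]] for c in _TSV_COLUMNS}
            records.append(_record_from_row(d, i))
    if not records:
        logger.warning("%s: empty CTF table", path)
        return records
    names = [r.micrograph_name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate micrograph name(s) in CTF table: {sorted(dupes)}")
    return records


def write_ctf_table(records: Sequence[CtfRecord], path: str | Path) -> None:
    """Write CTF records as a TSV table (inverse of :func:`read_ctf_table`)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in records:
        p = r.params
        lines.append(
            "\t".join(
                [
                    r.micrograph_name,
                    f"{p.defocus_u:.6g}",
                    f"{p.defocus_v:.6g}",
                    f"{math.degrees(p.astig_angle):.6g}",
                    f"{p.voltage:.6g}",
                    f"{p.cs:.6g}",
                    f"{p.amplitude_contrast:.6g}",
                    f"{math.degrees(p.phase_shift):.6g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
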