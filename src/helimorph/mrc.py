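"""Minimal MRC2014 reader/writer for float32 volumes and image stacks.

Only mode 2 (32-bit IEEE float, little endian) is supported, which is what
this package produces and consumes.  Volumes are written with spacegroup
ISPG=1 and image stacks with ISPG=0; the voxel/pixel size is stored in the
cell dimensions.  Write/read round trips are bit-identical for float data.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_SIZE = 1024
_MAP_MAGIC = b"MAP "
_MACHST_LE = b"\x44\x44\x00\x00"


def write_mrc(data: np.ndarray, path, apix: float, is_stack: bool | None = None) -> None:
    """Write a 2D image, 3D volume, or image stack as an MRC2014 file.

    ``data`` is interpreted with the slowest axis first: a 3D array is a
    volume (z, y, x) unless ``is_stack`` is true, in which case it is a
    stack of 2D images (n, y, x).  2D arrays are written as single-section
    files.
    """
    arr = np.asarray(data, dtype="<f4")
    if arr.ndim == 2:
        arr = arr[None]
        if is_stack is None:
            is_stack = True
    elif arr.ndim == 3:
        if is_stack is None:
            is_stack = False
    else:
        raise ValueError("data must be 2D or 3D")
    if apix <= 0:
        raise ValueError("apix must be positive")
    nz, ny, nx = arr.shape
    mz = 1 if is_stack else nz
    ispg = 0 if is_stack else 1
    dmin, dmax = float(arr.min()), float(arr.max())
    dmean = float(arr.mean())
    rms = float(arr.std())
    header = struct.pack(
        "<10i6f3i3f2i",
        nx, ny, nz,            # NX NY NZ
        2,                     # MODE 2: float32
        0, 0, 0,               # NXSTART NYSTART NZSTART
        nx, ny, mz,            # MX MY MZ
        nx * apix, ny * apix, mz * apix,  # CELLA
        90.0, 90.0, 90.0,      # CELLB
        1, 2, 3,               # MAPC MAPR MAPS
        dmin, dmax, dmean,     # DMIN DMAX DMEAN
        ispg,                  # ISPG
        0,                     # NSYMBT
    )
    header += b"\x00" * (196 - len(header))         # EXTRA (words 25-49)
    header += struct.pack("<3f", 0.0, 0.0, 0.0)     # ORIGIN (words 50-52)
    header += _MAP_MAGIC                            # MAP
    header += _MACHST_LE                            # MACHST
    header += struct.pack("<f", rms)                # RMS
    header += struct.pack("<i", 0)                  # NLABL
    header += b"\x00" * (_HEADER_SIZE - len(header))
    assert len(header) == _HEADER_SIZE
    with open(str(path), "wb") as fh:
        fh.write(header)
        fh.write(arr.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float, bool]:
    """Read an MRC2014 file; returns (data, apix, is_stack).

    ``data`` has shape (nz, ny, nx) in float32.  ``is_stack`` reflects the
    ISPG field (0 = image stack, 1 = volume).
    """
    with open(str(path), "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError("truncated MRC header")
        if header[208:212] != _MAP_MAGIC:
            raise ValueError("not an MRC2014 file (missing MAP magic)")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        if mode != 2:
            raise ValueError(f"unsupported MRC mode {mode} (only mode 2 float32)")
        mx, my, mz = struct.unpack("<3i", header[28:40])
        cella = struct.unpack("<3f", header[40:52])
        ispg = struct.unpack("<i", header[88:92])[0]
        nsymbt = struct.unpack("<i", header[92:96])[0]
        apix = cella[0] / mx if mx else 1.0
        fh.seek(_HEADER_SIZE + nsymbt)
        data = np.frombuffer(fh.read(nx * ny * nz * 4), dtype="<f4")
        if data.size != nx * ny * nz:
            raise ValueError("truncated MRC data block")
        data = data.reshape(nz, ny, nx).copy()
    return data, float(apix), ispg == 0
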