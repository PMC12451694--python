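"""Minimal codec for ImageJ ``.roi`` files and ``.zip`` archives of them.

Only the two vertex-list ROI kinds produced by manual cell annotation are
supported: polygon (type 0) and freehand (type 7).  All other kinds (line,
point, oval, ...) are rejected loudly with the kind named, since they cannot
carry a closed cell outline.

The classic binary layout is a big-endian 64-byte header ("Iout" magic,
version, type byte, int16 bounding box, vertex count) followed by the x then
y vertex coordinates as int16 offsets from the bounding-box corner.  ImageJ's
coordinates are (x, y) with integer values on pixel corners, which matches
this package's (row, col) corner-origin convention directly (x = col,
y = row).  Vertex coordinates are stored at integer precision, the declared
precision of this dialect.
"""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path

import numpy as np

MAGIC = b"Iout"
VERSION = 227
TYPE_POLYGON = 0
TYPE_FREEHAND = 7

_TYPE_NAMES = {
    0: "polygon",
    1: "rectangle",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "no-roi",
    7: "freehand",
    8: "traced",
    9: "angle",
    10: "point",
}


class RoiFormatError(ValueError):
    """Raised for corrupt files or unsupported ROI kinds."""


def encode(vertices: np.ndarray, roi_type: int = TYPE_POLYGON) -> bytes:
    """Serialize an ``(n, 2)`` (row, col) vertex array to ``.roi`` bytes."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise RoiFormatError("a polygon ROI needs an (n>=3, 2) vertex array")
    y = np.round(v[:, 0]).astype(int)
    x = np.round(v[:, 1]).astype(int)
    top, left = int(y.min()), int(x.min())
    bottom, right = int(y.max()), int(x.max())
    n = len(v)
    header = bytearray(64)
    struct.pack_into(">4sh", header, 0, MAGIC, VERSION)
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *(x - left)) + struct.pack(f">{n}h", *(y - top))
    return bytes(header) + body


def decode(data: bytes) -> np.ndarray:
    """Parse ``.roi`` bytes into an ``(n, 2)`` float (row, col) vertex array."""
    if len(data) < 64 or data[:4] != MAGIC:
        raise RoiFormatError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    if roi_type not in (TYPE_POLYGON, TYPE_FREEHAND):
        kind = _TYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise RoiFormatError(
            f"unsupported ImageJ ROI kind '{kind}'; only polygon and freehand "
            "cell outlines are accepted"
        )
    top, left, _bottom, _right = struct.unpack_from(">4h", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    need = 64 + 4 * n
    if n < 3 or len(data) < need:
        raise RoiFormatError("truncated ImageJ ROI file")
    x = np.array(struct.unpack_from(f">{n}h", data, 64), dtype=float) + left
    y = np.array(struct.unpack_from(f">{n}h", data, 64 + 2 * n), dtype=float) + top
    return np.column_stack([y, x])


def write_zip(rois: dict[str, np.ndarray], path: str | Path) -> None:
    """Write ``{cell_id: vertices}`` as a ``.zip`` of ``<cell_id>.roi``."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for cell_id, vertices in rois.items():
            info = zipfile.ZipInfo(f"{cell_id}.roi")  # fixed date => deterministic
            zf.writestr(info, encode(vertices))


def read_zip(path: str | Path) -> dict[str, np.ndarray]:
    """Read a ``.zip`` archive into ``{cell_id: vertices}`` (archive order)."""
    out: dict[str, np.ndarray] = {}
    try:
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                if not name.lower().endswith(".roi"):
                    continue
                out[Path(name).stem] = decode(zf.read(name))
    except zipfile.BadZipFile as exc:
        raise RoiFormatError(f"corrupt ROI archive: {path}") from exc
    return out
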