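"""Cell-outline annotations: the :class:`CellROI` type and its two on-disk
dialects (ImageJ ``.roi``/``.zip`` and a plain-JSON polygon format)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ijroi
from .geometry import as_shapely, rasterize_polygon

log = logging.getLogger(__name__)


@dataclass
class CellROI:
    """One annotated cell boundary polygon.

    ``polygon`` is an ``(n, 2)`` array of (row, col) vertices in the package's
    0-based corner-origin convention (see :mod:`faractin.geometry`).
    ``source`` records provenance: ``manual``, ``imported``, ``synthetic`` or
    ``jittered``.
    """

    cell_id: str
    polygon: np.ndarray
    source: str = "imported"
    _mask_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> "CellROI":
        poly = as_shapely(self.polygon)
        if len(self.polygon) < 3:
            raise ValueError(f"ROI {self.cell_id}: fewer than 3 vertices")
        if not poly.is_valid:
            raise ValueError(f"ROI {self.cell_id}: polygon is self-intersecting")
        if poly.area <= 0:
            raise ValueError(f"ROI {self.cell_id}: polygon has zero area")
        return self

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Raster mask of the polygon on an image of the given shape."""
        key = tuple(shape)
        if key not in self._mask_cache:
            self._mask_cache[key] = rasterize_polygon(self.polygon, shape)
        return self._mask_cache[key]

    def touches_border(self, shape: tuple[int, int]) -> bool:
        v = np.asarray(self.polygon, dtype=float)
        return bool(
            v[:, 0].min() <= 0
            or v[:, 1].min() <= 0
            or v[:, 0].max() >= shape[0]
            or v[:, 1].max() >= shape[1]
        )


def read_rois(path: str | Path) -> list[CellROI]:
    """Read cell ROIs from ``.json``, ImageJ ``.zip`` or a single ``.roi``.

    Vertices are returned in 0-based (row, col) pixel coordinates; ROI kinds
    other than closed polygons are rejected with the kind named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".json":
        payload = json.loads(path.read_text())
        records = payload["rois"] if isinstance(payload, dict) else payload
        rois = [
            CellROI(str(r["cell_id"]), np.asarray(r["vertices"], dtype=float)).validate()
            for r in records
        ]
    elif suffix == ".zip":
        rois = [
            CellROI(cell_id, vertices).validate()
            for cell_id, vertices in ijroi.read_zip(path).items()
        ]
    elif suffix == ".roi":
        rois = [CellROI(path.stem, ijroi.decode(path.read_bytes())).validate()]
    else:
        raise ValueError(f"unsupported ROI dialect: {path.name}")
    if not rois:
        log.warning("no ROIs found in %s", path)
    return rois


def write_rois(rois: list[CellROI], path: str | Path) -> None:
    """Write ROIs as ``.json`` or ImageJ ``.zip`` (integer-pixel precision)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        payload = {
            "rois": [
                {"cell_id": r.cell_id, "vertices": np.asarray(r.polygon, float).tolist()}
                for r in rois
            ]
        }
        path.write_text(json.dumps(payload))
    elif suffix == ".zip":
        ijroi.write_zip({r.cell_id: np.asarray(r.polygon) for r in rois}, path)
    else:
        raise ValueError(f"unsupported ROI dialect: {path.name}")


def jitter_rois(
    rois: list[CellROI], amplitude: float, rng: np.random.Generator
) -> list[CellROI]:
    """Displace every vertex by uniform noise in [-amplitude, +amplitude] px.

    Emulates a second examiner re-annotating the same cells.  Occasional
    self-intersections created by the jitter are repaired during
    rasterization (buffer(0)), so the returned ROIs are not re-validated.
    """
    out = []
    for roi in rois:
        v = np.asarray(roi.polygon, dtype=float)
        jitter = rng.uniform(-amplitude, amplitude, size=v.shape)
        out.append(CellROI(roi.cell_id, v + jitter, source="jittered"))
    return out
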