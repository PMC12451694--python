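"""Per-cell FAR quantification: the core measurement of the pipeline.

For each annotated cell the two channels are background-subtracted, a
nuclear mask is derived by thresholding DAPI within the cell outline, an
F-actin-positive mask by thresholding the actin channel within the outline,
and the FAR percentage is

    FAR% = 100 * (actin intensity in the nuclear region)
               / (total cellular actin intensity)

where, with the default ``denominator="actin_positive"``, both sums run over
the thresholded F-actin-positive area (numerator restricted to its
intersection with the nuclear mask).  The ``whole_cell`` alternative sums
over the full cell outline instead and is kept for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .geometry import polygon_bounds
from .image import MultiChannelImage, read_image
from .rois import CellROI, read_rois
from .tables import resolve_manifest_path

log = logging.getLogger(__name__)

QC_NO_NUCLEUS = "no_nucleus"
QC_BORDER = "border"
QC_EMPTY_ACTIN = "empty_actin"


@dataclass
class SegmentationConfig:
    """Tunable knobs of the per-cell segmentation.

    ``dapi_threshold``/``actin_threshold`` are either the string ``"otsu"``
    (threshold computed per cell on the background-subtracted intensities
    inside the outline) or a fixed non-negative value.
    """

    background_method: str = "outside_roi_median"  # or "fixed"
    background_value: float | tuple[float, float] = 0.0
    dapi_threshold: str | float = "otsu"
    actin_threshold: str | float = "otsu"
    min_nucleus_area: int = 50  # px^2
    fill_nuclear_holes: bool = True
    exclude_border_cells: bool = True
    denominator: str = "actin_positive"  # or "whole_cell"

    def validate(self) -> "SegmentationConfig":
        for name in ("dapi_threshold", "actin_threshold"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "otsu":
                    raise ValueError(f"{name} must be 'otsu' or a fixed value")
            elif v < 0:
                raise ValueError(f"fixed {name} must be >= 0")
        if self.min_nucleus_area < 0:
            raise ValueError("min_nucleus_area must be >= 0")
        if self.denominator not in ("actin_positive", "whole_cell"):
            raise ValueError("denominator must be 'actin_positive' or 'whole_cell'")
        if self.background_method not in ("outside_roi_median", "fixed"):
            raise ValueError("background_method must be 'outside_roi_median' or 'fixed'")
        return self


@dataclass
class CellMeasurement:
    """The atomic result: one cell's FAR% with its ingredients and QC flags."""

    cell_id: str
    far_percent: float  # NaN when undefined (flagged)
    nuclear_actin_sum: float
    total_actin_sum: float
    n_nuclei: int
    cell_area: int
    nuclear_area: int
    actin_positive_area: int
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return not self.qc_flags

    def to_record(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "far_percent": self.far_percent,
            "nuclear_actin_sum": self.nuclear_actin_sum,
            "total_actin_sum": self.total_actin_sum,
            "n_nuclei": self.n_nuclei,
            "cell_area": self.cell_area,
            "nuclear_area": self.nuclear_area,
            "actin_positive_area": self.actin_positive_area,
            "qc_flags": ";".join(sorted(self.qc_flags)),
        }


def measurements_to_frame(measurements: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame.from_records([m.to_record() for m in measurements])


def estimate_background(
    image: MultiChannelImage,
    rois: list[CellROI],
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Per-channel background level.

    Default: the median intensity over all pixels outside the union of the
    ROIs.  With no ROIs the whole-image median is used; if the ROIs tile the
    whole image the global 5th percentile is used instead (logged).
    """
    config = (config or SegmentationConfig()).validate()
    if config.background_method == "fixed":
        v = config.background_value
        pair = (v, v) if np.isscalar(v) else v
        return np.asarray(pair, dtype=float)
    pixels = np.asarray(image.pixels, dtype=float)
    if not rois:
        log.warning("no ROIs given; background set to the whole-image median")
        return np.median(pixels, axis=(1, 2))
    outside = np.ones(image.shape, dtype=bool)
    for roi in rois:
        outside &= ~roi.mask(image.shape)
    if not outside.any():
        log.warning("no pixels outside ROIs; background set to global 5th percentile")
        return np.percentile(pixels, 5, axis=(1, 2))
    return np.median(pixels[:, outside], axis=1)


def _threshold(values: np.ndarray, setting: str | float) -> float | None:
    """Resolve a threshold setting; None when the histogram is degenerate."""
    if isinstance(setting, str):  # "otsu"
        if values.size == 0 or np.ptp(values) == 0:
            return None
        return float(threshold_otsu(values))
    return float(setting)


def _subtracted_crop(image, roi, background):
    """Background-subtracted channel crops + ROI mask on the cell's bbox."""
    r0, r1, c0, c1 = polygon_bounds(roi.polygon, image.shape, pad=1)
    mask_full = roi.mask(image.shape)
    mask = mask_full[r0:r1, c0:c1]
    crop = np.asarray(image.pixels[:, r0:r1, c0:c1], dtype=float)
    sub = np.clip(crop - np.asarray(background, dtype=float)[:, None, None], 0.0, None)
    return (r0, r1, c0, c1), sub, mask


def segment_nucleus(
    image: MultiChannelImage,
    roi: CellROI,
    config: SegmentationConfig | None = None,
    background: np.ndarray | None = None,
):
    """Nuclear mask within the cell outline, from the DAPI channel.

    Thresholds background-subtracted DAPI restricted to the outline (Otsu by
    default), removes components below ``min_nucleus_area``, fills holes,
    and returns the union of surviving components — multinucleated cells
    yield one combined mask.  Returns ``(mask, n_nuclei, flags)`` with the
    mask on the full image grid; an empty mask carries the ``no_nucleus``
    flag.
    """
    config = (config or SegmentationConfig()).validate()
    if background is None:
        background = estimate_background(image, [roi], config)
    bounds, sub, mask = _subtracted_crop(image, roi, background)
    if not mask.any():
        raise ValueError(f"ROI {roi.cell_id} rasterizes to zero pixels")
    dapi = sub[image.channel_names.index("dapi")]
    thr = _threshold(dapi[mask], config.dapi_threshold)
    full = np.zeros(image.shape, dtype=bool)
    if thr is None:
        return full, 0, frozenset({QC_NO_NUCLEUS})
    nuc = (dapi > thr) & mask
    labels, n = ndi.label(nuc)
    if n and config.min_nucleus_area > 0:
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= config.min_nucleus_area) + 1
        nuc = np.isin(labels, keep)
        n = len(keep)
    if n == 0:
        log.info("cell %s: no nucleus above %d px^2", roi.cell_id, config.min_nucleus_area)
        return full, 0, frozenset({QC_NO_NUCLEUS})
    if config.fill_nuclear_holes:
        nuc = ndi.binary_fill_holes(nuc) & mask
    r0, r1, c0, c1 = bounds
    full[r0:r1, c0:c1] = nuc
    return full, int(n), frozenset()


def segment_actin(
    image: MultiChannelImage,
    roi: CellROI,
    config: SegmentationConfig | None = None,
    background: np.ndarray | None = None,
):
    """F-actin-positive mask within the cell outline.

    All supra-threshold pixels inside the outline; no size filtering.  A
    degenerate (constant) histogram yields an empty mask with the
    ``empty_actin`` flag rather than an invented threshold.
    """
    config = (config or SegmentationConfig()).validate()
    if background is None:
        background = estimate_background(image, [roi], config)
    bounds, sub, mask = _subtracted_crop(image, roi, background)
    if not mask.any():
        raise ValueError(f"ROI {roi.cell_id} rasterizes to zero pixels")
    actin = sub[image.channel_names.index("actin")]
    thr = _threshold(actin[mask], config.actin_threshold)
    full = np.zeros(image.shape, dtype=bool)
    if thr is None:
        return full, frozenset({QC_EMPTY_ACTIN})
    pos = (actin > thr) & mask
    if not pos.any():
        return full, frozenset({QC_EMPTY_ACTIN})
    r0, r1, c0, c1 = bounds
    full[r0:r1, c0:c1] = pos
    return full, frozenset()


def compute_far(
    image: MultiChannelImage,
    roi: CellROI,
    nuclear_mask: np.ndarray,
    actin_mask: np.ndarray,
    config: SegmentationConfig | None = None,
    background: np.ndarray | None = None,
    n_nuclei: int = 0,
    extra_flags: frozenset[str] = frozenset(),
) -> CellMeasurement:
    """Assemble the per-cell FAR measurement from the two masks."""
    config = (config or SegmentationConfig()).validate()
    if background is None:
        background = estimate_background(image, [roi], config)
    bounds, sub, mask = _subtracted_crop(image, roi, background)
    r0, r1, c0, c1 = bounds
    actin = sub[image.channel_names.index("actin")]
    nuc = nuclear_mask[r0:r1, c0:c1] & mask
    pos = actin_mask[r0:r1, c0:c1] & mask
    if config.denominator == "actin_positive":
        total = float(actin[pos].sum())
        nuclear = float(actin[nuc & pos].sum())
    else:  # whole_cell
        total = float(actin[mask].sum())
        nuclear = float(actin[nuc].sum())
    flags = set(extra_flags)
    if total > 0:
        far = 100.0 * nuclear / total
    else:
        far = float("nan")
        flags.add(QC_EMPTY_ACTIN)
        log.info("cell %s: zero total actin intensity; FAR undefined", roi.cell_id)
    return CellMeasurement(
        cell_id=roi.cell_id,
        far_percent=far,
        nuclear_actin_sum=nuclear,
        total_actin_sum=total,
        n_nuclei=n_nuclei,
        cell_area=int(mask.sum()),
        nuclear_area=int(nuc.sum()),
        actin_positive_area=int(pos.sum()),
        qc_flags=frozenset(flags),
    )


def process_image(
    image: MultiChannelImage,
    rois: list[CellROI],
    config: SegmentationConfig | None = None,
) -> list[CellMeasurement]:
    """Run the full per-cell chain over every ROI of one image.

    Output order matches ROI order.  Cells touching the image border are
    flagged (and thereby excluded downstream) when
    ``config.exclude_border_cells`` is set; every exclusion carries a QC
    flag and a log line.
    """
    config = (config or SegmentationConfig()).validate()
    if not rois:
        log.warning("process_image called with an empty ROI list")
        return []
    background = estimate_background(image, rois, config)
    measurements = []
    for roi in rois:
        flags = set()
        if config.exclude_border_cells and roi.touches_border(image.shape):
            flags.add(QC_BORDER)
            log.info("cell %s touches the image border; flagged", roi.cell_id)
        nuclear_mask, n_nuclei, nflags = segment_nucleus(image, roi, config, background)
        actin_mask, aflags = segment_actin(image, roi, config, background)
        m = compute_far(
            image, roi, nuclear_mask, actin_mask, config, background,
            n_nuclei=n_nuclei, extra_flags=frozenset(flags | set(nflags) | set(aflags)),
        )
        measurements.append(m)
    n_flagged = sum(not m.ok for m in measurements)
    if n_flagged:
        log.info("%d/%d cells flagged for exclusion", n_flagged, len(measurements))
    return measurements


def quantify_study(
    manifest: pd.DataFrame,
    config: SegmentationConfig | None = None,
    channel_map: dict[str, int] | None = None,
    manifest_path: str | Path | None = None,
) -> pd.DataFrame:
    """Quantify every image of a study manifest into one tidy cell table.

    The returned frame carries the manifest's design coordinates (donor,
    sample, condition, phase, replicate) next to each cell measurement.
    """
    config = (config or SegmentationConfig()).validate()
    frames = []
    for _, row in manifest.iterrows():
        image_path = row["image_path"]
        roi_path = row["roi_path"]
        if manifest_path is not None:
            image_path = resolve_manifest_path(manifest_path, image_path)
            roi_path = resolve_manifest_path(manifest_path, roi_path)
        image = read_image(image_path, channel_map)
        rois = read_rois(roi_path)
        frame = measurements_to_frame(process_image(image, rois, config))
        for col in ("donor", "sample", "condition", "phase", "replicate"):
            if col in row.index:
                frame[col] = row[col]
        frame["image_path"] = row["image_path"]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
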