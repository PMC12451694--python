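"""Synthetic two-channel podocyte-like image generator with ground truth.

The generator emulates the raw material of the F-actin redistribution (FAR)
assay: adherent cells stained for F-actin (phalloidin channel) and DNA
(DAPI channel).  Healthy cells show homogeneously distributed cytoplasmic
actin fibers; injured cells show an elevated nuclear actin fraction.  Every
rendered cell carries ``rho``, the target noiseless nuclear share of total
cellular actin intensity, which is the ground-truth analogue of the FAR
percentage the pipeline measures.

Construction of the actin channel: cytoplasmic texture is a sum of random
anti-aliased chords across the cell ellipse (Gaussian cross profile), masked
out of the nucleus; the nuclear component is the same fiber texture clipped
to the nucleus.  The two components are scaled analytically so that the
noiseless nuclear share equals ``rho`` exactly, and so the per-pixel
intensity statistics of nucleus and cytoplasm stay comparable — which keeps
a single Otsu threshold from preferentially discarding either compartment.

Noise model: Poisson (gain-scaled) applied to signal plus background, then
additive Gaussian read noise, then 16-bit quantization.  Identical
(spec, seed) pairs produce bit-identical images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ellipse_mask_crop,
    ellipse_norm2_crop,
    ellipse_polygon,
    polygon_bounds,
    rasterize_polygon,
    segment_profiles,
)
from .image import MultiChannelImage, write_image
from .rois import CellROI, write_rois
from .tables import MANIFEST_COLUMNS, write_manifest

log = logging.getLogger(__name__)

FIBER_SIGMA = 1.5  # px, Gaussian cross profile of one fiber
FIBER_COUNT_RANGE = (20, 60)  # random chords per cell
BINUCLEATION_RATE = 0.25  # fraction of cells with two nuclei
NUCLEUS_SCALE_RANGE = (0.42, 0.50)  # nucleus semi-axes relative to cell
CELL_MAJOR_RANGE = (34.0, 46.0)  # px, semi-axis
CELL_MINOR_RANGE = (22.0, 30.0)
TOTAL_ACTIN_RANGE = (1.4e5, 2.2e5)  # arbitrary intensity units per cell
DAPI_AMPLITUDE = 3000.0
MIN_CELL_GAP = 4.0  # px between bounding circles
NUCLEAR_CHORD_FRACTION = 0.5  # nuclear chords per nucleus, as a fraction of fiber_count


class SceneLayoutError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass
class CellSpec:
    """Geometry and intensity recipe for one rendered cell."""

    center: tuple[float, float]
    cell_axes: tuple[float, float]
    orientation: float = 0.0
    n_nuclei: int = 1
    nucleus_centers: tuple[tuple[float, float], ...] = ()
    nucleus_axes: tuple[tuple[float, float], ...] = ()
    rho: float = 0.15
    total_actin: float = 1.5e5
    fiber_count: int = 40
    dapi_amplitude: float = DAPI_AMPLITUDE

    def __post_init__(self):
        if not self.nucleus_centers:
            self.nucleus_centers = (self.center,)
        if not self.nucleus_axes:
            self.nucleus_axes = tuple(
                (0.45 * self.cell_axes[0], 0.45 * self.cell_axes[1])
                for _ in range(self.n_nuclei)
            )

    def validate(self) -> "CellSpec":
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if len(self.nucleus_centers) != self.n_nuclei or len(self.nucleus_axes) != self.n_nuclei:
            raise ValueError("nucleus_centers/nucleus_axes must match n_nuclei")
        if self.total_actin <= 0 or self.fiber_count < 1:
            raise ValueError("total_actin must be > 0 and fiber_count >= 1")
        ct, st = np.cos(self.orientation), np.sin(self.orientation)
        for ncenter, naxes in zip(self.nucleus_centers, self.nucleus_axes):
            if min(naxes) < 1.0:
                raise ValueError("nucleus semi-axes must be >= 1 px")
            # nucleus boundary must lie inside the cell ellipse
            t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
            br = ncenter[0] + (naxes[0] * np.cos(t)) * ct - (naxes[1] * np.sin(t)) * st
            bc = ncenter[1] + (naxes[0] * np.cos(t)) * st + (naxes[1] * np.sin(t)) * ct
            dr, dc = br - self.center[0], bc - self.center[1]
            u = dr * ct + dc * st
            v = -dr * st + dc * ct
            if np.any((u / self.cell_axes[0]) ** 2 + (v / self.cell_axes[1]) ** 2 > 1.0):
                raise ValueError("nucleus extends outside the cell ellipse")
        return self

    @property
    def bounding_radius(self) -> float:
        return float(max(self.cell_axes))


@dataclass
class SceneSpec:
    """One field of view: cells, background and the noise model."""

    image_shape: tuple[int, int]
    cells: list[CellSpec]
    background_level: float = 200.0
    poisson_gain: float = 1.0
    gaussian_sd: float | str = "auto"  # "auto" => 2% of per-channel max signal
    seed: int = 0

    def validate(self) -> "SceneSpec":
        for i, a in enumerate(self.cells):
            a.validate()
            for b in self.cells[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.bounding_radius + b.bounding_radius:
                    raise SceneLayoutError(
                        "cells overlap (bounding circles intersect); the generator "
                        "analyzes singular, non-touching cells only"
                    )
        return self


def _random_chords(
    center, axes, orientation, count, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Endpoints of random chords across an ellipse, with amplitude jitter."""
    t1, t2 = rng.uniform(0, 2 * np.pi, (2, count))
    amps = rng.uniform(0.6, 1.4, count)
    ct, st = np.cos(orientation), np.sin(orientation)

    def boundary(t):
        u = axes[0] * np.cos(t)
        v = axes[1] * np.sin(t)
        return np.column_stack([center[0] + u * ct - v * st, center[1] + u * st + v * ct])

    return boundary(t1), boundary(t2), amps


def _render_cell_crop(spec: CellSpec, canvas_shape, rng):
    """Render one cell on its bounding-box crop.

    Returns ``(bounds, raster_crop, nuclear_mask_crop, cell_mask_crop,
    polygon, stats)`` where ``raster_crop`` is a (2, h, w) noiseless float
    array and ``stats`` holds the exact noiseless nuclear/total actin sums.
    """
    spec.validate()
    polygon = ellipse_polygon(spec.center, spec.cell_axes, spec.orientation)
    bounds = polygon_bounds(polygon, canvas_shape, pad=3)
    r0, r1, c0, c1 = bounds
    if r1 <= r0 or c1 <= c0:
        raise ValueError("cell lies outside the canvas")
    crop_shape = (r1 - r0, c1 - c0)
    shifted = polygon - np.array([r0, c0], dtype=float)
    cell_mask = rasterize_polygon(shifted, crop_shape)

    nuc_mask = np.zeros(crop_shape, dtype=bool)
    dapi = np.zeros(crop_shape, dtype=float)
    for ncenter, naxes in zip(spec.nucleus_centers, spec.nucleus_axes):
        nc = (ncenter[0] - r0, ncenter[1] - c0)
        e2 = ellipse_norm2_crop(nc, naxes, spec.orientation, (0, crop_shape[0], 0, crop_shape[1]))
        inside = e2 <= 1.0
        nuc_mask |= inside
        profile = np.where(inside, (1.0 - np.minimum(e2, 1.0)) ** 0.3, 0.0)
        dapi = np.maximum(dapi, spec.dapi_amplitude * profile)
    nuc_mask &= cell_mask
    dapi[~nuc_mask] = 0.0

    # cytoplasmic fiber texture: chords across the cell, nucleus excluded
    p1, p2, amps = _random_chords(
        spec.center, spec.cell_axes, spec.orientation, spec.fiber_count, rng
    )
    offset = np.array([r0, c0], dtype=float)
    cyt = segment_profiles(p1 - offset, p2 - offset, (0, crop_shape[0], 0, crop_shape[1]),
                           FIBER_SIGMA, amps)
    cyt[~cell_mask | nuc_mask] = 0.0

    # nuclear component: the same texture statistics, clipped to each nucleus
    nuc = np.zeros(crop_shape, dtype=float)
    for ncenter, naxes in zip(spec.nucleus_centers, spec.nucleus_axes):
        count = max(8, int(spec.fiber_count * NUCLEAR_CHORD_FRACTION))
        q1, q2, namps = _random_chords(ncenter, naxes, spec.orientation, count, rng)
        nuc += segment_profiles(q1 - offset, q2 - offset,
                                (0, crop_shape[0], 0, crop_shape[1]), FIBER_SIGMA, namps)
    nuc[~nuc_mask] = 0.0

    s_cyt, s_nuc = cyt.sum(), nuc.sum()
    if spec.rho < 1.0 and s_cyt <= 0:
        raise ValueError("cytoplasmic fiber texture rendered empty; increase fiber_count")
    if spec.rho > 0.0 and s_nuc <= 0:
        raise ValueError("nuclear texture rendered empty; nucleus too small")
    a = spec.total_actin * (1.0 - spec.rho) / s_cyt if spec.rho < 1.0 else 0.0
    b = spec.total_actin * spec.rho / s_nuc if spec.rho > 0.0 else 0.0
    actin = a * cyt + b * nuc

    stats = {
        "rho": spec.rho,
        "nuclear_actin_sum": float(actin[nuc_mask].sum()),
        "total_actin_sum": float(actin[cell_mask].sum()),
        "n_nuclei": spec.n_nuclei,
    }
    raster = np.stack([dapi, actin])
    return bounds, raster, nuc_mask, cell_mask, polygon, stats


def render_cell(spec: CellSpec, canvas_shape: tuple[int, int], rng: np.random.Generator):
    """Render a single cell onto a full canvas.

    Returns ``(raster, nuclear_mask, polygon)``: a noiseless (2, H, W) float
    raster (dapi, actin), the boolean nuclear mask and the cell outline
    polygon.  The noiseless nuclear share of total actin equals ``spec.rho``
    exactly by construction.
    """
    bounds, crop, nuc_crop, _cell, polygon, _ = _render_cell_crop(spec, canvas_shape, rng)
    r0, r1, c0, c1 = bounds
    raster = np.zeros((2, *canvas_shape), dtype=float)
    raster[:, r0:r1, c0:c1] = crop
    nuclear_mask = np.zeros(canvas_shape, dtype=bool)
    nuclear_mask[r0:r1, c0:c1] = nuc_crop
    return raster, nuclear_mask, polygon


def render_scene(spec: SceneSpec):
    """Render a full field of view with noise, ROIs and a ground-truth table.

    Returns ``(image, rois, truth)``: a 16-bit :class:`MultiChannelImage`,
    one :class:`CellROI` per cell (ids ``cell_000`` ...), and a DataFrame
    with the exact noiseless per-cell nuclear/total actin sums and ``rho``.
    Deterministic: same spec and seed give bit-identical pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    noiseless = np.zeros((2, *spec.image_shape), dtype=float)
    rois: list[CellROI] = []
    records = []
    for i, cell in enumerate(spec.cells):
        cell_id = f"cell_{i:03d}"
        bounds, crop, _nuc, cell_mask, polygon, stats = _render_cell_crop(
            cell, spec.image_shape, rng
        )
        r0, r1, c0, c1 = bounds
        noiseless[:, r0:r1, c0:c1] += crop
        roi = CellROI(cell_id, polygon, source="synthetic")
        # the cell mask was already rasterized on the crop; prime the ROI's
        # cache so in-memory quantification need not repeat the work
        full_mask = np.zeros(spec.image_shape, dtype=bool)
        full_mask[r0:r1, c0:c1] = cell_mask
        roi._mask_cache[tuple(spec.image_shape)] = full_mask
        rois.append(roi)
        records.append({"cell_id": cell_id, **stats})

    signal = noiseless + spec.background_level
    gain = spec.poisson_gain
    if gain > 0:
        noisy = rng.poisson(signal / gain).astype(float) * gain
    else:  # shot noise disabled
        noisy = signal.copy()
    if spec.gaussian_sd == "auto":
        # one detector for both channels: read noise is 2% of the maximum
        # signal in the field (typically the DAPI peak), in absolute counts
        sd = 0.02 * signal.max()
    else:
        sd = float(spec.gaussian_sd)
    if sd > 0:
        noisy += rng.normal(0.0, sd, noisy.shape)
    pixels = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)
    image = MultiChannelImage(pixels)
    return image, rois, pd.DataFrame.from_records(records)


def sample_scene_cells(
    n_cells: int,
    image_shape: tuple[int, int],
    rho: float,
    rng: np.random.Generator,
    max_tries_per_cell: int = 3000,
) -> list[CellSpec]:
    """Draw random non-overlapping cell geometries with a common ``rho``."""
    cells: list[CellSpec] = []
    for _ in range(n_cells):
        a = rng.uniform(*CELL_MAJOR_RANGE)
        b = rng.uniform(*CELL_MINOR_RANGE)
        orientation = rng.uniform(0, np.pi)
        margin = a + 3.0
        if 2 * margin >= min(image_shape):
            raise SceneLayoutError("image_shape too small for a single interior cell")
        placed = False
        for _try in range(max_tries_per_cell):
            center = (
                rng.uniform(margin, image_shape[0] - margin),
                rng.uniform(margin, image_shape[1] - margin),
            )
            ok = all(
                np.hypot(center[0] - c.center[0], center[1] - c.center[1])
                >= a + c.bounding_radius + MIN_CELL_GAP
                for c in cells
            )
            if ok:
                placed = True
                break
        if not placed:
            raise SceneLayoutError(
                f"could not place {n_cells} non-overlapping cells in image of shape "
                f"{image_shape}; reduce cells_per_replicate or enlarge image_shape"
            )
        ct, st = np.cos(orientation), np.sin(orientation)
        s = rng.uniform(*NUCLEUS_SCALE_RANGE)
        if rng.random() < BINUCLEATION_RATE:
            naxes = (s * a / 1.35, s * b / 1.35)
            centers = []
            for sign in (-1.0, 1.0):
                u = sign * 0.40 * a
                v = rng.uniform(-0.05, 0.05) * b
                centers.append((center[0] + u * ct - v * st, center[1] + u * st + v * ct))
            nucleus_centers = tuple(centers)
            nucleus_axes = (naxes, naxes)
            n_nuclei = 2
        else:
            u = rng.uniform(-0.15, 0.15) * a
            v = rng.uniform(-0.15, 0.15) * b
            nucleus_centers = ((center[0] + u * ct - v * st, center[1] + u * st + v * ct),)
            nucleus_axes = ((s * a, s * b),)
            n_nuclei = 1
        cells.append(
            CellSpec(
                center=center,
                cell_axes=(a, b),
                orientation=orientation,
                n_nuclei=n_nuclei,
                nucleus_centers=nucleus_centers,
                nucleus_axes=nucleus_axes,
                rho=rho,
                total_actin=rng.uniform(*TOTAL_ACTIN_RANGE),
                fiber_count=int(rng.integers(FIBER_COUNT_RANGE[0], FIBER_COUNT_RANGE[1] + 1)),
            ).validate()
        )
    return cells


def simulate_replicate(
    rho: float,
    n_cells: int,
    seed,
    image_shape: tuple[int, int] = (768, 768),
    background_level: float = 200.0,
):
    """Convenience: one replicate field at a given ``rho`` (in-memory).

    ``seed`` may be an int or a sequence of ints (hierarchical seeding).
    """
    scene_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    layout_rng = np.random.default_rng([scene_seed, 0])
    cells = sample_scene_cells(n_cells, image_shape, rho, layout_rng)
    scene = SceneSpec(
        image_shape=image_shape,
        cells=cells,
        background_level=background_level,
        seed=scene_seed,
    )
    return render_scene(scene)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass
class ExposureSample:
    """One exposure material (pooled donor plasma or a patient sample)."""

    name: str
    condition: str  # "control" or "injurious"
    phase: str = "pre"  # pre- or post-transplant sampling


@dataclass
class StudyDesign:
    """Donor-line x exposure-sample x replicate layout of a synthetic study."""

    donor_lines: list[str]
    exposure_samples: list[ExposureSample]
    effect_map: dict[tuple[str, str], float]
    n_replicates: int = 3
    cells_per_replicate: int = 30
    image_shape: tuple[int, int] = (768, 768)
    background_level: float = 200.0

    def validate(self) -> "StudyDesign":
        controls = [s for s in self.exposure_samples if s.condition == "control"]
        if len(controls) != 1:
            raise ValueError("study design needs exactly one control exposure sample")
        if self.n_replicates < 1 or self.cells_per_replicate < 1:
            raise ValueError("n_replicates and cells_per_replicate must be >= 1")
        for donor in self.donor_lines:
            for sample in self.exposure_samples:
                if (donor, sample.name) not in self.effect_map:
                    raise ValueError(f"effect_map is missing ({donor}, {sample.name})")
        return self

    @property
    def control_sample(self) -> ExposureSample:
        return next(s for s in self.exposure_samples if s.condition == "control")


def default_study_design() -> StudyDesign:
    """The default 5-donor crossmatch design (75 image sets at N = 3).

    Mirrors the qualitative structure of a pre-transplant crossmatch: a
    pooled-donor-plasma control (PDP), three effective patient samples and
    one null patient sample; donor D3 is resistant to every sample and donor
    D5 responds with an intermediate effect.  Ground-truth nuclear actin
    fractions: baseline 0.15, intermediate 0.25, strong 0.40.
    """
    donors = ["D1", "D2", "D3", "D4", "D5"]
    samples = [
        ExposureSample("PDP", "control", "pre"),
        ExposureSample("P1A", "injurious", "pre"),
        ExposureSample("P2A", "injurious", "pre"),
        ExposureSample("P3A", "injurious", "pre"),
        ExposureSample("P4A", "injurious", "pre"),
    ]
    base, mid, high = 0.15, 0.25, 0.40
    effect: dict[tuple[str, str], float] = {}
    for donor in donors:
        for sample in samples:
            rho = base
            if sample.name in ("P1A", "P2A", "P4A"):
                if donor in ("D1", "D2", "D4"):
                    rho = high
                elif donor == "D5":
                    rho = mid
            effect[(donor, sample.name)] = rho
    return StudyDesign(donors, samples, effect).validate()


def generate_study(design: StudyDesign, out_dir: str | Path, seed: int):
    """Write a full synthetic study to disk.

    Produces one two-channel TIFF + ROI files (JSON and ImageJ .zip) per
    donor x sample x replicate, a ``manifest.csv`` linking files to design
    coordinates, and a ``truth.csv`` with per-cell ground truth.  Returns
    ``(manifest, truth)`` as DataFrames.  Fully deterministic in ``seed``.
    """
    design.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    manifest_rows = []
    truth_frames = []
    for donor in design.donor_lines:
        for sample in design.exposure_samples:
            rho = design.effect_map[(donor, sample.name)]
            for rep in range(1, design.n_replicates + 1):
                scene_seed = int(master.integers(0, 2**31 - 1))
                layout_rng = np.random.default_rng([scene_seed, 0])
                cells = sample_scene_cells(
                    design.cells_per_replicate, design.image_shape, rho, layout_rng
                )
                scene = SceneSpec(
                    image_shape=design.image_shape,
                    cells=cells,
                    background_level=design.background_level,
                    seed=scene_seed,
                )
                image, rois, truth = render_scene(scene)
                stem = f"{donor}_{sample.name}_r{rep}"
                image_path = f"{stem}.tif"
                roi_path = f"{stem}_rois.json"
                write_image(image, out_dir / image_path)
                write_rois(rois, out_dir / roi_path)
                write_rois(rois, out_dir / f"{stem}_rois.zip")
                row = {
                    "image_path": image_path,
                    "roi_path": roi_path,
                    "donor": donor,
                    "sample": sample.name,
                    "condition": sample.condition,
                    "phase": sample.phase,
                    "replicate": rep,
                    "seed": scene_seed,
                }
                manifest_rows.append(row)
                truth = truth.assign(
                    donor=donor, sample=sample.name, condition=sample.condition,
                    phase=sample.phase, replicate=rep,
                )
                truth_frames.append(truth)
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    write_manifest(manifest, out_dir / "manifest.csv")
    truth_table = pd.concat(truth_frames, ignore_index=True)
    truth_table.to_csv(out_dir / "truth.csv", index=False)
    log.info("wrote %d image sets to %s", len(manifest), out_dir)
    return manifest, truth_table
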