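"""CSV tables: study manifest, per-cell measurements, group results."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "image_path",
    "roi_path",
    "donor",
    "sample",
    "condition",
    "phase",
    "replicate",
    "seed",
]

MEASUREMENT_COLUMNS = [
    "cell_id",
    "far_percent",
    "nuclear_actin_sum",
    "total_actin_sum",
    "n_nuclei",
    "cell_area",
    "nuclear_area",
    "actin_positive_area",
    "qc_flags",
]

GROUP_RESULT_COLUMNS = [
    "donor",
    "sample",
    "condition",
    "phase",
    "n_replicates",
    "replicate_means",
    "group_mean",
    "group_sd",
    "control_mean",
    "p_value",
    "p_value_adjusted",
    "adjusted",
    "significance",
    "significance_adjusted",
]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in MANIFEST_COLUMNS if c in manifest.columns]
    manifest.loc[:, cols].to_csv(path, index=False)


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load a study manifest, verifying referenced files and key uniqueness."""
    path = Path(path)
    manifest = pd.read_csv(path)
    missing = [c for c in ("image_path", "roi_path", "donor", "sample", "replicate") if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    key = manifest[["donor", "sample", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        dupes = key[key.duplicated()].tolist()
        raise ValueError(f"duplicate (donor, sample, replicate) rows in manifest: {dupes}")
    if check_files:
        base = path.parent
        for col in ("image_path", "roi_path"):
            for p in manifest[col]:
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = base / candidate
                if not candidate.exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    return manifest


def resolve_manifest_path(manifest_path: str | Path, entry: str) -> Path:
    p = Path(entry)
    return p if p.is_absolute() else Path(manifest_path).parent / p


def _write_table(frame: pd.DataFrame, path: str | Path, columns: list[str], what: str) -> None:
    if len(frame) == 0:
        raise ValueError(f"refusing to write an empty {what} table to {path}")
    cols = [c for c in columns if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame.loc[:, cols].to_csv(path, index=False)


def write_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    """Per-cell measurement CSV with a declared, stable column order."""
    _write_table(measurements, path, MEASUREMENT_COLUMNS, "measurement")


def read_measurements(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["qc_flags"] = frame["qc_flags"].fillna("")
    return frame


def write_group_results(results: pd.DataFrame, path: str | Path) -> None:
    _write_table(results, path, GROUP_RESULT_COLUMNS, "group-result")


def read_group_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
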