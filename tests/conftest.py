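import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import faractin as fa


def make_image(dapi, actin):
    """Two-channel image from explicit per-pixel arrays (test helper)."""
    return fa.MultiChannelImage(np.stack([np.asarray(dapi, float), np.asarray(actin, float)]))


def rect_roi(r0, c0, r1, c1, cell_id="cell"):
    """Rectangular ROI covering pixels [r0, r1) x [c0, c1)."""
    return fa.CellROI(cell_id, np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], float))


@pytest.fixture(scope="session")
def default_replicate():
    """One rendered field at rho = 0.25 with 10 cells, reused read-only."""
    return fa.simulate_replicate(rho=0.25, n_cells=10, seed=11)


@pytest.fixture(scope="session")
def tiny_study_design():
    """A miniature 2-donor study that renders in a few seconds."""
    samples = [
        fa.ExposureSample("PDP", "control", "pre"),
        fa.ExposureSample("P1A", "injurious", "pre"),
    ]
    effect = {
        ("D1", "PDP"): 0.15, ("D1", "P1A"): 0.40,
        ("D2", "PDP"): 0.15, ("D2", "P1A"): 0.15,
    }
    return fa.StudyDesign(
        donor_lines=["D1", "D2"],
        exposure_samples=samples,
        effect_map=effect,
        n_replicates=3,
        cells_per_replicate=4,
        image_shape=(300, 300),
    ).validate()


@pytest.fixture(scope="session")
def tiny_study(tiny_study_design, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_study")
    manifest, truth = fa.generate_study(tiny_study_design, out, seed=5)
    return out, manifest, truth
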