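#!/usr/bin/env python
"""Generate the synthetic crossmatch study.

Renders the default design — 5 donor podocyte lines x (1 pooled-donor-plasma
control + 4 patient samples) x 3 replicates, 30 annotated cells per
replicate — and writes images, ROI files, the manifest and the ground-truth
table under scratch/study/ (image data is bulky and regenerable, so it stays
out of results/).
"""

import argparse
from pathlib import Path

import faractin as fa

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "study")
    args = parser.parse_args()

    design = fa.default_study_design()
    manifest, truth = fa.generate_study(design, args.out, args.seed)
    n_groups = len(design.donor_lines) * len(design.exposure_samples)
    print(f"design: {len(design.donor_lines)} donors x "
          f"{len(design.exposure_samples)} samples x {design.n_replicates} replicates")
    print(f"wrote {len(manifest)} image sets ({len(truth)} cells, "
          f"{n_groups} donor x sample groups) to {args.out}")
    print("ground-truth nuclear actin fractions per group:")
    print(truth.groupby(["donor", "sample"])["rho"].first().unstack().to_string())


if __name__ == "__main__":
    main()
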