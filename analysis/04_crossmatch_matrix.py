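#!/usr/bin/env python
"""Assemble and render the donor x patient-sample crossmatch matrix.

Each grid cell holds the group-mean FAR% of one donor podocyte line under
one patient sample, with the significance of its comparison against that
donor's pooled-donor-plasma control.  Writes results/crossmatch_pre.png and
its CSV twin.
"""

import argparse
from pathlib import Path

import pandas as pd

import faractin as fa

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--group-results", type=Path,
                        default=ROOT / "results" / "group_results.csv")
    parser.add_argument("--phase", default="pre")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "crossmatch_pre.png")
    args = parser.parse_args()

    results = pd.read_csv(args.group_results)
    matrix = fa.build_matrix(results, phase=args.phase)
    fig_path, csv_path = fa.render_heatmap(matrix, args.out)
    print(f"{len(matrix.donors)} donors x {len(matrix.samples)} samples "
          f"({args.phase}-Tx phase)")
    print("mean FAR% with significance stars:")
    stars = matrix.pivot("significance")
    far = matrix.pivot("mean_far").round(1)
    print((far.astype(str) + " " + stars.fillna("")).to_string())
    print(f"wrote {fig_path} and {csv_path}")


if __name__ == "__main__":
    main()
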