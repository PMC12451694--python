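"""Donor-line x patient-sample crossmatch matrix with significance flags.

Every grid cell holds the group-mean FAR% of one donor podocyte line exposed
to one patient sample, with the p-value of its comparison against that
donor's pooled-donor-plasma control and the star code.  Missing
combinations are carried explicitly, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import significance_code

log = logging.getLogger(__name__)

MATRIX_COLUMNS = [
    "donor",
    "sample",
    "phase",
    "mean_far",
    "p_value",
    "significance",
    "n_replicates",
    "missing",
]


@dataclass
class CrossmatchMatrix:
    donors: list[str]
    samples: list[str]
    table: pd.DataFrame  # tidy, one row per donor x sample, MATRIX_COLUMNS
    control_reference: dict[str, float]  # donor -> control mean FAR
    phase: str

    def pivot(self, field: str) -> pd.DataFrame:
        return self.table.pivot(index="donor", columns="sample", values=field).reindex(
            index=self.donors, columns=self.samples
        )


def build_matrix(group_results: pd.DataFrame, phase: str) -> CrossmatchMatrix:
    """Assemble the crossmatch grid for one sampling phase.

    ``group_results`` is the output of :func:`faractin.stats.group_results`;
    ordering of donors and samples follows their first appearance there
    (i.e. the manifest's declared order).  A donor without a control
    comparison raises with the donor named; absent donor x sample pairs are
    marked ``missing``.
    """
    sub = group_results[group_results["phase"] == phase] if "phase" in group_results.columns else group_results
    if len(sub) == 0:
        raise ValueError(f"no group results for phase '{phase}'")
    donors = list(group_results["donor"].drop_duplicates())
    samples = list(sub["sample"].drop_duplicates())
    control_reference = {}
    for donor in donors:
        fam = group_results[group_results["donor"] == donor]
        if len(fam) == 0 or fam["control_mean"].isna().all():
            raise ValueError(f"donor {donor} has no control comparison")
        control_reference[donor] = float(fam["control_mean"].iloc[0])
    rows = []
    for donor in donors:
        for sample in samples:
            match = sub[(sub["donor"] == donor) & (sub["sample"] == sample)]
            if len(match) == 0:
                log.warning("crossmatch cell (%s, %s) is missing", donor, sample)
                rows.append({
                    "donor": donor, "sample": sample, "phase": phase,
                    "mean_far": np.nan, "p_value": np.nan, "significance": "",
                    "n_replicates": 0, "missing": True,
                })
            else:
                r = match.iloc[0]
                rows.append({
                    "donor": donor, "sample": sample, "phase": phase,
                    "mean_far": r["group_mean"], "p_value": r["p_value"],
                    "significance": significance_code(r["p_value"]),
                    "n_replicates": int(r["n_replicates"]), "missing": False,
                })
    table = pd.DataFrame(rows, columns=MATRIX_COLUMNS)
    return CrossmatchMatrix(donors, samples, table, control_reference, phase)


def render_heatmap(matrix: CrossmatchMatrix, path: str | Path, cmap: str = "viridis"):
    """Render the matrix as a heatmap and write its CSV twin.

    The figure colors cells by mean FAR% and overlays the star code of each
    significance call; the CSV twin (same stem, ``.csv``) carries every
    plotted number so no value exists only in the figure.  Returns
    ``(figure_path, csv_path)``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    csv_path = path.with_suffix(".csv")
    matrix.table.to_csv(csv_path, index=False)

    values = matrix.pivot("mean_far").to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.9 * len(matrix.samples), 1.0 + 0.7 * len(matrix.donors))
    )
    im = ax.imshow(values, cmap=cmap, aspect="auto")
    ax.set_xticks(range(len(matrix.samples)), matrix.samples)
    ax.set_yticks(range(len(matrix.donors)), matrix.donors)
    ax.set_xlabel(f"patient sample ({matrix.phase}-Tx)")
    ax.set_ylabel("donor podocyte line")
    for i, donor in enumerate(matrix.donors):
        for j, sample in enumerate(matrix.samples):
            row = matrix.table[
                (matrix.table["donor"] == donor) & (matrix.table["sample"] == sample)
            ].iloc[0]
            if row["missing"]:
                text = "n/a"
            else:
                stars = row["significance"]
                text = f"{row['mean_far']:.1f}" + (f"\n{stars}" if stars != "ns" else "")
            ax.text(j, i, text, ha="center", va="center", fontsize=8,
                    color="white" if not row["missing"] else "gray")
    fig.colorbar(im, ax=ax, label="mean FAR (%)")
    fig.suptitle("FAR crossmatch vs. pooled donor control", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, csv_path
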