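"""Replicate-level statistics for the FAR assay.

The experimental unit is the independent replicate (N = 3 by default), not
the pooled cell: per-cell FAR values are first averaged within each
donor x sample x replicate, and group comparisons run on those replicate
means.  Pooling cells across replicates would treat pseudo-replicates as
independent and inflate significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


@dataclass
class AgreementSummary:
    """Inter-observer agreement over paired per-cell measurements."""

    n_cells_paired: int
    mean_rel_diff: float  # % of the pairwise-mean FAR
    sd_rel_diff: float
    corr_with_mean: float  # correlation of rel. diff with effect size


def aggregate_replicates(cells: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-cell FAR to one summary row per donor x sample x replicate.

    Flagged cells (non-empty ``qc_flags``) are excluded and counted in the
    log; replicates left with zero usable cells are dropped with a warning.
    """
    required = {"donor", "sample", "replicate", "far_percent", "qc_flags"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table is missing columns: {sorted(missing)}")
    flags = cells["qc_flags"].fillna("").astype(str)
    usable = cells[(flags == "") & cells["far_percent"].notna()]
    n_excluded = len(cells) - len(usable)
    if n_excluded:
        log.info("excluded %d flagged cells from aggregation", n_excluded)
    keys = ["donor", "sample", "replicate"]
    carry = [c for c in ("condition", "phase") if c in cells.columns]
    grouped = usable.groupby(keys, sort=False)
    summary = grouped.agg(
        n_cells=("far_percent", "size"),
        mean_far=("far_percent", "mean"),
        sd_far=("far_percent", lambda s: s.std(ddof=1)),
        **{c: (c, "first") for c in carry},
    ).reset_index()
    expected = cells[keys].drop_duplicates()
    dropped = len(expected) - len(summary)
    if dropped:
        log.warning("%d replicate(s) had zero usable cells and were dropped", dropped)
    return summary


def compare_to_control(
    group: np.ndarray, control: np.ndarray, variant: str = "student"
) -> float:
    """Two-sided p-value of the unpaired t-test on replicate means.

    ``variant="student"`` is the classic equal-variance form; ``"welch"``
    drops the equal-variance assumption.  Degenerate inputs with zero pooled
    variance give p = 1 when the means are equal and raise otherwise.
    """
    group = np.asarray(group, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(group) < 2 or len(control) < 2:
        raise ValueError("need at least 2 replicate means on each side")
    if np.var(group, ddof=1) == 0 and np.var(control, ddof=1) == 0:
        if group.mean() == control.mean():
            return 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = sps.ttest_ind(group, control, equal_var=(variant == "student"))
    return float(res.pvalue)


def dunnett_many_to_one(
    groups: list[np.ndarray],
    control: np.ndarray,
    seed: int | None = None,
    variant: str = "student",
) -> np.ndarray:
    """Dunnett-adjusted two-sided p-values for many-to-one comparisons.

    All comparisons share the pooled one-way-ANOVA error; adjustment is by
    the multivariate t distribution of the max-|t| statistic (randomized-QMC
    evaluation, seeded).  With a single treatment group the procedure
    reduces exactly to the pairwise t-test.  Each adjusted p is floored at
    its single-comparison pooled-error p — a provable lower bound that also
    absorbs the QMC estimator's small Monte-Carlo error, keeping the
    monotonicity guarantee adjusted >= unadjusted exact.
    """
    if not groups:
        raise ValueError("need at least one treatment group")
    control = np.asarray(control, dtype=float)
    if len(groups) == 1:
        return np.array([compare_to_control(groups[0], control, variant)])
    rng = np.random.default_rng(seed)
    res = sps.dunnett(*[np.asarray(g, float) for g in groups], control=control,
                      alternative="two-sided", random_state=rng)
    adjusted = np.asarray(res.pvalue, dtype=float)
    df = sum(len(g) for g in groups) + len(control) - len(groups) - 1
    marginal = 2.0 * sps.t.sf(np.abs(res.statistic), df)
    return np.clip(np.maximum(adjusted, marginal), 0.0, 1.0)


def significance_code(p: float) -> str:
    """Map a p-value to the star code (boundary-inclusive: p = .05 -> '*')."""
    if not 0.0 <= p <= 1.0 or np.isnan(p):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for level, stars in SIGNIFICANCE_LEVELS:
        if p <= level:
            return stars
    return "ns"


def group_results(
    replicates: pd.DataFrame,
    variant: str = "student",
    dunnett: str = "auto",
    seed: int | None = None,
) -> pd.DataFrame:
    """Compare every donor x sample group against that donor's control.

    Within each donor family the control is the sample with
    ``condition == "control"``.  The pairwise t-test p-value is always
    reported; when a family has two or more treatment samples and
    ``dunnett != "never"``, Dunnett-adjusted p-values sharing the pooled
    ANOVA error are reported alongside.  Significance stars are coded from
    the pairwise p (the assay's primary read-out); the adjusted stars are a
    separate column.
    """
    rows = []
    for donor in replicates["donor"].drop_duplicates():
        fam = replicates[replicates["donor"] == donor]
        ctrl = fam[fam["condition"] == "control"] if "condition" in fam.columns else fam.iloc[0:0]
        if len(ctrl) == 0:
            raise ValueError(f"donor {donor} has no control group")
        control_means = ctrl["mean_far"].to_numpy()
        treatments = [s for s in fam["sample"].drop_duplicates() if s not in set(ctrl["sample"])]
        group_means = {
            s: fam.loc[fam["sample"] == s, "mean_far"].to_numpy() for s in treatments
        }
        adjusted: dict[str, float] = {}
        if dunnett != "never" and len(treatments) >= 2:
            adj = dunnett_many_to_one(
                [group_means[s] for s in treatments], control_means, seed=seed,
                variant=variant,
            )
            adjusted = dict(zip(treatments, adj))
        for s in treatments:
            means = group_means[s]
            sub = fam[fam["sample"] == s]
            p = compare_to_control(means, control_means, variant)
            p_adj = adjusted.get(s, np.nan)
            rows.append({
                "donor": donor,
                "sample": s,
                "condition": sub["condition"].iloc[0] if "condition" in sub.columns else "",
                "phase": sub["phase"].iloc[0] if "phase" in sub.columns else "",
                "n_replicates": len(means),
                "replicate_means": ";".join(f"{m:.6g}" for m in means),
                "group_mean": float(means.mean()),
                "group_sd": float(means.std(ddof=1)) if len(means) > 1 else np.nan,
                "control_mean": float(control_means.mean()),
                "p_value": p,
                "p_value_adjusted": p_adj,
                "adjusted": bool(adjusted),
                "significance": significance_code(p),
                "significance_adjusted": (
                    significance_code(p_adj) if not np.isnan(p_adj) else ""
                ),
            })
    return pd.DataFrame(rows)


def interobserver_agreement(
    meas_a: pd.DataFrame, meas_b: pd.DataFrame
) -> AgreementSummary:
    """Agreement between two examiners' measurements of the same cells.

    Cells are paired by ``cell_id`` (and image when present); only pairs
    unflagged on both sides enter.  The per-cell relative difference is
    (FAR_A - FAR_B) / mean(FAR_A, FAR_B) * 100 (Bland-Altman style);
    the summary is its mean +/- SD, plus the correlation of the relative
    difference with the pairwise-mean FAR — near zero when the agreement is
    independent of effect size (reported, not enforced).
    """
    keys = ["cell_id"] + [
        c for c in ("image_path",) if c in meas_a.columns and c in meas_b.columns
    ]

    def usable(df):
        flags = df["qc_flags"].fillna("").astype(str) if "qc_flags" in df.columns else ""
        out = df[(flags == "") & df["far_percent"].notna()] if "qc_flags" in df.columns else df
        return out[keys + ["far_percent"]]

    merged = usable(meas_a).merge(usable(meas_b), on=keys, suffixes=("_a", "_b"))
    pair_mean = (merged["far_percent_a"] + merged["far_percent_b"]) / 2.0
    merged = merged[pair_mean > 0]
    pair_mean = pair_mean[pair_mean > 0]
    if len(merged) == 0:
        raise ValueError("no usable paired cells for agreement analysis")
    rel = (merged["far_percent_a"] - merged["far_percent_b"]) / pair_mean * 100.0
    if len(merged) > 2 and rel.std(ddof=1) > 0 and pair_mean.std(ddof=1) > 0:
        corr = float(np.corrcoef(rel, pair_mean)[0, 1])
    else:
        corr = float("nan")
    return AgreementSummary(
        n_cells_paired=len(merged),
        mean_rel_diff=float(rel.mean()),
        sd_rel_diff=float(rel.std(ddof=1)) if len(rel) > 1 else 0.0,
        corr_with_mean=corr,
    )
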