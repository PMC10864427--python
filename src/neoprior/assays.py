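"""Assay-level summary statistics for T-cell activation and killing readouts.

Covers the cytotoxicity formula
``% lysis = 100 - (OD of co-culture / OD of target cells alone) x 100``,
mean +/- SEM replicate summaries, and group comparisons (two-sided
Student's t test for two groups, one-way ANOVA with Tukey HSD post hoc
for more) at alpha = 0.05, the conventions of ELISpot, flow-cytometry
frequency and MTS killing analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AssayRangeWarning(UserWarning):
    """A computed percentage fell outside [0, 100]."""


def percent_lysis(od_cocult: float, od_target: float) -> float:
    """Percent cancer-cell lysis from MTS OD490 readings.

    ``100 - (OD_coculture / OD_target) x 100``.  Values below 0 (target
    wells outgrown by the co-culture) or above 100 are returned as-is and
    flagged with :class:`AssayRangeWarning`; clipping would hide assay
    problems.
    """
    if od_target <= 0:
        raise ValueError("target-alone OD must be positive")
    if od_cocult < 0:
        raise ValueError("co-culture OD must be non-negative")
    value = 100.0 - (od_cocult / od_target) * 100.0
    if not 0.0 <= value <= 100.0:
        warnings.warn(
            f"percent lysis {value:.2f} outside [0, 100]", AssayRangeWarning,
            stacklevel=2,
        )
    return value


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sem: float  # NaN when undefined (single replicate)
    n: int

    @property
    def sem_defined(self) -> bool:
        return not math.isnan(self.sem)


def summarize(replicates: Sequence[float]) -> ReplicateSummary:
    """Mean and standard error of the mean (sample SD / sqrt(n)).

    A single replicate yields its value with SEM flagged undefined (NaN).
    """
    x = np.asarray(replicates, dtype=float)
    if x.size == 0:
        raise ValueError("no replicates")
    if x.size == 1:
        return ReplicateSummary(mean=float(x[0]), sem=float("nan"), n=1)
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size))
    return ReplicateSummary(mean=float(x.mean()), sem=sem, n=int(x.size))


@dataclass
class GroupComparison:
    """Result of a two-group t test or a one-way ANOVA with Tukey HSD."""

    method: str  # "t-test" or "anova-tukey"
    statistic: float  # t for two groups, F otherwise
    pvalue: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj, significant


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare >= 2 replicate groups.

    Two groups: pooled-variance two-sided Student's t test.  More than
    two: one-way ANOVA F test with Tukey HSD (Tukey-Kramer for unbalanced
    designs) pairwise adjustment.  ``pairwise`` flags each pair at the
    given alpha.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two replicates")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("one label per group required")

    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": labels[0],
                    "group_b": labels[1],
                    "p_adj": float(p),
                    "significant": bool(p < alpha),
                }
            ]
        )
        return GroupComparison("t-test", float(t), float(p), pairwise)

    f, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        p_adj = float(tukey.pvalue[i, j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    return GroupComparison("anova-tukey", float(f), float(p), pd.DataFrame(rows))


PLATE_COLUMNS = ["donor", "condition", "et_ratio", "replicate", "value"]


def read_plate(path: str) -> pd.DataFrame:
    """Read a long-form plate TSV (donor, condition, et_ratio, replicate, value)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table {path} lacks columns {sorted(missing)}")
    if (df["value"] < 0).any():
        raise ValueError("plate readings must be non-negative")
    return df


def summarize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per (donor, condition, E:T) mean/SEM/n across replicates."""
    rows = []
    for (donor, cond, ratio), grp in plate.groupby(
        ["donor", "condition", "et_ratio"], sort=True
    ):
        s = summarize(grp["value"].to_numpy())
        rows.append(
            {
                "donor": donor,
                "condition": cond,
                "et_ratio": ratio,
                "mean": s.mean,
                "sem": s.sem,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows, columns=["donor", "condition", "et_ratio", "mean", "sem", "n"])


def lysis_from_plate(plate: pd.DataFrame, target_condition: str = "TA") -> pd.DataFrame:
    """Convert OD readings to percent lysis against the target-alone wells.

    The target-alone OD is averaged per (donor, E:T is ignored for the
    target wells); each co-culture replicate is converted individually.
    """
    out_rows = []
    for donor, grp in plate.groupby("donor", sort=True):
        target = grp[grp["condition"] == target_condition]
        if target.empty:
            raise ValueError(
                f"donor {donor}: no {target_condition!r} (target-alone) wells"
            )
        od_target = float(target["value"].mean())
        for row in grp[grp["condition"] != target_condition].itertuples():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", AssayRangeWarning)
                value = percent_lysis(float(row.value), od_target)
            out_rows.append(
                {
                    "donor": donor,
                    "condition": row.condition,
                    "et_ratio": row.et_ratio,
                    "replicate": row.replicate,
                    "percent_lysis": value,
                }
            )
    return pd.DataFrame(
        out_rows,
        columns=["donor", "condition", "et_ratio", "replicate", "percent_lysis"],
    )
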