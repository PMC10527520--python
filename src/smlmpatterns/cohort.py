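"""Cross-condition aggregation of per-cell nanoscale statistics.

Per-cell readouts (self-clustering g(20 nm), EOM at 20 and 200 nm and
their segregation companions) are aggregated per condition (cell line) as
mean ± SEM, compared against a reference (off-target) condition with a
two-sided test, and combined with per-condition scalar effector readouts
(ligand-positive fraction, Ca++ influx, killing extent) into a normalized
parameter matrix with its Pearson correlation structure.

Normalization divides each parameter column by its maximum across cell
lines, so each column's best line scores 1. Excess killing is killing
extent minus that of the reference line (0 for the reference itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CellSummary",
    "ParameterMatrix",
    "aggregate_condition",
    "excess_killing",
    "normalize_and_correlate",
    "significance_stars",
]

METRICS = (
    "self_clustering",
    "eom_20",
    "eom_200",
    "segregation_20",
    "segregation_200",
)


@dataclass(frozen=True)
class CellSummary:
    """Nanoscale readouts for one cell (averaged over its ROIs)."""

    condition: str
    self_clustering: float  # univariate g at 20 nm, channel 1
    eom_20: float
    eom_200: float
    n_rois: int = 1

    @property
    def segregation_20(self) -> float:
        return 1.0 - self.eom_20

    @property
    def segregation_200(self) -> float:
        return 1.0 - self.eom_200

    def as_row(self) -> dict:
        return {
            "condition": self.condition,
            "self_clustering": self.self_clustering,
            "eom_20": self.eom_20,
            "eom_200": self.eom_200,
            "segregation_20": self.segregation_20,
            "segregation_200": self.segregation_200,
            "n_rois": self.n_rois,
        }


def summaries_frame(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def significance_stars(p: float) -> str:
    """Conventional per-comparison stars: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def aggregate_condition(
    summaries: Sequence[CellSummary],
    reference_condition: str,
    test: Literal["mannwhitney", "welch"] = "mannwhitney",
    adjust: Literal["none", "fdr_bh"] = "none",
) -> pd.DataFrame:
    """Per-condition mean ± SEM for each metric, with tests vs reference.

    Each condition's per-cell values are compared against the reference
    (off-target) condition with a two-sided test; p-values are reported
    per comparison (no multiplicity adjustment by default, selectable
    Benjamini-Hochberg). Single-cell conditions get SEM = NaN and are
    flagged.
    """
    df = summaries_frame(summaries)
    if reference_condition not in set(df["condition"]):
        raise ValueError(f"unknown reference condition {reference_condition!r}")
    ref = df[df["condition"] == reference_condition]

    rows = []
    for cond, grp in df.groupby("condition", sort=False):
        row: dict = {"condition": cond, "n_cells": len(grp)}
        for m in METRICS:
            vals = grp[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) >= 2 else np.nan
            )
            if cond == reference_condition:
                row[f"{m}_p"] = np.nan
            else:
                row[f"{m}_p"] = _two_sample_p(vals, ref[m].to_numpy(dtype=float), test)
        row["flag_single_cell"] = len(grp) < 2
        rows.append(row)
    out = pd.DataFrame(rows)

    p_cols = [f"{m}_p" for m in METRICS]
    if adjust == "fdr_bh":
        flat = out[p_cols].to_numpy().ravel()
        mask = np.isfinite(flat)
        adj = flat.copy()
        if mask.any():
            adj[mask] = multipletests(flat[mask], method="fdr_bh")[1]
        out[p_cols] = adj.reshape(out[p_cols].shape)
    for m in METRICS:
        out[f"{m}_stars"] = [
            significance_stars(p) if np.isfinite(p) else ""
            for p in out[f"{m}_p"]
        ]
    return out


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


def excess_killing(
    killing_by_line: Mapping[str, float], reference: str
) -> dict[str, float]:
    """Killing extent of each line minus the reference (off-target) line."""
    if reference not in killing_by_line:
        raise ValueError(f"reference {reference!r} not among killing values")
    ref_val = killing_by_line[reference]
    return {line: v - ref_val for line, v in killing_by_line.items()}


@dataclass
class ParameterMatrix:
    """Max-normalized per-cell-line parameters and their correlations.

    ``normalized`` has cell lines as rows; every column is divided by its
    maximum across lines (so column maxima are 1). ``correlations`` is the
    Pearson matrix over lines for every pair of parameter columns.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    correlations: pd.DataFrame

    def lower_triangle(self) -> pd.DataFrame:
        """Correlations in reporting layout: strictly lower triangle."""
        c = self.correlations.copy()
        mask = np.triu(np.ones(c.shape, dtype=bool))
        return c.mask(mask)


def normalize_and_correlate(raw: pd.DataFrame) -> ParameterMatrix:
    """Normalize parameter columns to max 1 and compute Pearson r pairs.

    ``raw``: one row per cell line, numeric parameter columns (e.g.
    ligand, segregation_20, segregation_200, self_clustering, ca_influx,
    excess_killing). Requires >= 3 rows for a meaningful correlation.
    A zero column maximum is an error naming the column.
    """
    if len(raw) < 3:
        raise ValueError("need >= 3 cell lines for a meaningful correlation")
    num = raw.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need >= 2 numeric parameter columns")
    maxima = num.max(axis=0)
    for col, m in maxima.items():
        if m == 0:
            raise ValueError(f"column {col!r} has zero maximum; cannot normalize")
    normalized = num / maxima
    corr = pd.DataFrame(
        np.corrcoef(num.to_numpy(dtype=float), rowvar=False),
        index=num.columns,
        columns=num.columns,
    )
    out_norm = raw.copy()
    out_norm[num.columns] = normalized
    return ParameterMatrix(raw=raw, normalized=out_norm, correlations=corr)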