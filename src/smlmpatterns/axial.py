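"""Axial (z) separation of two channels at a cell-cell interface.

3D SMLM of receptor/phosphatase pairs at tight contacts asks whether one
species sits systematically higher than the other along the optical axis.
This module summarizes per-channel z distributions and tests the offset
with a two-sided two-sample test on per-molecule z values (merged
molecules, not raw localizations, to avoid blinking pseudo-replication).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .locio import ROI, LocalizationTable, crop_roi

__all__ = ["AxialSummary", "height_separation"]


@dataclass
class AxialSummary:
    """Per-channel axial statistics and their two-sample comparison.

    ``delta_z`` = mean z(channel 1) - mean z(channel 2), in nm; a positive
    value means channel 1 sits higher. SEM of the difference combines the
    two per-channel standard errors in quadrature.
    """

    n1: int
    n2: int
    mean_z1: float
    mean_z2: float
    sd_z1: float
    sd_z2: float
    p_value: float
    test: str

    @property
    def delta_z(self) -> float:
        return self.mean_z1 - self.mean_z2

    @property
    def sem_delta_z(self) -> float:
        return float(np.hypot(self.sd_z1 / np.sqrt(self.n1), self.sd_z2 / np.sqrt(self.n2)))


def height_separation(
    table: LocalizationTable,
    roi: ROI | None = None,
    test: Literal["mannwhitney", "welch"] = "mannwhitney",
) -> AxialSummary:
    """Axial separation between channel 1 and channel 2 inside an ROI.

    The default Mann-Whitney U test is robust to the non-Gaussian z
    profiles typical of SMLM; a Welch t-test is selectable. Requires at
    least 2 molecules with z per channel.
    """
    if not table.has_z:
        raise ValueError(
            "table has no z column; use the 2D pipeline for this dataset"
        )
    if roi is not None:
        table = crop_roi(table, roi)
    if "channel" not in table.data.columns:
        raise ValueError("table has no channel column")
    z1 = table.select_channel(1).data["z"].to_numpy(dtype=float)
    z2 = table.select_channel(2).data["z"].to_numpy(dtype=float)
    z1, z2 = z1[np.isfinite(z1)], z2[np.isfinite(z2)]
    if len(z1) < 2 or len(z2) < 2:
        raise ValueError(
            f"need >= 2 molecules with z per channel (got {len(z1)}, {len(z2)})"
        )
    if test == "mannwhitney":
        p = float(stats.mannwhitneyu(z1, z2, alternative="two-sided").pvalue)
    elif test == "welch":
        p = float(stats.ttest_ind(z1, z2, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return AxialSummary(
        n1=len(z1),
        n2=len(z2),
        mean_z1=float(z1.mean()),
        mean_z2=float(z2.mean()),
        sd_z1=float(z1.std(ddof=1)),
        sd_z2=float(z2.std(ddof=1)),
        p_value=p,
        test=test,
    )
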