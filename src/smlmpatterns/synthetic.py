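"""Synthetic two-color localization data with known ground truth.

Stand-in for raw two-color SMLM imaging of receptor pairs at cell-cell
interfaces: generates homogeneous Poisson (CSR) or Thomas (clustered)
point patterns in a rectangular window, couples two channels under the
reference models the downstream statistics are anchored on (independence,
random labelling, co-clustering, displaced/segregated clusters), and
emulates fluorophore blinking so that the over-counting correction can be
tested against known molecule counts.

Thomas process: Poisson-distributed parents, each with a Poisson number
of offspring scattered isotropically Gaussian around the parent. Children
falling outside the window are wrapped toroidally by default, consistent
with the toroidal edge correction of the estimators.

All simulations are driven by an explicit numpy Generator or seed; a
fixed seed reproduces output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .locio import ROI, LocalizationTable

__all__ = [
    "SyntheticConfig",
    "ThomasParams",
    "BlinkingParams",
    "TwoColorSample",
    "simulate_csr",
    "simulate_thomas",
    "simulate_two_color",
    "emulate_blinking",
]

NM2_PER_UM2 = 1e6

#: Default localization precision (nm); keeps simulated data at the ~20 nm
#: effective resolution of dSTORM.
DEFAULT_LOCALIZATION_SIGMA = 15.0

CouplingMode = Literal["independent", "random_label", "co_clustered", "segregated"]


@dataclass(frozen=True)
class ThomasParams:
    """Thomas (Neyman-Scott) cluster process parameters.

    parent_intensity: parents per µm²; mean_offspring: mean children per
    parent; cluster_sigma: isotropic Gaussian scatter of children (nm).
    """

    parent_intensity: float = 5.0
    mean_offspring: float = 10.0
    cluster_sigma: float = 30.0

    def __post_init__(self) -> None:
        if self.parent_intensity <= 0 or self.mean_offspring <= 0 or self.cluster_sigma <= 0:
            raise ValueError("Thomas parameters must be positive")


@dataclass(frozen=True)
class BlinkingParams:
    """Fluorophore blinking / over-counting model.

    Each molecule emits a geometric (memoryless, support >= 1) number of
    localizations with the given mean, at consecutive frames separated by
    geometric dark gaps of mean ``gap_frames_mean``; every localization is
    jittered by an isotropic Gaussian of ``localization_sigma`` nm.
    """

    mean_emissions: float = 4.0
    gap_frames_mean: float = 0.0
    localization_sigma: float = DEFAULT_LOCALIZATION_SIGMA
    n_frames: int = 2000
    frame_rate: float = 13.4

    def __post_init__(self) -> None:
        if self.mean_emissions < 1:
            raise ValueError("mean_emissions must be >= 1")
        if self.gap_frames_mean < 0 or self.localization_sigma < 0:
            raise ValueError("gap and sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic two-color sample."""

    window: ROI = field(default_factory=lambda: ROI(0, 4000, 0, 4000))
    process: Literal["csr", "thomas"] = "thomas"
    intensity: float = 100.0  # points per µm² (CSR)
    thomas: ThomasParams = field(default_factory=ThomasParams)
    coupling: CouplingMode = "independent"
    label_p: float = 0.5  # P(channel 1) under random labelling
    displacement: float = 0.0  # nm, channel-2 parent shift when segregated
    blinking: BlinkingParams = field(default_factory=BlinkingParams)
    z_mean: tuple[float, float] | None = None  # per-channel mean z (nm)
    z_sd: float = 20.0
    boundary: Literal["wrap", "truncate"] = "wrap"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window.area <= 0:
            raise ValueError("window must have positive area")
        if not (0 < self.label_p < 1):
            raise ValueError("label_p must be in (0, 1)")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.displacement < 0:
            raise ValueError("displacement must be non-negative")


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _wrap(points: np.ndarray, window: ROI) -> np.ndarray:
    lo = np.array([window.x_min, window.y_min])
    box = np.array([window.width, window.height])
    return lo + np.mod(points - lo, box)


def simulate_csr(
    config: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Homogeneous Poisson pattern: Poisson count, uniform positions (nm)."""
    rng = _rng(rng if rng is not None else config.seed)
    w = config.window
    mean_count = config.intensity * w.area / NM2_PER_UM2
    n = rng.poisson(mean_count)
    x = rng.uniform(w.x_min, w.x_max, n)
    y = rng.uniform(w.y_min, w.y_max, n)
    return np.column_stack([x, y])


def simulate_thomas(
    config: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    parents: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thomas cluster pattern.

    Returns (points, parent_index per point, parent positions). Passing
    ``parents`` reuses an existing parent set (for co-clustered channels).
    """
    rng = _rng(rng if rng is not None else config.seed)
    w = config.window
    p = config.thomas
    if parents is None:
        n_parents = rng.poisson(p.parent_intensity * w.area / NM2_PER_UM2)
        parents = np.column_stack(
            [
                rng.uniform(w.x_min, w.x_max, n_parents),
                rng.uniform(w.y_min, w.y_max, n_parents),
            ]
        )
    counts = rng.poisson(p.mean_offspring, len(parents))
    parent_idx = np.repeat(np.arange(len(parents)), counts)
    offsets = rng.normal(0.0, p.cluster_sigma, size=(counts.sum(), 2))
    pts = parents[parent_idx] + offsets
    if config.boundary == "wrap":
        pts = _wrap(pts, w)
    else:
        keep = w.contains(pts[:, 0], pts[:, 1])
        pts, parent_idx = pts[keep], parent_idx[keep]
    return pts, parent_idx, parents


@dataclass
class TwoColorSample:
    """Ground truth for one simulated two-color pattern."""

    points1: np.ndarray
    points2: np.ndarray
    config: SyntheticConfig
    parents1: np.ndarray | None = None
    parents2: np.ndarray | None = None
    parent_idx1: np.ndarray | None = None
    parent_idx2: np.ndarray | None = None

    @property
    def points12(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points1, self.points2

    @property
    def n1(self) -> int:
        return len(self.points1)

    @property
    def n2(self) -> int:
        return len(self.points2)

    def ground_truth_frame(self) -> pd.DataFrame:
        """Sidecar table: molecule id, channel, position, parent id."""
        rows = []
        for ch, pts, pidx in ((1, self.points1, self.parent_idx1), (2, self.points2, self.parent_idx2)):
            df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
            df.insert(0, "channel", ch)
            df.insert(0, "molecule", np.arange(len(pts)))
            df["parent"] = pidx if pidx is not None else -1
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _single_pattern(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if config.process == "csr":
        return simulate_csr(config, rng), None, None
    pts, pidx, parents = simulate_thomas(config, rng)
    return pts, pidx, parents


def simulate_two_color(
    config: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> TwoColorSample:
    """Two coupled channels under one of the reference models.

    independent
        Two separate draws of the process — the "no interaction" model
        (EOM anchor 0).
    random_label
        One draw; each point assigned channel 1 with probability
        ``label_p`` — the random-labelling model (EOM anchor 1).
    co_clustered
        Thomas channels sharing one parent set (each channel draws its
        own offspring).
    segregated
        Like co_clustered but channel-2 parents displaced by
        ``displacement`` nm in a random direction per parent;
        displacement 0 coincides with co_clustered.
    """
    rng = _rng(rng if rng is not None else config.seed)
    mode = config.coupling
    if mode == "independent":
        p1, i1, par1 = _single_pattern(config, rng)
        p2, i2, par2 = _single_pattern(config, rng)
        return TwoColorSample(p1, p2, config, par1, par2, i1, i2)
    if mode == "random_label":
        pts, pidx, parents = _single_pattern(config, rng)
        to_ch1 = rng.random(len(pts)) < config.label_p
        return TwoColorSample(
            pts[to_ch1],
            pts[~to_ch1],
            config,
            parents,
            parents,
            pidx[to_ch1] if pidx is not None else None,
            pidx[~to_ch1] if pidx is not None else None,
        )
    if mode in ("co_clustered", "segregated"):
        if config.process != "thomas":
            raise ValueError(f"{mode} coupling requires the Thomas process")
        p1, i1, parents = simulate_thomas(config, rng)
        if mode == "segregated" and config.displacement > 0:
            theta = rng.uniform(0, 2 * np.pi, len(parents))
            shift = config.displacement * np.column_stack([np.cos(theta), np.sin(theta)])
            parents2 = _wrap(parents + shift, config.window)
        else:
            parents2 = parents
        p2, i2, _ = simulate_thomas(config, rng, parents=parents2)
        return TwoColorSample(p1, p2, config, parents, parents2, i1, i2)
    raise ValueError(f"unknown coupling mode {mode!r}")


def emulate_blinking(
    molecules: np.ndarray,
    config: SyntheticConfig | None = None,
    blinking: BlinkingParams | None = None,
    channel: int | None = None,
    z: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> LocalizationTable:
    """Expand molecule positions into a blinking localization table.

    Each molecule emits geometric(mean ``mean_emissions``) localizations:
    the first at a frame uniform over the movie, later ones after
    geometric dark gaps; all jittered by Gaussian(localization_sigma).
    With ``mean_emissions = 1`` and zero sigma the output reproduces the
    input positions exactly. Records are sorted by frame.
    """
    if blinking is None:
        blinking = config.blinking if config is not None else BlinkingParams()
    rng = _rng(rng if rng is not None else (config.seed if config is not None else None))
    mols = np.asarray(molecules, dtype=float)
    n = len(mols)
    n_emissions = rng.geometric(1.0 / blinking.mean_emissions, n)

    mol_idx = np.repeat(np.arange(n), n_emissions)
    start = rng.integers(0, blinking.n_frames, n)
    # per-emission dark gap before it (0 for the first emission)
    if blinking.gap_frames_mean > 0:
        gaps = rng.geometric(
            1.0 / (1.0 + blinking.gap_frames_mean), size=len(mol_idx)
        )  # support >= 1: consecutive frames when no dark gap
    else:
        gaps = np.ones(len(mol_idx), dtype=np.int64)
    first = np.r_[True, np.diff(mol_idx) != 0]
    gaps[first] = 0
    frames = start[mol_idx] + _segmented_cumsum(gaps, mol_idx)

    jitter = rng.normal(0.0, blinking.localization_sigma, size=(len(mol_idx), 2))
    xy = mols[mol_idx, :2] + jitter

    data = {"frame": frames.astype(np.int64), "x": xy[:, 0], "y": xy[:, 1]}
    if z is not None:
        zj = rng.normal(0.0, blinking.localization_sigma, size=len(mol_idx))
        data["z"] = np.asarray(z, dtype=float)[mol_idx] + zj
    if channel is not None:
        data["channel"] = np.full(len(mol_idx), channel, dtype=np.int64)
    data["molecule_id"] = mol_idx  # ground-truth sidecar column
    df = pd.DataFrame(data).sort_values("frame", kind="stable").reset_index(drop=True)
    window = config.window if config is not None else None
    return LocalizationTable(df, frame_rate=blinking.frame_rate, window=window)


def _segmented_cumsum(values: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each new segment id."""
    out = np.cumsum(values)
    first = np.r_[True, np.diff(segments) != 0]
    offsets = np.zeros_like(out)
    starts = np.flatnonzero(first)
    offsets[starts] = out[starts] - values[starts]
    np.maximum.accumulate(offsets, out=offsets)
    return out - offsets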