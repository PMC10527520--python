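"""Localization-table I/O and preprocessing for SMLM point-pattern analysis.

A *localization* is one detected blinking event of a fluorophore, with a
fitted sub-pixel position. Because a single molecule blinks several times,
localization tables over-count molecules; :func:`merge_localizations` links
events close in space and time into single molecule records. ROI cropping
and live-sequence frame accumulation round out the preprocessing stage.

All coordinates are in nanometres throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "ROI",
    "LocalizationTable",
    "Dialect",
    "THUNDERSTORM_DIALECT",
    "read_localizations",
    "write_localizations",
    "crop_roi",
    "merge_localizations",
    "accumulate_live_frames",
    "FormatError",
]

#: Default acquisition frame rate for fixed-cell dSTORM movies (frames/s).
DEFAULT_FRAME_RATE = 13.4
#: Camera pixel size at the sample (nm); localization coordinates are already
#: in nm, this is retained as table metadata only.
DEFAULT_PIXEL_SIZE = 160.0


class FormatError(ValueError):
    """Raised when a localization file does not match the declared dialect."""


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest, half-open ``[min, max)`` in nm."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate ROI: ({self.x_min}, {self.x_max}) x "
                f"({self.y_min}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min)
            & (x < self.x_max)
            & (y >= self.y_min)
            & (y < self.y_max)
        )


# Canonical internal column names. Optional quality columns are carried
# through verbatim when present.
_CORE_COLUMNS = ("frame", "x", "y")
_OPTIONAL_COLUMNS = ("z", "channel", "intensity", "sigma", "uncertainty")


@dataclass
class LocalizationTable:
    """Per-emitter records plus acquisition metadata.

    ``data`` holds one row per localization with at least columns
    ``frame`` (non-negative int), ``x``, ``y`` (nm) and optionally ``z``
    (nm), ``channel`` (1 or 2), ``intensity`` (photons), ``sigma`` and
    ``uncertainty`` (nm).
    """

    data: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE
    pixel_size: float = DEFAULT_PIXEL_SIZE
    window: ROI | None = None

    def __post_init__(self) -> None:
        for col in _CORE_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"missing mandatory column: {col!r}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise FormatError(f"non-finite coordinate at row {bad}")
        if "channel" in self.data.columns and len(self.data):
            ch = self.data["channel"].to_numpy()
            if not np.isin(ch, (1, 2)).all():
                raise FormatError("channel values must be 1 or 2")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_z(self) -> bool:
        return "z" in self.data.columns

    @property
    def channels(self) -> tuple[int, ...]:
        if "channel" not in self.data.columns:
            return ()
        return tuple(sorted(int(c) for c in self.data["channel"].unique()))

    def positions(self, channel: int | None = None) -> np.ndarray:
        """(n, 2) array of x, y in nm, optionally for one channel."""
        df = self.select_channel(channel).data if channel is not None else self.data
        return df[["x", "y"]].to_numpy(dtype=float)

    def select_channel(self, channel: int) -> "LocalizationTable":
        if "channel" not in self.data.columns:
            raise ValueError("table has no channel column")
        sub = self.data[self.data["channel"] == channel].reset_index(drop=True)
        return replace(self, data=sub)

    def sorted_by_frame(self) -> "LocalizationTable":
        return replace(
            self, data=self.data.sort_values("frame", kind="stable").reset_index(drop=True)
        )

    def bounding_roi(self, pad: float = 0.0) -> ROI:
        """Tight ROI around the data (padded; max edges nudged open)."""
        if not len(self):
            raise ValueError("empty table has no bounding ROI")
        x = self.data["x"].to_numpy(dtype=float)
        y = self.data["y"].to_numpy(dtype=float)
        eps = 1e-6
        return ROI(
            x.min() - pad, x.max() + pad + eps, y.min() - pad, y.max() + pad + eps
        )


@dataclass(frozen=True)
class Dialect:
    """Column-mapping spec for a localization CSV dialect.

    ``columns`` maps canonical names (frame, x, y, z, channel, intensity,
    sigma, uncertainty) to file headers. ``unit_scale`` converts file
    coordinates to nm (1000.0 for files in µm). ``channel_from_frame_parity``
    assigns channels from frame parity when no channel column exists:
    even frames -> ``parity_channel_even``, odd -> the other channel.
    """

    columns: Mapping[str, str]
    unit_scale: float = 1.0
    channel_from_frame_parity: bool = False
    parity_channel_even: int = 1

    def header_for(self, name: str) -> str | None:
        return self.columns.get(name)


#: Default dialect: the CSV export headers of common localization software.
THUNDERSTORM_DIALECT = Dialect(
    columns={
        "frame": "frame",
        "x": "x [nm]",
        "y": "y [nm]",
        "z": "z [nm]",
        "channel": "channel",
        "intensity": "intensity [photon]",
        "sigma": "sigma [nm]",
        "uncertainty": "uncertainty [nm]",
    }
)


def read_localizations(
    path: str | Path,
    dialect: Dialect = THUNDERSTORM_DIALECT,
    frame_rate: float = DEFAULT_FRAME_RATE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Coordinates are converted to nm via ``dialect.unit_scale``. The channel
    is taken from a channel column when mapped and present, else from frame
    parity when ``dialect.channel_from_frame_parity`` is set, else omitted.

    Raises
    ------
    FormatError
        If a mandatory mapped column is absent from the file.
    ValueError
        If a coordinate fails to parse; the message names the row index.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    out: dict[str, np.ndarray] = {}
    for name in _CORE_COLUMNS:
        header = dialect.header_for(name)
        if header is None or header not in raw.columns:
            raise FormatError(
                f"missing mandatory column {header or name!r} in {path.name}"
            )
        out[name] = _parse_numeric(raw[header], name)
    for name in _OPTIONAL_COLUMNS:
        header = dialect.header_for(name)
        if header is not None and header in raw.columns:
            out[name] = _parse_numeric(raw[header], name)
    df = pd.DataFrame(out)
    for coord in ("x", "y", "z"):
        if coord in df.columns:
            df[coord] = df[coord] * dialect.unit_scale
    df["frame"] = df["frame"].astype(np.int64)
    if "channel" in df.columns:
        df["channel"] = df["channel"].astype(np.int64)
    elif dialect.channel_from_frame_parity:
        even = dialect.parity_channel_even
        df["channel"] = np.where(df["frame"] % 2 == 0, even, 3 - even)
    return LocalizationTable(df, frame_rate=frame_rate, pixel_size=pixel_size)


def _parse_numeric(series: pd.Series, name: str) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"non-numeric value {series[row]!r} for column {name!r} at row {row}"
        )
    return values.to_numpy()


def write_localizations(
    table: LocalizationTable,
    path: str | Path,
    dialect: Dialect = THUNDERSTORM_DIALECT,
) -> None:
    """Write a table in the given CSV dialect (inverse of read)."""
    df = table.data.copy()
    rename = {
        name: header
        for name, header in dialect.columns.items()
        if name in df.columns
    }
    for coord in ("x", "y", "z"):
        if coord in df.columns:
            df[coord] = df[coord] / dialect.unit_scale
    df.rename(columns=rename).to_csv(path, index=False)


def crop_roi(table: LocalizationTable, roi: ROI) -> LocalizationTable:
    """Keep records strictly inside ``[min, max)`` of the ROI.

    An ROI disjoint from the data yields an empty table, not an error.
    The table's window metadata is replaced by ``roi``.
    """
    x = table.data["x"].to_numpy(dtype=float)
    y = table.data["y"].to_numpy(dtype=float)
    keep = roi.contains(x, y)
    return replace(table, data=table.data[keep].reset_index(drop=True), window=roi)


def max_frame_gap(gap_ms: float, frame_rate: float) -> int:
    """Temporal gap in ms -> max allowed frame separation for linking.

    ``ceil(gap * fps)``, floored at 1 so that consecutive frames always
    link (a gap shorter than one frame interval still spans two frames).
    """
    if gap_ms < 0:
        raise ValueError("temporal gap must be non-negative")
    return max(1, math.ceil(gap_ms / 1000.0 * frame_rate))


def merge_localizations(
    table: LocalizationTable,
    distance_threshold: float = 20.0,
    max_temporal_gap: float = 50.0,
    frame_rate: float | None = None,
) -> LocalizationTable:
    """Group blinking events into molecules (over-counting correction).

    Localizations are linked when within ``distance_threshold`` nm and
    separated by at most the frame equivalent of ``max_temporal_gap`` ms;
    connected components of this spatiotemporal graph become one molecule
    each, placed at the intensity-weighted (unweighted if intensity is
    absent) mean position, carrying the first participating frame.

    Must be applied per channel: defaults (20 nm, 50 ms) follow standard
    fixed-cell dSTORM practice. With both thresholds at zero only
    coincident same-frame localizations merge.
    """
    if distance_threshold < 0:
        raise ValueError("distance threshold must be non-negative")
    if max_temporal_gap < 0:
        raise ValueError("temporal gap must be non-negative")
    if "channel" in table.data.columns and len(set(table.channels)) > 1:
        raise ValueError(
            "merge_localizations operates on a single channel; "
            f"got channels {table.channels} — apply per channel"
        )
    n = len(table)
    if n == 0:
        return table
    fps = table.frame_rate if frame_rate is None else frame_rate
    gap_frames = 0 if max_temporal_gap == 0 else max_frame_gap(max_temporal_gap, fps)

    df = table.sorted_by_frame().data
    xy = df[["x", "y"]].to_numpy(dtype=float)
    frames = df["frame"].to_numpy(dtype=np.int64)

    labels = _link_components(xy, frames, distance_threshold, gap_frames)
    merged = _collapse_groups(df, labels)
    return replace(table, data=merged)


def _link_components(
    xy: np.ndarray, frames: np.ndarray, dist: float, gap: int
) -> np.ndarray:
    """Connected-component labels of the spatiotemporal linkage graph."""
    n = len(xy)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=dist, output_type="ndarray")
    if len(pairs):
        ok = np.abs(frames[pairs[:, 0]] - frames[pairs[:, 1]]) <= gap
        pairs = pairs[ok]
    rows = pairs[:, 0] if len(pairs) else np.empty(0, dtype=np.int64)
    cols = pairs[:, 1] if len(pairs) else np.empty(0, dtype=np.int64)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def _collapse_groups(df: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    work = df.copy()
    work["_group"] = labels
    weights = (
        work["intensity"].to_numpy(dtype=float)
        if "intensity" in work.columns
        else np.ones(len(work))
    )
    if not np.all(weights > 0):
        weights = np.ones(len(work))
    work["_w"] = weights
    for coord in ("x", "y", "z"):
        if coord in work.columns:
            work[f"_{coord}w"] = work[coord] * work["_w"]

    grouped = work.groupby("_group", sort=True)
    agg: dict[str, pd.Series] = {}
    wsum = grouped["_w"].sum()
    for coord in ("x", "y", "z"):
        if coord in work.columns:
            agg[coord] = grouped[f"_{coord}w"].sum() / wsum
    agg["frame"] = grouped["frame"].min()
    if "intensity" in work.columns:
        agg["intensity"] = grouped["intensity"].sum()
    if "channel" in work.columns:
        agg["channel"] = grouped["channel"].first()
    for extra in ("sigma", "uncertainty"):
        if extra in work.columns:
            agg[extra] = grouped[extra].mean()
    out = pd.DataFrame(agg).reset_index(drop=True)
    out["frame"] = out["frame"].astype(np.int64)
    if "channel" in out.columns:
        out["channel"] = out["channel"].astype(np.int64)
    # column order: frame first, then coordinates, like the input
    ordered = [c for c in ("frame", "x", "y", "z", "channel", "intensity", "sigma", "uncertainty") if c in out.columns]
    return out[ordered]


@dataclass
class AccumulatedImage:
    """One accumulated live-sequence image: a block of raw SMLM frames."""

    table: LocalizationTable
    start_frame: int
    timestamp: float  # seconds; frame time of the first participating frame
    partial: bool = False


def accumulate_live_frames(
    movie: LocalizationTable,
    frames_per_image: int = 50,
    alternating_channels: bool = False,
    parity_channel_even: int = 1,
) -> list[AccumulatedImage]:
    """Partition an SMLM movie into accumulated live-imaging frames.

    Consecutive blocks of ``frames_per_image`` raw frames form one image,
    assigned the frame time of the first participating frame. With
    ``alternating_channels`` the raw-frame parity maps to channels (even
    parity -> ``parity_channel_even``), emulating alternating two-color
    acquisition. A trailing partial block is kept and flagged.
    """
    if frames_per_image < 1:
        raise ValueError("frames_per_image must be >= 1")
    df = movie.sorted_by_frame().data.copy()
    if alternating_channels:
        even = parity_channel_even
        df["channel"] = np.where(df["frame"] % 2 == 0, even, 3 - even).astype(np.int64)
    if not len(df):
        return []
    last = int(df["frame"].max())
    images: list[AccumulatedImage] = []
    for start in range(0, last + 1, frames_per_image):
        stop = start + frames_per_image
        block = df[(df["frame"] >= start) & (df["frame"] < stop)].reset_index(drop=True)
        images.append(
            AccumulatedImage(
                table=replace(movie, data=block),
                start_frame=start,
                timestamp=start / movie.frame_rate,
                partial=stop > last + 1,
            )
        )
    return images
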