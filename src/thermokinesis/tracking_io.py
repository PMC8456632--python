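"""Read/write per-frame tracking tables and apply ROI clipping.

The input dialect is a delimited text table (comma or tab, header row)
with one row per animal per frame, as produced by common offline
trackers. Column names are configurable. On ingestion, each animal's
record is split into maximal runs of consecutive frames spent inside the
region of interest (ROI), the rectangle at ``roi_margin`` from the pool
walls; heading is converted to radians and unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "FrameStream",
    "TrackingFormatError",
    "read_tracking_table",
    "streams_from_dataframe",
    "streams_to_dataframe",
    "write_tracking_table",
]

DEFAULT_COLUMNS: dict[str, str] = {
    "frame": "frame",
    "x": "x",
    "y": "y",
    "heading": "heading",
    "id": "id",
}


class TrackingFormatError(ValueError):
    """Raised for malformed tracking tables (missing columns, bad frames)."""


@dataclass(frozen=True)
class ArenaConfig:
    """Arena geometry and acquisition parameters.

    Coordinates are in mm with the origin at a pool corner; y spans the
    short (45 mm) side. Headings are radians internally; set
    ``heading_degrees`` if the tracker writes degrees.
    """

    width: float = 100.0  # mm
    height: float = 45.0  # mm
    roi_margin: float = 5.0  # mm
    fps: float = 25.0  # Hz
    heading_degrees: bool = False
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.roi_margin < min(self.width, self.height) / 2:
            raise ValueError("roi_margin must be below half the smallest side")

    @property
    def roi_bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the ROI rectangle."""
        m = self.roi_margin
        return m, self.width - m, m, self.height - m


@dataclass
class FrameStream:
    """One animal's record over one continuous ROI residency.

    ``heading`` is unwrapped (no +-pi jumps between consecutive frames);
    ``t`` advances at the fixed step 1/fps.
    """

    animal_id: int
    frame: np.ndarray  # int, consecutive
    t: np.ndarray  # s
    x: np.ndarray  # mm
    y: np.ndarray  # mm
    heading: np.ndarray  # rad, unwrapped

    def __post_init__(self) -> None:
        n = len(self.frame)
        for name in ("t", "x", "y", "heading"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field {name!r}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


def _require_columns(df: pd.DataFrame, columns: Mapping[str, str]) -> None:
    for role in ("frame", "x", "y", "heading", "id"):
        name = columns.get(role, role)
        if name not in df.columns:
            raise TrackingFormatError(
                f"required column {name!r} (role {role!r}) missing from table"
            )


def streams_from_dataframe(df: pd.DataFrame, config: ArenaConfig) -> list[FrameStream]:
    """Group a raw tracking table into per-animal ROI-residency streams.

    Rows outside the ROI are dropped; a missing frame inside a run splits
    the run (no interpolation). Raises :class:`TrackingFormatError` on
    missing columns or non-monotone frame indices within an animal.
    """
    cols = {**DEFAULT_COLUMNS, **dict(config.columns)}
    _require_columns(df, cols)
    xmin, xmax, ymin, ymax = config.roi_bounds
    streams: list[FrameStream] = []
    for animal_id, group in df.groupby(cols["id"], sort=True):
        frames = group[cols["frame"]].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise TrackingFormatError(
                f"non-monotone frame indices for animal {animal_id}"
            )
        x = group[cols["x"]].to_numpy(dtype=float)
        y = group[cols["y"]].to_numpy(dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrackingFormatError(f"non-finite coordinates for animal {animal_id}")
        heading = group[cols["heading"]].to_numpy(dtype=float)
        if config.heading_degrees:
            heading = np.deg2rad(heading)
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        # split at ROI exits and at any skipped frame
        consecutive = np.diff(frames) == 1
        boundary = np.flatnonzero(~(inside[1:] & inside[:-1] & consecutive)) + 1
        for start, stop in zip(
            np.concatenate(([0], boundary)), np.concatenate((boundary, [len(frames)]))
        ):
            if stop <= start or not inside[start]:
                continue
            sl = slice(start, stop)
            streams.append(
                FrameStream(
                    animal_id=int(animal_id),
                    frame=frames[sl],
                    t=frames[sl] / config.fps,
                    x=x[sl],
                    y=y[sl],
                    heading=np.unwrap(heading[sl]),
                )
            )
    return streams


def read_tracking_table(path, config: ArenaConfig | None = None) -> list[FrameStream]:
    """Read a delimited tracking table into ROI-residency streams.

    The delimiter (comma or tab) is sniffed from the header line.
    """
    config = config or ArenaConfig()
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    return streams_from_dataframe(df, config)


def streams_to_dataframe(
    streams: Iterable[FrameStream], config: ArenaConfig | None = None
) -> pd.DataFrame:
    """Flatten streams back into a raw table (radians, interleaved by frame)."""
    config = config or ArenaConfig()
    cols = {**DEFAULT_COLUMNS, **dict(config.columns)}
    parts = [
        pd.DataFrame(
            {
                cols["frame"]: s.frame,
                cols["x"]: s.x,
                cols["y"]: s.y,
                cols["heading"]: s.heading,
                cols["id"]: s.animal_id,
            }
        )
        for s in streams
    ]
    if not parts:
        return pd.DataFrame(columns=[cols[k] for k in ("frame", "x", "y", "heading", "id")])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values([cols["id"], cols["frame"]], kind="stable").reset_index(
        drop=True
    )


def write_tracking_table(
    streams: Iterable[FrameStream],
    path,
    config: ArenaConfig | None = None,
    float_format: str = "%.6f",
) -> None:
    """Write streams as a CSV table; empty input yields a header-only file."""
    df = streams_to_dataframe(streams, config)
    df.to_csv(path, index=False, float_format=float_format)
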