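"""Reading and writing of multi-channel time-lapse stacks and tabular outputs.

A :class:`Movie` is the container every other module consumes: an ordered
stack of multi-channel frames with acquisition metadata (frame interval in
minutes, pixel size in micrometres, optional z-spacing).  Coordinates are
0-based, row-major, origin at the top-left, pixel centres at integer
coordinates; areas are in px^2 with ``pixel_size`` available for um^2
conversion.

On disk a movie is a multi-page TIFF with page index ``(t*Z + z)*C + c``
(time slowest, channel fastest) and the metadata stored as JSON in the image
description, so read/write round-trips are bit-exact for 8/16-bit integer and
32-bit float data.  Intensities are handled as real numbers internally
regardless of the on-disk type; unmixed images may be negative and are
written as 32-bit float.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNEL_LABELS = ("reporter", "reference", "brightfield")

#: default frame intervals (minutes) per imaging method
METHOD_FRAME_INTERVALS = {"method1": 3.0, "method2": 10.0 / 60.0, "method3": 1.0}


@dataclass
class AcquisitionMeta:
    """Free-form acquisition annotations carried alongside a movie."""

    temperature_label: str = ""
    method_label: str = "method1"
    start_time_offset: float = 0.0

    def default_frame_interval(self) -> float:
        try:
            return METHOD_FRAME_INTERVALS[self.method_label]
        except KeyError:
            raise ValueError(f"unknown method label {self.method_label!r}") from None


@dataclass
class Movie:
    """Multi-channel time-lapse stack.

    Parameters
    ----------
    data
        Array of shape ``(T, C, Y, X)`` or ``(T, C, Z, Y, X)``.
    channel_names
        One label per channel, typically drawn from
        ``{"reporter", "reference", "brightfield"}``.
    frame_interval
        Minutes between consecutive frames (> 0).
    pixel_size
        Micrometres per pixel (> 0).
    z_spacing
        Micrometres between z-planes; ``None`` for single-plane movies.
    """

    data: np.ndarray
    channel_names: Sequence[str]
    frame_interval: float = 3.0
    pixel_size: float = 0.2
    z_spacing: float | None = None
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"movie data must be (T, C, Y, X) or (T, C, Z, Y, X); got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but {len(self.channel_names)} names"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2] if self.data.ndim == 5 else 1

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes; frame 0 is at time 0."""
        return np.arange(self.n_frames) * float(self.frame_interval)

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_names).index(label)
        except ValueError:
            raise KeyError(f"movie has no channel {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        """All frames of one channel, shape ``(T, [Z,] Y, X)``."""
        return self.data[:, self.channel_index(label)]

    def has_channel(self, label: str) -> bool:
        return label in list(self.channel_names)


def _metadata_dict(movie: Movie) -> dict:
    d = {
        "frame_interval": movie.frame_interval,
        "pixel_size": movie.pixel_size,
        "channel_names": list(movie.channel_names),
        "n_z": movie.n_z,
    }
    if movie.z_spacing is not None:
        d["z_spacing"] = movie.z_spacing
    return d


def write_movie(movie: Movie, path: str | os.PathLike) -> None:
    """Write a movie as a multi-page TIFF, pages ordered (t*Z + z)*C + c.

    Integer data is written unchanged; float data is written as 32-bit float
    (unmixed images may hold negative residuals).  Metadata goes into the
    image description as JSON.
    """
    data = movie.data
    if data.ndim == 4:
        pages = data.reshape(movie.n_frames * movie.n_channels, *data.shape[2:])
    else:
        # (T, C, Z, Y, X) -> (T, Z, C, Y, X) so channel varies fastest
        pages = np.transpose(data, (0, 2, 1, 3, 4)).reshape(
            movie.n_frames * movie.n_z * movie.n_channels, *data.shape[3:]
        )
    if np.issubdtype(pages.dtype, np.floating):
        pages = pages.astype(np.float32)
    tifffile.imwrite(path, pages, description=json.dumps(_metadata_dict(movie)))


def read_movie(
    path: str | os.PathLike,
    channel_map: Mapping[str, int] | None = None,
    n_z: int | None = None,
) -> Movie:
    """Read a multi-page TIFF written by :func:`write_movie` (or compatible).

    Parameters
    ----------
    channel_map
        Maps channel labels to their position in the per-timepoint page
        order.  When omitted, the metadata stored in the file is used.
    n_z
        Number of z-planes per channel; defaults to the stored metadata
        (or 1).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the page count is not divisible by ``channels x z`` or a channel
        label is unknown.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    stored: dict = {}
    if desc:
        try:
            stored = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            stored = {}

    if pages.ndim == 2:
        pages = pages[None]

    if channel_map is None:
        names = stored.get("channel_names")
        if names is None:
            raise ValueError("no channel map given and none stored in file")
        channel_map = {name: i for i, name in enumerate(names)}
    for label in channel_map:
        if label not in CHANNEL_LABELS:
            raise ValueError(
                f"unknown channel label {label!r}; expected one of {CHANNEL_LABELS}"
            )
    n_c = len(channel_map)
    if n_z is None:
        n_z = int(stored.get("n_z", 1))
    n_pages = pages.shape[0]
    if n_pages % (n_c * n_z) != 0:
        raise ValueError(
            f"page count mismatch: {n_pages} pages not divisible by "
            f"{n_c} channels x {n_z} z-planes"
        )
    n_t = n_pages // (n_c * n_z)
    order = sorted(channel_map, key=channel_map.get)
    stack = pages.reshape(n_t, n_z, n_c, *pages.shape[1:])
    stack = np.transpose(stack, (0, 2, 1, 3, 4))  # -> (T, C, Z, Y, X)
    if n_z == 1:
        stack = stack[:, :, 0]
    return Movie(
        data=stack,
        channel_names=order,
        frame_interval=float(stored.get("frame_interval", 3.0)),
        pixel_size=float(stored.get("pixel_size", 0.2)),
        z_spacing=stored.get("z_spacing"),
    )


def export_tables(traces, events, out_dir: str | os.PathLike) -> None:
    """Write ``traces.csv`` and ``events.csv`` under ``out_dir``.

    ``traces`` is an iterable of :class:`~fissionlapse.quantification.CellTrace`;
    ``events`` an iterable of :class:`~fissionlapse.kinetics_events.EventLog`.
    Empty inputs yield header-only files.  Times are in minutes.
    """
    os.makedirs(out_dir, exist_ok=True)
    trace_rows = []
    for tr in traces:
        for i in range(len(tr.times)):
            trace_rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": i,
                    "time_min": tr.times[i],
                    "total_signal": tr.total_signal[i],
                    "hull_area_px2": tr.hull_area[i],
                    "concentration": tr.concentration[i],
                }
            )
    trace_cols = ["cell_id", "frame", "time_min", "total_signal", "hull_area_px2", "concentration"]
    pd.DataFrame(trace_rows, columns=trace_cols).to_csv(
        os.path.join(out_dir, "traces.csv"), index=False
    )

    event_rows = []
    for log in events:
        for ev in log.events:
            event_rows.append(
                {
                    "cell_id": log.cell_id,
                    "event_type": ev.type,
                    "cycle_index": ev.cycle_index,
                    "frame": "" if ev.frame is None else ev.frame,
                    "time_min": "" if ev.frame is None else ev.frame * log.frame_interval,
                    "censoring_flag": ev.censoring_flag,
                }
            )
    event_cols = ["cell_id", "event_type", "cycle_index", "frame", "time_min", "censoring_flag"]
    pd.DataFrame(event_rows, columns=event_cols).to_csv(
        os.path.join(out_dir, "events.csv"), index=False
    )
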