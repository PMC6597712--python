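"""File I/O: headered CSV for tabular data, grayscale TIFF for images.

Traces are written as ``time_s,value`` CSV with epoch annotations as
``# key=value`` header comments; residue tables, densitometry tables and
event lists round-trip through plain headered CSV.  Movies and images are
16-bit grayscale TIFF with the pixel size carried in a JSON image
description.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .types import (
    DensitometryTable,
    EventList,
    MaskedImagePair,
    ResidueTable,
    TimeSeriesTrace,
    TirfMovie,
)

__all__ = [
    "read_trace_csv", "write_trace_csv",
    "read_residue_table_csv", "write_residue_table_csv",
    "read_densitometry_csv", "write_densitometry_csv",
    "read_events_csv", "write_events_csv",
    "read_movie_tiff", "write_movie_tiff",
    "read_image_pair_tiff", "write_image_pair_tiff",
]

PathLike = Union[str, Path]
_TRACE_KEYS = ("t_stim", "t_nh4cl", "t_baf", "identifier")


def write_trace_csv(trace: TimeSeriesTrace, path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key in _TRACE_KEYS:
            val = getattr(trace, key)
            if val not in (None, ""):
                fh.write(f"# {key}={val}\n")
        pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
            fh, index=False)


def read_trace_csv(path: PathLike) -> TimeSeriesTrace:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key.strip()] = val.strip()
    data = pd.read_csv(path, comment="#")
    kwargs = {}
    for key in ("t_stim", "t_nh4cl", "t_baf"):
        if key in meta:
            kwargs[key] = float(meta[key])
    return TimeSeriesTrace(data["time_s"].to_numpy(), data["value"].to_numpy(),
                           identifier=meta.get("identifier", path.stem), **kwargs)


def write_residue_table_csv(table: ResidueTable, path: PathLike) -> None:
    table.data.to_csv(path, index=False)


def read_residue_table_csv(path: PathLike) -> ResidueTable:
    return ResidueTable(pd.read_csv(path))


def write_densitometry_csv(table: DensitometryTable, path: PathLike) -> None:
    table.data.to_csv(path, index=False)


def read_densitometry_csv(path: PathLike) -> DensitometryTable:
    return DensitometryTable(pd.read_csv(path))


def write_events_csv(events: EventList, path: PathLike) -> None:
    events.events.to_csv(path, index=False)


def read_events_csv(path: PathLike) -> EventList:
    return EventList(pd.read_csv(path))


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    clipped = np.clip(np.round(arr), 0, np.iinfo(np.uint16).max)
    return clipped.astype(np.uint16)


def write_movie_tiff(movie: TirfMovie, path: PathLike) -> None:
    desc = json.dumps({"pixel_size_nm": movie.pixel_size,
                       "frame_interval_s": movie.frame_interval})
    tifffile.imwrite(path, _to_uint16(movie.frames), description=desc)


def read_movie_tiff(path: PathLike) -> TirfMovie:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        meta = _parse_description(tif)
    return TirfMovie(frames, frame_interval=meta.get("frame_interval_s", 1.0),
                     pixel_size=meta.get("pixel_size_nm", 100.0))


def write_image_pair_tiff(img: MaskedImagePair, path_r: PathLike,
                          path_g: PathLike, path_mask: PathLike) -> None:
    desc = json.dumps({"pixel_size_nm": img.pixel_size})
    tifffile.imwrite(path_r, _to_uint16(img.channel_r), description=desc)
    tifffile.imwrite(path_g, _to_uint16(img.channel_g), description=desc)
    tifffile.imwrite(path_mask, img.cell_mask.astype(np.uint8), description=desc)


def read_image_pair_tiff(path_r: PathLike, path_g: PathLike,
                         path_mask: PathLike) -> MaskedImagePair:
    with tifffile.TiffFile(path_r) as tif:
        red = tif.asarray().astype(float)
        meta = _parse_description(tif)
    green = tifffile.imread(path_g).astype(float)
    mask = tifffile.imread(path_mask).astype(bool)
    return MaskedImagePair(channel_r=red, channel_g=green, cell_mask=mask,
                           pixel_size=meta.get("pixel_size_nm", 100.0))


def _parse_description(tif: "tifffile.TiffFile") -> dict:
    desc = tif.pages[0].description
    if not desc:
        return {}
    try:
        return json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
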