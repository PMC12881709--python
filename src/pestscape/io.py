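"""Plain-text I/O: ESRI ASCII grid rasters and CSV point/site tables.

Rasters are exchanged as ESRI ASCII grids (``.asc``) — a simple header plus a
row-major matrix, top row first — which round-trips exactly and is readable by
the common GIS stacks. Presence–absence survey tables and presence-background
point sets are CSV with fixed column contracts:

* PA table: ``site_id, x_km, y_km, n_surveys, n_detections``
* PB points: ``x_km, y_km``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec, Raster

_NODATA = -9999.0

PA_COLUMNS = ["site_id", "x_km", "y_km", "n_surveys", "n_detections"]
PB_COLUMNS = ["x_km", "y_km"]


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.origin[0]}\n"
        f"yllcorner {g.origin[1]}\n"
        f"cellsize {g.cell_km}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the northernmost (top) row.
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path, name: str = "", units: str = "") -> Raster:
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        cell_km=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    vals = np.atleast_2d(vals)[::-1]
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(grid, vals, name=name or Path(path).stem, units=units)


def validate_pa_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the PA survey-table contract; returns the validated frame."""
    missing = [c for c in PA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PA table missing columns: {missing}")
    if (df["n_surveys"] < 1).any():
        raise ValueError("n_surveys must be >= 1 at every site")
    if ((df["n_detections"] < 0) | (df["n_detections"] > df["n_surveys"])).any():
        raise ValueError("n_detections must lie in [0, n_surveys]")
    return df


def validate_pb_points(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PB points missing columns: {missing}")
    return df


def read_pa_table(path: str | Path) -> pd.DataFrame:
    return validate_pa_table(pd.read_csv(path))


def read_pb_points(path: str | Path) -> pd.DataFrame:
    return validate_pb_points(pd.read_csv(path))


def write_pa_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_pa_table(df)[PA_COLUMNS].to_csv(path, index=False)


def write_pb_points(df: pd.DataFrame, path: str | Path) -> None:
    validate_pb_points(df)[PB_COLUMNS].to_csv(path, index=False)
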