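"""Raster persistence as ESRI ASCII grids (plain text, world-referenced)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from fxsim.grid import GridSpec


def write_ascii_grid(path: str | Path, data: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    """Write a 2-D raster as an ESRI ASCII grid.

    Row 0 of ``data`` is written first, i.e. treated as the northernmost row.
    """
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid {grid.shape}")
    x0, y0 = grid.origin
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    body = np.where(np.isfinite(data), data, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    grid = GridSpec(
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
        cell_size=meta["cellsize"],
        origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
    )
    nodata = meta.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return data, grid
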