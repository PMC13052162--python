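"""Minimal Esri ASCII grid I/O.

The pipeline exchanges single-band rasters (DEM, river mask, sea mask, conductance)
as plain-text Esri ASCII grids: a six-line header followed by whitespace-separated
rows, northernmost row first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class AsciiGrid:
    """A single-band raster on a regular grid.

    ``data[0, 0]`` is the north-west cell, matching the on-disk row order.
    ``cellsize`` is in the same (planar) unit as ``xllcorner``/``yllcorner``.
    """

    data: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata_value: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "AsciiGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
        )


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: not an Esri ASCII grid (missing ncols/nrows)")
    body = "\n".join(lines[n_header:])
    data = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} values, found {data.size}")
    return AsciiGrid(
        data=data.reshape(nrows, ncols),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata_value=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: AsciiGrid, path: str | Path) -> None:
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata_value:.10g}\n")
        for row in grid.data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
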