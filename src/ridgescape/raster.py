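"""Gridded surfaces (climate layers, elevation, suitability, offset, resistance).

A :class:`RasterGrid` is a 2-D float array with a shared cell-indexing
contract: ``data[row, col]``, row 0 at the top (north), col 0 at the west.
All layers of one analysis share shape and cell size, so cellwise algebra
between them is well defined.  Serialization uses the ESRI ASCII grid
dialect, a plain-text format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band gridded surface.

    Parameters
    ----------
    data:
        2-D array, ``data[row, col]``; NaN marks missing cells.
    cellsize:
        Edge length of a cell in map units (default 1.0).
    xllcorner, yllcorner:
        Coordinates of the lower-left corner (map units).
    """

    data: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if min(self.data.shape) < 2:
            raise ValueError(
                f"degenerate grid {self.data.shape}: both dimensions must be >= 2"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy_with(self, data: np.ndarray) -> "RasterGrid":
        return RasterGrid(np.asarray(data, dtype=float), self.cellsize,
                          self.xllcorner, self.yllcorner)

    def write_ascii(self, path) -> None:
        """Write as ESRI ASCII grid (text)."""
        nrows, ncols = self.data.shape
        body = np.where(np.isnan(self.data), NODATA, self.data)
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {self.xllcorner:.6f}\n")
            fh.write(f"yllcorner {self.yllcorner:.6f}\n")
            fh.write(f"cellsize {self.cellsize:.6f}\n")
            fh.write(f"NODATA_value {NODATA:.1f}\n")
            for row in body:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 2 and parts[0].lower() in (
                        "ncols", "nrows", "xllcorner", "yllcorner",
                        "cellsize", "nodata_value"):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        data = np.array(rows, dtype=float)
        nodata = header.get("nodata_value", NODATA)
        data[data == nodata] = np.nan
        if "ncols" in header and data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid body does not match declared dimensions")
        return cls(data, header.get("cellsize", 1.0),
                   header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))


def check_conformable(*grids: RasterGrid) -> None:
    """Raise if the grids do not share a shape."""
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"rasters are not conformable: shapes {sorted(shapes)}")
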