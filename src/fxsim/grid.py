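"""Grid geometry shared by all rasters in a simulation."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell raster geometry.

    Parameters
    ----------
    nrows, ncols
        Grid dimensions; at least 10 each.
    cell_size
        Cell edge length in meters. The default 100 m gives 1-ha cells, the
        grain at which all outputs are analyzed.
    origin
        World coordinates (x, y) of the lower-left corner, meters.
    """

    nrows: int
    ncols: int
    cell_size: float = 100.0
    origin: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.nrows < 10 or self.ncols < 10:
            raise ValueError(f"grid must be at least 10x10, got {self.nrows}x{self.ncols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (1.0 at the default 100-m cell)."""
        return self.cell_size**2 / 1e4
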