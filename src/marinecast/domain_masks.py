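"""Spatial masks for the index domains: coastal distance bands and boxes.

Cell membership is decided by the cell centre (not area overlap), bounds are
closed intervals, and longitudes use the -180..180 convention; masks are
deterministic functions of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import ConfigurationError
from .synthetic_ocean import GridSpec

__all__ = ["RegionMask", "coastal_band", "box"]


@dataclass(frozen=True)
class RegionMask:
    """A boolean selection of ocean cells with a human-readable descriptor."""

    grid: GridSpec
    included: np.ndarray
    descriptor: str

    def __post_init__(self):
        inc = np.asarray(self.included, dtype=bool)
        if inc.shape != self.grid.shape:
            raise ConfigurationError("mask shape does not match grid")
        if np.any(inc & self.grid.land_mask):
            raise ConfigurationError("mask includes land cells")
        object.__setattr__(self, "included", inc)

    @property
    def n_cells(self) -> int:
        return int(self.included.sum())

    def flat_indices(self) -> np.ndarray:
        return np.nonzero(self.included.ravel())[0]

    def is_subset_of(self, other: "RegionMask") -> bool:
        return bool(np.all(~self.included | other.included))


def coastal_band(grid: GridSpec, max_km: float, lat_min: float, lat_max: float) -> RegionMask:
    """Ocean cells within ``max_km`` of the coast and inside [lat_min, lat_max].

    The habitat-compression domains are the 75 km and 150 km bands off
    California (35–40°N).  Raises if no cell qualifies (the index would be
    undefined there, e.g. a band narrower than half a cell on a coarse grid).
    """
    if not (max_km > 0):
        raise ConfigurationError("max_km must be positive")
    if not (lat_min < lat_max):
        raise ConfigurationError("lat_min must be below lat_max")
    lat_ok = (grid.lats >= lat_min) & (grid.lats <= lat_max)
    included = (
        grid.ocean_mask
        & lat_ok[:, None]
        & (np.nan_to_num(grid.coast_distance, nan=np.inf) <= max_km)
    )
    if not included.any():
        raise ConfigurationError(
            f"no ocean cells within {max_km} km of the coast in {lat_min}-{lat_max}N"
        )
    return RegionMask(
        grid=grid,
        included=included,
        descriptor=f"<= {max_km:g} km of coast, {lat_min:g}-{lat_max:g}N",
    )


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


def box(
    grid: GridSpec, lat_min: float, lat_max: float, lon_min: float, lon_max: float
) -> RegionMask:
    """Ocean cells whose centres lie in the closed lat/lon box.

    Used for the Southern California Bight domain (31–34°N, 120–116°W) of
    the loggerhead-closure indicator.
    """
    if not (lat_min < lat_max):
        raise ConfigurationError("lat bounds must be ordered")
    lo, hi = float(_wrap_lon(lon_min)), float(_wrap_lon(lon_max))
    if not (lo < hi):
        raise ConfigurationError("lon bounds must be ordered after wrapping to -180..180")
    lats_ok = (grid.lats >= lat_min) & (grid.lats <= lat_max)
    lons = _wrap_lon(grid.lons)
    lons_ok = (lons >= lo) & (lons <= hi)
    included = grid.ocean_mask & lats_ok[:, None] & lons_ok[None, :]
    if not included.any():
        raise ConfigurationError(
            f"box {lat_min}-{lat_max}N, {lo}-{hi}E contains no ocean cells"
        )
    return RegionMask(
        grid=grid,
        included=included,
        descriptor=f"box {lat_min:g}-{lat_max:g}N, {lo:g}-{hi:g}E",
    )
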