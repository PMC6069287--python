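"""Data model and I/O for multiband surface-reflectance scenes.

A :class:`ReflectanceScene` is a dated stack of co-registered reflectance
bands on a common north-up grid, with Sentinel-2 MSI band semantics
attached through a :class:`BandMap`. Scenes, masks and classified maps
travel as GeoTIFF; sample plots as CSV.
"""
from __future__ import annotations

import datetime as _dt
import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._geotiff import read_geotiff, write_geotiff
from .errors import (
    BandMapError,
    InputError,
    PlotOutOfBoundsError,
    ResolutionError,
    SamplingError,
)
from .grids import GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthStage",
    "StressLevel",
    "BandMap",
    "ReflectanceScene",
    "PlotTable",
    "read_scene",
    "write_scene",
    "resample_to_grid",
    "sample_pixels",
    "sample_random_mask_pixels",
    "DEFAULT_SCALE_FACTOR",
    "CLASS_CODES",
    "CODE_TO_LEVEL",
]

DEFAULT_SCALE_FACTOR = 10000.0

# Sentinel-2 L2A band semantics used by the indices. Central wavelengths
# and native resolutions follow the MSI band definitions.
REQUIRED_BAND_KEYS = (
    "B2_blue_490",
    "B4_red_665",
    "B5_rededge_705",
    "B6_rededge_740",
    "B7_rededge_783",
)
_WAVELENGTHS = {
    "B2_blue_490": 490,
    "B4_red_665": 665,
    "B5_rededge_705": 705,
    "B6_rededge_740": 740,
    "B7_rededge_783": 783,
}
_NATIVE_RES = {
    "B2_blue_490": 10,
    "B4_red_665": 10,
    "B5_rededge_705": 20,
    "B6_rededge_740": 20,
    "B7_rededge_783": 20,
}


class GrowthStage(str, enum.Enum):
    """Rice phenological windows, each observed on two acquisition dates."""

    BOOTING = "booting"
    FLOWERING = "flowering"
    MATURE = "mature"

    @property
    def order(self) -> int:
        return ("booting", "flowering", "mature").index(self.value)


class StressLevel(str, enum.Enum):
    """Ordered heavy-metal stress labels assigned to the study areas."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"


#: Class codes for 8-bit classified maps: 0 is nodata.
CLASS_CODES = {StressLevel.HIGH: 1, StressLevel.MEDIUM: 2, StressLevel.LOW: 3}
CODE_TO_LEVEL = {v: k for k, v in CLASS_CODES.items()}


@dataclass(frozen=True)
class BandMap:
    """Mapping from semantic band keys to 0-based band indices in a file.

    The five keys required by the indices must all be present with distinct
    indices before any index computation.
    """

    entries: dict[str, int]
    central_wavelength_nm: dict[str, int] = field(default_factory=lambda: dict(_WAVELENGTHS))
    native_resolution_m: dict[str, int] = field(default_factory=lambda: dict(_NATIVE_RES))

    def __post_init__(self):
        missing = [k for k in REQUIRED_BAND_KEYS if k not in self.entries]
        if missing:
            raise BandMapError(f"band map missing keys: {missing}")
        idx = [self.entries[k] for k in REQUIRED_BAND_KEYS]
        if len(set(idx)) != len(idx):
            raise BandMapError(f"band map indices not distinct: {self.entries}")
        for k in REQUIRED_BAND_KEYS:
            if self.central_wavelength_nm.get(k) != _WAVELENGTHS[k]:
                raise BandMapError(
                    f"central wavelength for {k} must be {_WAVELENGTHS[k]} nm "
                    f"(got {self.central_wavelength_nm.get(k)})"
                )

    @classmethod
    def sentinel2(cls) -> "BandMap":
        """Default profile: bands stored in order B2, B4, B5, B6, B7."""
        return cls(entries={k: i for i, k in enumerate(REQUIRED_BAND_KEYS)})

    def index_of(self, key: str) -> int:
        if key not in self.entries:
            raise BandMapError(f"unknown band key {key!r}")
        return self.entries[key]


@dataclass
class ReflectanceScene:
    """A dated multiband reflectance raster on a common grid.

    ``bands`` is a (nbands, rows, cols) float array of surface reflectance
    in 0..1; ``nodata_mask`` is True where any band is invalid and is the
    authoritative validity record.
    """

    bands: np.ndarray
    geom: GridGeometry
    band_map: BandMap
    acquisition_date: _dt.date
    growth_stage: GrowthStage
    nodata_mask: np.ndarray

    def __post_init__(self):
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3:
            raise InputError("bands must be a (nbands, rows, cols) array")
        if self.bands.shape[1:] != self.geom.shape:
            raise InputError(
                f"band shape {self.bands.shape[1:]} != grid shape {self.geom.shape}"
            )
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.geom.shape:
            raise InputError("nodata_mask shape mismatch")
        n = self.bands.shape[0]
        for key, i in self.band_map.entries.items():
            if not (0 <= i < n):
                raise BandMapError(f"band key {key!r} -> index {i} outside 0..{n - 1}")
        valid = ~self.nodata_mask
        if not np.all(np.isfinite(self.bands[:, valid])):
            raise InputError("non-finite reflectance outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.geom.shape

    def band(self, key: str) -> np.ndarray:
        """Reflectance array for a semantic band key."""
        return self.bands[self.band_map.index_of(key)]


class PlotTable:
    """Sample plots: id, map coordinates, stress label, study-area label.

    Thin wrapper over a pandas DataFrame with validated columns
    ``plot_id, x, y, stress_level, area_label``.
    """

    COLUMNS = ["plot_id", "x", "y", "stress_level", "area_label"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"plot table missing columns: {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["plot_id"] = frame["plot_id"].astype(str)
        if frame["plot_id"].duplicated().any():
            dupes = frame.loc[frame["plot_id"].duplicated(), "plot_id"].tolist()
            raise InputError(f"duplicate plot ids: {dupes}")
        levels = {lv.value for lv in StressLevel}
        bad = sorted(set(frame["stress_level"].astype(str)) - levels)
        if bad:
            raise InputError(f"unknown stress levels: {bad}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def read_csv(cls, path) -> "PlotTable":
        return cls(pd.read_csv(path, dtype={"plot_id": str}))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")

    def labels(self) -> pd.Series:
        return self.frame["stress_level"]


def read_scene(
    path,
    band_map: BandMap,
    date: _dt.date,
    stage: GrowthStage,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
) -> ReflectanceScene:
    """Read a multiband GeoTIFF as a reflectance scene.

    Integer-scaled reflectance (values beyond 1.5) is auto-detected and
    divided by ``scale_factor`` (Sentinel-2 L2A convention, default 10000).
    The file's nodata value populates the scene's mask.
    """
    array, geom, nodata, _meta = read_geotiff(path)
    if array.ndim == 2:
        array = array[None, :, :]
    nbands = array.shape[0]
    for key, i in band_map.entries.items():
        if not (0 <= i < nbands):
            raise BandMapError(
                f"{path}: band key {key!r} -> index {i}, file has {nbands} bands"
            )
    bands = array.astype(np.float64)
    mask = ~np.isfinite(bands).all(axis=0)
    if nodata is not None:
        mask |= np.any(array == nodata, axis=0)
    valid = ~mask
    if valid.any() and np.nanmax(np.abs(bands[:, valid])) > 1.5:
        logger.info("%s: integer-scaled reflectance detected; dividing by %g", path, scale_factor)
        bands = bands / scale_factor
    bands[:, mask] = np.nan
    return ReflectanceScene(
        bands=bands,
        geom=geom,
        band_map=band_map,
        acquisition_date=date,
        growth_stage=GrowthStage(stage),
        nodata_mask=mask,
    )


def write_scene(scene: ReflectanceScene, path, nodata: float = -9999.0) -> None:
    """Write a scene as float32 multiband GeoTIFF with a nodata sentinel."""
    out = scene.bands.astype(np.float32).copy()
    out[:, scene.nodata_mask] = nodata
    write_geotiff(
        path,
        out,
        scene.geom,
        nodata=nodata,
        metadata={
            "acquisition_date": scene.acquisition_date.isoformat(),
            "growth_stage": scene.growth_stage.value,
            "band_keys": {k: v for k, v in scene.band_map.entries.items()},
        },
    )


def _resample_2d(values: np.ndarray, k_up: int, k_down: int, reduce_any: bool = False):
    """Nearest-neighbour retiling by integer factors (first up, then down)."""
    out = values
    if k_up > 1:
        out = np.repeat(np.repeat(out, k_up, axis=0), k_up, axis=1)
    if k_down > 1:
        if reduce_any:
            r, c = out.shape
            out = out.reshape(r // k_down, k_down, c // k_down, k_down).any(axis=(1, 3))
        else:
            # nearest to the target cell centre: for an even factor the centre
            # sits on a source-cell corner; take the upper-left of the tied four
            off = (k_down - 1) // 2
            out = out[off::k_down, off::k_down]
    return out


def resample_to_grid(scene: ReflectanceScene, target_resolution_m: float) -> ReflectanceScene:
    """Retile a scene onto a grid at ``target_resolution_m``.

    Nearest-neighbour in both directions, preserving the envelope. When
    aggregating, any contributing nodata cell marks the output cell nodata.
    """
    if abs(target_resolution_m - scene.geom.resolution) < 1e-9:
        return scene
    new_geom = scene.geom.with_resolution(target_resolution_m)  # raises ResolutionError
    factor = scene.geom.resolution / target_resolution_m
    if factor > 1:
        k_up, k_down = round(factor), 1
    else:
        k_up, k_down = 1, round(1 / factor)
    logger.info(
        "resampling %s m -> %s m (nearest-neighbour, factor %s)",
        scene.geom.resolution, target_resolution_m, k_up if k_up > 1 else f"1/{k_down}",
    )
    bands = np.stack([_resample_2d(b, k_up, k_down) for b in scene.bands])
    mask = _resample_2d(scene.nodata_mask, k_up, k_down, reduce_any=True)
    bands = bands.copy()
    bands[:, mask] = np.nan
    return replace(scene, bands=bands, geom=new_geom, nodata_mask=mask)


def sample_pixels(raster, plots: PlotTable) -> pd.DataFrame:
    """Point-in-cell sampling of a raster at plot coordinates.

    ``raster`` is anything with ``geom``, ``nodata_mask`` and either a
    2-D ``values`` array (index raster) or 3-D ``bands`` (scene). Returns a
    DataFrame with one row per plot: pixel (row, col), sampled value(s) and
    a ``valid`` flag (False where the plot lands on nodata — flagged, never
    dropped). Plots outside the extent raise, naming the offending ids.
    """
    geom: GridGeometry = raster.geom
    x = plots.frame["x"].to_numpy(dtype=float)
    y = plots.frame["y"].to_numpy(dtype=float)
    inside = geom.contains(x, y)
    if not inside.all():
        raise PlotOutOfBoundsError(plots.frame.loc[~inside, "plot_id"].tolist())
    row, col = geom.cell_of(x, y)
    out = plots.frame.copy()
    out["row"] = row
    out["col"] = col
    if hasattr(raster, "values") and getattr(raster, "values") is not None:
        out["value"] = np.asarray(raster.values)[row, col]
    else:
        for key, i in sorted(raster.band_map.entries.items(), key=lambda kv: kv[1]):
            out[key] = raster.bands[i, row, col]
    out["valid"] = ~raster.nodata_mask[row, col]
    return out


def sample_random_mask_pixels(mask: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` distinct (row, col) cells uniformly from the True cells.

    Deterministic for a given seed; no global random state is touched.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = np.flatnonzero(mask)
    if n > flat.size:
        raise SamplingError(f"requested {n} pixels but mask has only {flat.size} true cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    return np.column_stack([rows, cols])
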