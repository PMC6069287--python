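"""Red-edge spectral indices: CI_red-edge, PSRI and their ratio HMSSI.

CI_red-edge = R783/R705 - 1 rises with canopy chlorophyll and falls under
stress; PSRI = (R680 - R500)/R750 rises with the carotenoid:chlorophyll
ratio and hence with stress. HMSSI = CI_red-edge / PSRI combines the two
opposite responses, so class differences multiply while multiplicative
illumination-like errors common to all bands cancel (both component
indices are ratios of bands, i.e. degree-0 homogeneous).

On Sentinel-2 MSI the reflectance symbols map to bands as R783 -> band 7,
R705 -> band 5, R680 -> band 4, R500 -> band 2 and R750 -> band 6 (740 nm;
the symbol keeps the original index definition's wavelength, the band
assignment follows the MSI band set).

Pixels where a denominator falls inside the guard band |den| < 1e-6 are
flagged invalid rather than propagated as infinities; negative PSRI
(healthy, non-senescing canopy) is propagated with its sign into HMSSI,
never clipped.
"""
from __future__ import annotations

import datetime as _dt
import enum
import logging
from dataclasses import dataclass

import numpy as np

from ._geotiff import read_geotiff, write_geotiff
from .errors import BandMapError, DomainError, IndexKindError
from .grids import GridGeometry
from .raster_core import GrowthStage, ReflectanceScene

logger = logging.getLogger(__name__)

__all__ = [
    "GUARD_EPS",
    "IndexKind",
    "IndexValue",
    "IndexRaster",
    "compute_ci",
    "compute_psri",
    "compute_hmssi",
    "hmssi_from_bands",
    "compute_index_raster",
    "write_index_raster",
    "read_index_raster",
]

#: Denominator guard in reflectance units; guarded cells become invalid/nodata.
GUARD_EPS = 1e-6


class IndexKind(str, enum.Enum):
    CI_REDEDGE = "ci_rededge"
    PSRI = "psri"
    HMSSI = "hmssi"


@dataclass(frozen=True)
class IndexValue:
    """A single index evaluation; ``valid`` is False if a guard fired."""

    value: float
    index_kind: IndexKind
    valid: bool = True


def _check_nonnegative(**reflectances: float) -> None:
    for name, r in reflectances.items():
        if not np.isfinite(r):
            raise DomainError(f"{name} must be finite, got {r}")
        if r < 0:
            raise DomainError(f"reflectance {name} must be >= 0, got {r}")


def compute_ci(r783: float, r705: float) -> IndexValue:
    """Red-edge chlorophyll index: R783/R705 - 1."""
    _check_nonnegative(r783=r783, r705=r705)
    if r705 < GUARD_EPS:
        return IndexValue(np.nan, IndexKind.CI_REDEDGE, valid=False)
    return IndexValue(r783 / r705 - 1.0, IndexKind.CI_REDEDGE)


def compute_psri(r680: float, r500: float, r750: float) -> IndexValue:
    """Plant senescence reflectance index: (R680 - R500)/R750."""
    _check_nonnegative(r680=r680, r500=r500, r750=r750)
    if r750 < GUARD_EPS:
        return IndexValue(np.nan, IndexKind.PSRI, valid=False)
    return IndexValue((r680 - r500) / r750, IndexKind.PSRI)


def compute_hmssi(ci: IndexValue, psri: IndexValue) -> IndexValue:
    """Heavy metal stress sensitive index: CI_red-edge / PSRI.

    The sign of PSRI is preserved (negative PSRI yields negative HMSSI);
    |PSRI| inside the guard band, or an invalid input, yields an invalid
    result.
    """
    if ci.index_kind is not IndexKind.CI_REDEDGE:
        raise IndexKindError(f"first argument must be ci_rededge, got {ci.index_kind.value}")
    if psri.index_kind is not IndexKind.PSRI:
        raise IndexKindError(f"second argument must be psri, got {psri.index_kind.value}")
    if not (ci.valid and psri.valid) or abs(psri.value) < GUARD_EPS:
        return IndexValue(np.nan, IndexKind.HMSSI, valid=False)
    return IndexValue(ci.value / psri.value, IndexKind.HMSSI)


def hmssi_from_bands(r783, r705, r680, r500, r750) -> IndexValue:
    """Evaluate the full chain CI, PSRI -> HMSSI from five band reflectances."""
    return compute_hmssi(compute_ci(r783, r705), compute_psri(r680, r500, r750))


@dataclass
class IndexRaster:
    """Single-band float raster of one index on one acquisition date.

    The nodata mask is a superset of the union of source-band nodata and
    denominator-guard cells.
    """

    values: np.ndarray
    geom: GridGeometry
    index_kind: IndexKind
    source_date: _dt.date
    growth_stage: GrowthStage
    nodata_mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.geom.shape or self.nodata_mask.shape != self.geom.shape:
            raise ValueError("values/nodata_mask shape must match grid shape")

    def masked_values(self) -> np.ndarray:
        """Values with nodata as NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out


def _ci_arrays(scene: ReflectanceScene):
    r783 = scene.band("B7_rededge_783")
    r705 = scene.band("B5_rededge_705")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = r783 / r705 - 1.0
    guard = np.abs(r705) < GUARD_EPS
    return values, guard


def _psri_arrays(scene: ReflectanceScene):
    r680 = scene.band("B4_red_665")
    r500 = scene.band("B2_blue_490")
    r750 = scene.band("B6_rededge_740")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (r680 - r500) / r750
    guard = np.abs(r750) < GUARD_EPS
    return values, guard


def compute_index_raster(scene: ReflectanceScene, kind: IndexKind | str) -> IndexRaster:
    """Apply a scalar index definition to every pixel of a scene."""
    kind = IndexKind(kind)
    if kind is IndexKind.CI_REDEDGE:
        values, guard = _ci_arrays(scene)
    elif kind is IndexKind.PSRI:
        values, guard = _psri_arrays(scene)
    else:
        ci, g1 = _ci_arrays(scene)
        psri, g2 = _psri_arrays(scene)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = ci / psri
        guard = g1 | g2 | (np.abs(psri) < GUARD_EPS)
    mask = scene.nodata_mask | guard | ~np.isfinite(values)
    values = values.copy()
    values[mask] = np.nan
    n_guard = int(np.count_nonzero(guard & ~scene.nodata_mask))
    if n_guard:
        logger.info("%s: %d pixels hit the denominator guard", kind.value, n_guard)
    if kind is IndexKind.HMSSI:
        n_neg = int(np.count_nonzero((values < 0) & ~mask))
        if n_neg:
            logger.info("hmssi: %d pixels have negative PSRI -> negative HMSSI (sign preserved)", n_neg)
    return IndexRaster(
        values=values,
        geom=scene.geom,
        index_kind=kind,
        source_date=scene.acquisition_date,
        growth_stage=scene.growth_stage,
        nodata_mask=mask,
    )


def write_index_raster(raster: IndexRaster, path, nodata: float = -9999.0) -> None:
    """Write as single-band float32 GeoTIFF with kind and date in metadata."""
    out = raster.values.astype(np.float32).copy()
    out[raster.nodata_mask] = nodata
    write_geotiff(
        path,
        out,
        raster.geom,
        nodata=nodata,
        metadata={
            "index_kind": raster.index_kind.value,
            "source_date": raster.source_date.isoformat(),
            "growth_stage": raster.growth_stage.value,
        },
    )


def read_index_raster(path) -> IndexRaster:
    array, geom, nodata, meta = read_geotiff(path)
    if array.ndim != 2:
        raise BandMapError(f"{path}: index raster must be single-band")
    values = array.astype(np.float64)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= array == nodata
    values[mask] = np.nan
    return IndexRaster(
        values=values,
        geom=geom,
        index_kind=IndexKind(meta["index_kind"]),
        source_date=_dt.date.fromisoformat(meta["source_date"]),
        growth_stage=GrowthStage(meta["growth_stage"]),
        nodata_mask=mask,
    )
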