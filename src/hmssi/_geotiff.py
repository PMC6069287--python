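"""Minimal GeoTIFF reader/writer built on tifffile.

Writes the standard GeoTIFF georeferencing tags (ModelPixelScale,
ModelTiepoint, GDAL_NODATA) plus a JSON ImageDescription carrying the CRS
string and arbitrary scene metadata, and reads them back. Only north-up
grids with square pixels are supported — which is all the package produces
or consumes.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import RasterFormatError
from .grids import GridGeometry

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GDAL_NODATA = 42113


def write_geotiff(
    path,
    array: np.ndarray,
    geom: GridGeometry,
    nodata: float | int | None = None,
    metadata: dict | None = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as a GeoTIFF."""
    array = np.asarray(array)
    if array.ndim == 2:
        shape_rc = array.shape
    elif array.ndim == 3:
        shape_rc = array.shape[1:]
    else:
        raise ValueError("array must be 2-D or 3-D (bands, rows, cols)")
    if shape_rc != geom.shape:
        raise ValueError(f"array shape {shape_rc} != grid shape {geom.shape}")

    desc = {"crs": geom.crs}
    if metadata:
        desc.update(metadata)
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (geom.resolution, geom.resolution, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geom.x0, geom.y0, 0.0)),
    ]
    if nodata is not None:
        extratags.append((TAG_GDAL_NODATA, "s", 0, repr(nodata) if isinstance(nodata, float) else str(nodata)))
    kwargs = {"planarconfig": "separate"} if array.ndim == 3 else {}
    tifffile.imwrite(
        Path(path),
        array,
        description=json.dumps(desc),
        extratags=extratags,
        **kwargs,
    )


def read_geotiff(path) -> tuple[np.ndarray, GridGeometry, float | None, dict]:
    """Read a GeoTIFF written by :func:`write_geotiff` (or compatible).

    Returns ``(array, geometry, nodata, metadata)``. ``array`` keeps the
    on-disk dtype and is (bands, rows, cols) for multiband files.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            array = tif.asarray()
            tags = page.tags
            scale_tag = tags.get(TAG_MODEL_PIXEL_SCALE)
            tiepoint_tag = tags.get(TAG_MODEL_TIEPOINT)
            nodata_tag = tags.get(TAG_GDAL_NODATA)
            desc_tag = tags.get("ImageDescription")
            # materialise tag values before the file closes
            scale = None if scale_tag is None else tuple(scale_tag.value)
            tiepoint = None if tiepoint_tag is None else tuple(tiepoint_tag.value)
            nodata_str = None if nodata_tag is None else str(nodata_tag.value)
            desc = None if desc_tag is None else desc_tag.value
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise RasterFormatError(f"{path}: not a readable TIFF ({exc})") from exc

    if scale is None or tiepoint is None:
        raise RasterFormatError(f"{path}: no georeferencing tags (not a GeoTIFF)")
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-9:
        raise RasterFormatError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
    i, j, _, x, y, _ = (float(v) for v in tiepoint)
    x0 = x - j * sx
    y0 = y + i * sy

    metadata: dict = {}
    if desc is not None:
        try:
            metadata = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            metadata = {}
    crs = metadata.pop("crs", "EPSG:32649")

    if array.ndim == 2:
        rows, cols = array.shape
    else:
        rows, cols = array.shape[1], array.shape[2]
    geom = GridGeometry(rows=rows, cols=cols, x0=x0, y0=y0, resolution=sx, crs=crs)

    nodata = None
    if nodata_str is not None:
        try:
            nodata = float(nodata_str.strip().rstrip("\x00"))
        except ValueError:
            nodata = None
    return array, geom, nodata, metadata
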