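"""Single-band raster I/O.

Layers are written as single-band TIFF files carrying the standard
GeoTIFF ModelPixelScale / ModelTiepoint tags and the GDAL nodata tag, so
they open in GIS tooling with correct geometry; reading them back
reproduces integer layers bit-exactly and floating-point layers to
within representation error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidArgumentError
from .lattice import Lattice

MODEL_PIXEL_SCALE = 33550
MODEL_TIEPOINT = 33922
GDAL_NODATA = 42113


def write_layer(
    path: str | Path,
    values: np.ndarray,
    lattice: Lattice,
    nodata: float = -9999.0,
    description: str = "",
) -> None:
    """Write one band with geo tags; float64 preserved, ints stay ints."""
    arr = np.asarray(values)
    if arr.shape != lattice.shape:
        raise InvalidArgumentError(f"layer shape {arr.shape} != lattice {lattice.shape}")
    x0, y0 = lattice.origin
    # cell_size is km; tags are in CRS units (here: km)
    extratags = [
        (MODEL_PIXEL_SCALE, "d", 3, (lattice.cell_size, lattice.cell_size, 0.0)),
        (MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(str(path), arr, extratags=extratags, description=description)


def read_layer(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read one band plus its geo metadata (cell_size, origin, nodata)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        meta = {}
        tags = page.tags
        if MODEL_PIXEL_SCALE in tags:
            meta["cell_size"] = float(tags[MODEL_PIXEL_SCALE].value[0])
        if MODEL_TIEPOINT in tags:
            tp = tags[MODEL_TIEPOINT].value
            meta["origin"] = (float(tp[3]), float(tp[4]))
        if GDAL_NODATA in tags:
            meta["nodata"] = float(tags[GDAL_NODATA].value)
    return arr, meta


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
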