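"""LAI retrieval from 4-band reflectance and soil pollution indices.

LAI is retrieved through the Green-Blue NDVI,

    GBNDVI = (NIR - (G + B)) / (NIR + (G + B)),
    LAI    = 0.3243 * exp(5.3944 * GBNDVI),

an exponential regression chosen over plain NDVI because the combined
green+blue term delays saturation at high canopy density.  Soil
contamination is summarized per area by the single-factor pollution
index, the mean ratio of measured topsoil concentration to the regional
background value, with three levels (Safe / Level I / Level II) at
index thresholds 1 and 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .crop_model import InputError

__all__ = [
    "MultispectralScene",
    "LAIRaster",
    "SoilSampleTable",
    "gbndvi",
    "lai_from_gbndvi",
    "invert_lai_to_gbndvi",
    "pollution_index",
    "truncate_2dec",
    "classify_pollution",
]

logger = logging.getLogger(__name__)

#: coefficients of the exponential GBNDVI -> LAI regression
LAI_COEF_A = 0.3243
LAI_COEF_B = 5.3944

#: sentinel for masked / undefined raster cells (never 0: LAI 0 is legal)
NODATA = -9999.0

#: warn when a retrieved LAI exceeds this (suspicious for a rice canopy)
MAX_PLAUSIBLE_LAI = 8.0

BAND_ORDER = ("blue", "green", "red", "nir")


@dataclass
class MultispectralScene:
    """4-band surface-reflectance grids with a rice mask.

    Reflectances are unitless in [0, 1]; ``mask`` is True on rice pixels.
    ``geotransform`` is carried as opaque metadata (6-tuple affine, GDAL
    convention) and never interpreted by the computations.
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    doy: int
    mask: np.ndarray
    geotransform: tuple = (0.0, 30.0, 0.0, 0.0, 0.0, -30.0)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.blue, self.green, self.red,
                                    self.nir, self.mask)}
        if len(shapes) != 1:
            raise InputError("scene bands and mask must share one shape")
        for name in BAND_ORDER:
            band = getattr(self, name)
            if band.min() < 0 or band.max() > 1:
                raise InputError(f"reflectance band {name!r} outside [0, 1]")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def to_tiff(self, path: str | Path) -> None:
        """Write bands (blue, green, red, nir, mask) as a multiband TIFF."""
        stack = np.stack([self.blue, self.green, self.red, self.nir,
                          self.mask.astype(np.float32)]).astype(np.float32)
        meta = json.dumps({"doy": self.doy, "geotransform": list(self.geotransform),
                           "bands": list(BAND_ORDER) + ["mask"]})
        tifffile.imwrite(Path(path), stack, description=meta)

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultispectralScene":
        with tifffile.TiffFile(Path(path)) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if stack.shape[0] != 5:
            raise InputError("scene TIFF must hold 5 bands (blue,green,red,nir,mask)")
        b, g, r, n, m = (np.asarray(x, dtype=float) for x in stack)
        return cls(b, g, r, n, doy=int(meta["doy"]), mask=m > 0.5,
                   geotransform=tuple(meta.get("geotransform", (0, 30, 0, 0, 0, -30))))


@dataclass
class LAIRaster:
    """Per-pixel LAI grid; masked cells hold the NODATA sentinel."""

    lai: np.ndarray
    doy: int
    mask: np.ndarray
    nodata: float = NODATA

    def valid_values(self) -> np.ndarray:
        return self.lai[self.mask]

    def to_tiff(self, path: str | Path) -> None:
        meta = json.dumps({"doy": self.doy, "nodata": self.nodata})
        tifffile.imwrite(Path(path), self.lai.astype(np.float32), description=meta)


@dataclass(frozen=True)
class SoilSampleTable:
    """Soil heavy-metal sample rows: area, metal, concentration, background.

    Concentrations and background values are mg/kg dry soil.
    """

    table: pd.DataFrame

    REQUIRED = ("area", "metal", "soil_conc", "background")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"soil table missing column(s) {missing}")
        if (self.table["soil_conc"] <= 0).any() or (self.table["background"] <= 0).any():
            raise InputError("soil concentrations and backgrounds must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SoilSampleTable":
        return cls(pd.read_csv(path))


def gbndvi(scene: MultispectralScene) -> np.ndarray:
    """Green-Blue NDVI per pixel, in [-1, 1]; NODATA where undefined.

    Pixels with a zero NIR + G + B denominator (or outside the rice mask)
    are set to the NODATA sentinel; zero-denominator pixels are counted
    and logged.
    """
    num = scene.nir - (scene.green + scene.blue)
    den = scene.nir + (scene.green + scene.blue)
    out = np.full(scene.shape, NODATA)
    bad = (den == 0) & scene.mask
    ok = scene.mask & ~bad
    out[ok] = num[ok] / den[ok]
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("gbndvi: %d masked-in pixel(s) with zero denominator "
                       "set to nodata", n_bad)
    return out


def lai_from_gbndvi(index: np.ndarray, doy: int = 0,
                    mask: np.ndarray | None = None) -> LAIRaster:
    """Exponential GBNDVI -> LAI regression, applied per pixel.

    Strictly increasing in the index; no saturation cap is applied, but
    pixels above ``MAX_PLAUSIBLE_LAI`` are counted and logged.
    """
    idx = np.asarray(index, dtype=float)
    if mask is None:
        mask = idx != NODATA
    lai = np.full(idx.shape, NODATA)
    lai[mask] = LAI_COEF_A * np.exp(LAI_COEF_B * idx[mask])
    n_big = int((lai[mask] > MAX_PLAUSIBLE_LAI).sum())
    if n_big:
        logger.warning("lai_from_gbndvi: %d pixel(s) above LAI %.1f", n_big,
                       MAX_PLAUSIBLE_LAI)
    return LAIRaster(lai, doy, np.asarray(mask, dtype=bool))


def invert_lai_to_gbndvi(lai):
    """Exact inverse of the LAI regression: ln(lai / a) / b.  Needs lai > 0."""
    arr = np.asarray(lai, dtype=float)
    if np.any(arr <= 0):
        raise InputError("invert_lai_to_gbndvi requires positive LAI")
    out = np.log(arr / LAI_COEF_A) / LAI_COEF_B
    return float(out) if np.isscalar(lai) or arr.ndim == 0 else out


def pollution_index(samples: SoilSampleTable, metal: str) -> pd.Series:
    """Per-area single-factor pollution index: mean(soil / background).

    Full precision; use :func:`truncate_2dec` for 2-decimal reporting.
    """
    df = samples.table
    sub = df[df["metal"] == metal]
    if sub.empty:
        raise InputError(f"no soil samples for metal {metal!r}")
    return sub.groupby("area").apply(
        lambda g: float(np.mean(g["soil_conc"] / g["background"])),
        include_groups=False)


def truncate_2dec(x: float) -> float:
    """Truncate (floor) a positive index to 2 decimals for reporting."""
    return np.floor(float(x) * 100.0) / 100.0


def classify_pollution(index: float) -> str:
    """Pollution level from the single-factor index (thresholds 1 and 2)."""
    if index < 0:
        raise InputError("pollution index cannot be negative")
    if index <= 1.0:
        return "Safe"
    if index <= 2.0:
        return "Level I"
    return "Level II"
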