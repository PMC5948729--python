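"""Key-period selection on LAI curves via Harris corner detection.

A seasonal LAI (or LAI-ratio) curve is rendered as a binary grayscale
image — one column per day, one row per ``y_step`` of curve value, the
curve drawn as a connected one-pixel polyline — and scored with the
Harris corner measure

    R = det(M) - k * trace(M)^2

on the Gaussian-weighted structure tensor M of the image gradients.
Days whose pixels are local maxima of R mark corner-like curvature in
the trajectory: growth onset, allocation shifts, the canopy peak, and
senescence breaks.  Points found on the stressed LAI curve and on the
stressed/reference ratio curve are screened against each other with the
LAI growth rate to give the final key period, the recommended dates for
imagery acquisition and field sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line

from .crop_model import InputError, ParameterError

__all__ = [
    "CurveImage",
    "HarrisResponse",
    "DominantPointSet",
    "rasterize_curve",
    "gaussian_kernel",
    "smooth",
    "harris_response",
    "detect_dominant_points",
    "ratio_curve",
    "growth_rate",
    "screen_points",
    "select_images",
    "fit_dominant_points",
    "find_dominant_points",
    "auto_y_step",
]

#: rows of empty headroom added above and below the curve so border effects
#: of the smoothing/derivative kernels never touch it
_PAD_ROWS = 16


@dataclass
class CurveImage:
    """Grayscale rasterization of a per-day curve.

    Column j is the day ``x_origin_doy + j``; row i holds the value
    ``y_origin + i * y_step`` (row index grows with the value).
    """

    pixels: np.ndarray
    x_origin_doy: int
    y_step: float
    y_origin: float

    def __post_init__(self) -> None:
        if self.y_step <= 0:
            raise InputError("y_step must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise InputError("curve-image intensities must lie in [0, 1]")

    def col_to_doy(self, col: int) -> int:
        return self.x_origin_doy + int(col)


@dataclass
class HarrisResponse:
    """Per-pixel Harris corner measure aligned to its source CurveImage."""

    response: np.ndarray
    image: CurveImage
    k: float
    sigma: float


@dataclass
class DominantPointSet:
    """Ordered corner-point DOYs with the per-point Harris response."""

    doys: np.ndarray
    source: str  # LAI | RATIO | MERGED
    response: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doys, dtype=int)
        if d.size and np.any(np.diff(d) <= 0):
            raise InputError("dominant-point DOYs must increase strictly")
        object.__setattr__(self, "doys", d)
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))

    def __len__(self) -> int:
        return len(self.doys)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"doy": self.doys, "source": self.source,
                      "response": self.response}).to_csv(path, index=False)


def rasterize_curve(series: Sequence[float], y_step: float = 0.001,
                    x_origin_doy: int = 0, pad_rows: int = _PAD_ROWS) -> CurveImage:
    """Render a per-day series as a binary image with a connected polyline.

    Consecutive days are joined by a one-pixel line (Bresenham), so the
    drawn curve is 8-connected and gradients exist along its whole length.
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InputError("rasterize_curve needs a 1-D series of >= 2 days")
    if not np.all(np.isfinite(v)):
        raise InputError("rasterize_curve: series contains non-finite values")
    if y_step <= 0:
        raise InputError("y_step must be positive")
    y_origin = float(v.min() - pad_rows * y_step)
    rows = np.rint((v - y_origin) / y_step).astype(int)
    img = np.zeros((int(rows.max()) + 1 + pad_rows, len(v)))
    img[rows[0], 0] = 1.0
    for j in range(1, len(v)):
        rr, cc = _draw_line(rows[j - 1], j - 1, rows[j], j)
        img[rr, cc] = 1.0
    return CurveImage(img, x_origin_doy, y_step, y_origin)


def gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    """Normalized isotropic Gaussian on a size x size centered lattice."""
    if size % 2 == 0 or size < 3:
        raise InputError("kernel size must be odd and >= 3")
    if sigma <= 0:
        raise InputError("sigma must be positive")
    r = size // 2
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    g = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    return g / g.sum()


def smooth(image: CurveImage, kernel: np.ndarray) -> CurveImage:
    """Convolve the curve image with a normalized kernel (reflective border)."""
    if kernel.shape[0] > image.pixels.shape[0] or kernel.shape[1] > image.pixels.shape[1]:
        raise InputError("smoothing kernel larger than the image")
    if not np.isclose(kernel.sum(), 1.0):
        raise InputError("smoothing kernel must be normalized to sum 1")
    out = ndimage.convolve(image.pixels, kernel, mode="reflect")
    np.clip(out, 0.0, 1.0, out=out)
    return CurveImage(out, image.x_origin_doy, image.y_step, image.y_origin)


def harris_response(image: CurveImage, k: float = 0.04,
                    sigma_deriv: float = 1.0, sigma_window: float = 3.0,
                    window: int = 9) -> HarrisResponse:
    """Harris corner measure from Gaussian derivatives and window averaging.

    Gradients Ix, Iy come from Gaussian-derivative filters at
    ``sigma_deriv``; the products Ix^2, Iy^2, IxIy are averaged with a
    ``window`` x ``window`` Gaussian at ``sigma_window`` to form the
    structure tensor, and R = det(M) - k * trace(M)^2.
    """
    if not 0.04 <= k <= 0.06:
        raise ParameterError("Harris k must lie in [0.04, 0.06]")
    px = image.pixels
    ix = ndimage.gaussian_filter(px, sigma_deriv, order=(0, 1), mode="reflect")
    iy = ndimage.gaussian_filter(px, sigma_deriv, order=(1, 0), mode="reflect")
    g = gaussian_kernel(sigma_window, window)
    axx = ndimage.convolve(ix * ix, g, mode="reflect")
    ayy = ndimage.convolve(iy * iy, g, mode="reflect")
    axy = ndimage.convolve(ix * iy, g, mode="reflect")
    r = (axx * ayy - axy * axy) - k * (axx + ayy) ** 2
    return HarrisResponse(r, image, k, sigma_window)


def detect_dominant_points(response: HarrisResponse, window: int = 9,
                           rel_threshold: float = 0.01) -> DominantPointSet:
    """Report days whose pixels are local Harris maxima.

    A pixel survives if it is the maximum of R over its window x window
    neighborhood and exceeds ``rel_threshold`` times the largest interior
    response (suppressing numerically-zero maxima on flat background).
    Pixels within half a window of the left/right image border are not
    reported (their neighborhood is truncated).  If several rows of one
    column qualify, the highest-R row wins; points within ``window``
    columns of each other are merged to the higher-R one.
    """
    if window % 2 == 0 or window < 3:
        raise InputError("window must be odd and >= 3")
    r = response.response
    margin = window // 2 + 1
    if r.shape[1] <= 2 * margin:
        return DominantPointSet(np.array([], int), "LAI", np.array([]))
    interior = np.full_like(r, -np.inf)
    interior[:, margin:-margin] = r[:, margin:-margin]
    peak = interior.max()
    if not np.isfinite(peak) or peak <= 0:
        return DominantPointSet(np.array([], int), "LAI", np.array([]))
    thr = rel_threshold * peak
    local_max = r >= ndimage.maximum_filter(r, size=window, mode="reflect")
    cand = np.argwhere(local_max & (interior > thr))

    best_row: dict[int, int] = {}
    for i, j in cand:
        if j not in best_row or r[i, j] > r[best_row[j], j]:
            best_row[j] = i
    merged: list[tuple[int, int]] = []  # (col, row)
    for j in sorted(best_row):
        i = best_row[j]
        if merged and j - merged[-1][0] < window:
            if r[i, j] > r[merged[-1][1], merged[-1][0]]:
                merged[-1] = (j, i)
        else:
            merged.append((j, i))
    doys = np.array([response.image.col_to_doy(j) for j, _ in merged], int)
    vals = np.array([r[i, j] for j, i in merged])
    return DominantPointSet(doys, "LAI", vals)


def ratio_curve(lai_stressed: Sequence[float], lai_reference: Sequence[float],
                epsilon: float = 0.05) -> tuple[np.ndarray, int]:
    """Elementwise stressed/reference LAI ratio.

    Days at either end where the reference canopy is below ``epsilon``
    (ratio ill-defined on a bare field) are trimmed; returns the trimmed
    ratio and the index offset of its first retained day.
    """
    s = np.asarray(lai_stressed, dtype=float)
    rf = np.asarray(lai_reference, dtype=float)
    if s.shape != rf.shape:
        raise InputError("ratio_curve needs aligned series of equal length")
    valid = rf >= epsilon
    if not valid.any():
        raise InputError("reference LAI below epsilon everywhere")
    first = int(np.argmax(valid))
    last = len(rf) - int(np.argmax(valid[::-1]))
    return s[first:last] / rf[first:last], first


def growth_rate(series: Sequence[float]) -> np.ndarray:
    """First differences of a per-day series, aligned to the later day."""
    v = np.asarray(series, dtype=float)
    if len(v) < 2:
        raise InputError("growth_rate needs >= 2 points")
    return np.diff(v)


def _rate_change(gr: np.ndarray, gr_start_doy: int, doy: int,
                 half_window: int = 3) -> float:
    """|growth-rate change| across a +-half_window-day window around doy."""
    i = doy - gr_start_doy
    lo = max(0, i - half_window)
    hi = min(len(gr) - 1, i + half_window)
    if hi <= lo:
        return 0.0
    return abs(float(gr[hi] - gr[lo]))


def screen_points(points_lai: DominantPointSet, points_ratio: DominantPointSet,
                  gr_lai: np.ndarray, gr_start_doy: int,
                  match_tol: int = 2, compete_window: int = 30) -> DominantPointSet:
    """Merge the LAI-curve and ratio-curve point sets into the key period.

    Points of the two sets coincident within ``match_tol`` days are kept
    once.  Each remaining point is paired with the nearest unpaired point
    of the other set; if the pair lies within ``compete_window`` days the
    two are alternative locations of the same feature and the one with the
    larger LAI growth-rate change (over a +-3-day window) survives, ties
    going to the LAI-curve point.  Points with no competitor are kept.
    """
    if len(points_lai) == 0 or len(points_ratio) == 0:
        raise InputError("screen_points needs two non-empty point sets")
    lai_pts = list(points_lai.doys)
    ratio_pts = list(points_ratio.doys)
    kept: list[int] = []
    unmatched_ratio = ratio_pts.copy()
    unmatched_lai = []
    for a in lai_pts:
        hit = next((b for b in unmatched_ratio if abs(a - b) <= match_tol), None)
        if hit is not None:
            kept.append(a)
            unmatched_ratio.remove(hit)
        else:
            unmatched_lai.append(a)
    # proximity pairing of the leftovers
    for a in unmatched_lai:
        near = [b for b in unmatched_ratio if abs(a - b) <= compete_window]
        if not near:
            kept.append(a)
            continue
        b = min(near, key=lambda x: abs(a - x))
        unmatched_ratio.remove(b)
        da = _rate_change(gr_lai, gr_start_doy, a)
        db = _rate_change(gr_lai, gr_start_doy, b)
        kept.append(a if da >= db else b)  # tie -> LAI-curve point
    kept.extend(unmatched_ratio)
    doys = np.array(sorted(set(kept)), int)
    return DominantPointSet(doys, "MERGED", np.full(len(doys), np.nan))


def select_images(available_dates: Sequence[int],
                  key_points: DominantPointSet | Sequence[int]) -> list[int]:
    """Nearest available acquisition date for each key point (ties: earlier)."""
    avail = sorted(set(int(d) for d in available_dates))
    if not avail:
        raise InputError("select_images needs at least one available date")
    points = key_points.doys if isinstance(key_points, DominantPointSet) else key_points
    chosen = set()
    for p in points:
        best = min(avail, key=lambda d: (abs(d - int(p)), d))
        chosen.add(best)
    return sorted(chosen)


def fit_dominant_points(series: Sequence[float], start_doy: int,
                        points: DominantPointSet | Sequence[int]
                        ) -> tuple[np.ndarray, float]:
    """Piecewise-linear fit through the dominant points; returns (fit, R^2).

    The series endpoints are always included as anchors; R^2 is the squared
    Pearson correlation between the fitted and original series.
    """
    from .assimilation import r_squared

    v = np.asarray(series, dtype=float)
    doys = np.arange(start_doy, start_doy + len(v))
    pts = points.doys if isinstance(points, DominantPointSet) else np.asarray(points, int)
    anchors = np.unique(np.concatenate([[doys[0], doys[-1]], pts]))
    if np.any((anchors < doys[0]) | (anchors > doys[-1])):
        raise InputError("dominant points outside the series range")
    anchor_vals = v[anchors - start_doy]
    fitted = np.interp(doys, anchors, anchor_vals)
    return fitted, r_squared(fitted, v)


def auto_y_step(series: Sequence[float], target_max_slope: float = 10.0) -> float:
    """Rasterization step making the steepest day-to-day move ~target px.

    Keeps the rendered curve's aspect in the range where a 9 x 9 Harris
    window can see orientation change at a bend; falls back to 1e-3 for a
    constant series.
    """
    d = np.abs(np.diff(np.asarray(series, dtype=float)))
    m = float(d.max()) if len(d) else 0.0
    return m / target_max_slope if m > 0 else 1e-3


def find_dominant_points(series: Sequence[float], start_doy: int,
                         y_step: float | None = None,
                         smooth_sigma: float = 1.0, smooth_size: int = 9,
                         k: float = 0.04, sigma_deriv: float = 1.0,
                         sigma_window: float = 3.0, window: int = 9,
                         rel_threshold: float = 0.01,
                         source: str = "LAI") -> DominantPointSet:
    """Full curve-to-points chain: rasterize, smooth, Harris, detect.

    ``y_step=None`` selects the adaptive step of :func:`auto_y_step`.
    """
    if y_step is None:
        y_step = auto_y_step(series)
    img = rasterize_curve(series, y_step, x_origin_doy=start_doy)
    img = smooth(img, gaussian_kernel(smooth_sigma, smooth_size))
    resp = harris_response(img, k=k, sigma_deriv=sigma_deriv,
                           sigma_window=sigma_window, window=window)
    pts = detect_dominant_points(resp, window=window, rel_threshold=rel_threshold)
    pts.source = source
    return pts


def save_image_png(image_or_response, path: str | Path) -> None:
    """Dump a CurveImage or HarrisResponse as an 8-bit PNG for inspection."""
    import imageio.v3 as iio

    arr = (image_or_response.pixels if isinstance(image_or_response, CurveImage)
           else image_or_response.response)
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled[::-1] * 255).astype(np.uint8))
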