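"""Clot-waveform digitizer: recover a turbidity curve from a plot raster.

Clinical analyzers export clot waveforms as plots with fixed axis ranges
(time 0-60 s, transmitted light 0-4000 mA).  Given a grayscale raster and
an explicit axis calibration (the pixel box of the plot area and the data
ranges it spans), the extractor scans each time column for dark "curve"
pixels and maps their darkness-weighted centroid row back to mA.  Columns
where the curve is missing (gridline gaps, dashed styles) are filled by
linear interpolation from neighboring columns, capped at 20% of columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from clotwave.waveform import Waveform, WaveformError


class ExtractionError(ValueError):
    """Curve extraction failed."""


@dataclass(frozen=True)
class AxisCalibration:
    """Pixel box of the plot area and the data ranges it spans.

    ``left``/``right`` are inclusive pixel columns, ``top``/``bottom``
    inclusive pixel rows of the plot interior.  ``y_increases_downward``
    reflects raster convention: the top row maps to ``light_range[1]``.
    """

    left: int
    top: int
    right: int
    bottom: int
    t_range: tuple = (0.0, 60.0)
    light_range: tuple = (0.0, 4000.0)
    y_increases_downward: bool = True

    def __post_init__(self) -> None:
        if not (self.right > self.left and self.bottom > self.top):
            raise ExtractionError("degenerate plot box")
        if not (self.t_range[1] > self.t_range[0]
                and self.light_range[1] > self.light_range[0]):
            raise ExtractionError("axis ranges must be increasing")

    def col_of_time(self, t: float) -> float:
        t0, t1 = self.t_range
        return self.left + (t - t0) / (t1 - t0) * (self.right - self.left)

    def value_of_row(self, row: float) -> float:
        v0, v1 = self.light_range
        frac = (row - self.top) / (self.bottom - self.top)
        if self.y_increases_downward:
            return v1 - frac * (v1 - v0)
        return v0 + frac * (v1 - v0)


def extract_curve(img: np.ndarray, cal: AxisCalibration,
                  dark_threshold: Optional[float] = None,
                  max_gap_frac: float = 0.20) -> Waveform:
    """Extract the curve from a grayscale plot raster.

    Parameters
    ----------
    img : 2-D array
        Grayscale intensities, 0 = black.  Any numeric range is accepted.
    cal : AxisCalibration
        Plot-box geometry and axis ranges.
    dark_threshold : float, optional
        Pixels strictly darker than this count as curve; default is an
        Otsu split of the plot-box intensities.

    Returns a transparency waveform on t = 0..60 s (or the integer grid
    spanning ``cal.t_range``), values within ``cal.light_range``.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ExtractionError("image must be a nonempty 2-D grayscale array")
    if not (0 <= cal.left and cal.right < img.shape[1]
            and 0 <= cal.top and cal.bottom < img.shape[0]):
        raise ExtractionError("plot box outside image bounds")
    box = img[cal.top:cal.bottom + 1, cal.left:cal.right + 1]
    if dark_threshold is None:
        if np.ptp(box) == 0:
            raise ExtractionError("blank image: no contrast in plot box")
        dark_threshold = float(threshold_otsu(box))
    if not np.any(box < dark_threshold):
        raise ExtractionError("no pixels darker than threshold in plot box")

    t0, t1 = cal.t_range
    t_grid = np.arange(int(round(t0)), int(round(t1)) + 1, dtype=float)
    rows = np.arange(cal.top, cal.bottom + 1, dtype=float)
    values = np.full(t_grid.size, np.nan)
    for i, t in enumerate(t_grid):
        col = int(round(cal.col_of_time(t)))
        col = min(max(col, cal.left), cal.right)
        column = img[cal.top:cal.bottom + 1, col]
        dark = column < dark_threshold
        if not np.any(dark):
            continue
        weights = dark_threshold - column[dark]   # darker pixels weigh more
        if weights.sum() <= 0:
            weights = np.ones(dark.sum())
        row_c = float(np.average(rows[dark], weights=weights))
        values[i] = cal.value_of_row(row_c)

    missing = np.isnan(values)
    if missing.all() or missing.mean() > max_gap_frac:
        raise ExtractionError(
            f"{int(missing.sum())}/{missing.size} columns without curve "
            f"pixels exceeds the {max_gap_frac:.0%} gap limit")
    if missing.any():
        values[missing] = np.interp(t_grid[missing], t_grid[~missing],
                                    values[~missing])
    values = np.clip(values, cal.light_range[0], cal.light_range[1])
    return Waveform(times=t_grid, values=values, kind="transparency")


def render_curve(times: np.ndarray, values: np.ndarray,
                 cal: AxisCalibration, shape: tuple,
                 stroke: int = 3, background: float = 255.0,
                 ink: float = 0.0) -> np.ndarray:
    """Rasterize a curve into a synthetic plot image (testing aid).

    The inverse of :func:`extract_curve` up to pixel quantization: for a
    dense sweep of times, the nearest pixel column gets a vertical stroke
    of ``stroke`` pixels centered on the curve row.
    """
    img = np.full(shape, background, dtype=float)
    t_dense = np.linspace(times[0], times[-1],
                          (cal.right - cal.left + 1) * 4)
    v_dense = np.interp(t_dense, times, values)
    half = stroke // 2
    v0, v1 = cal.light_range
    for t, v in zip(t_dense, v_dense):
        col = int(round(cal.col_of_time(t)))
        if not (cal.left <= col <= cal.right):
            continue
        frac = (v - v0) / (v1 - v0)
        if cal.y_increases_downward:
            row = cal.bottom - frac * (cal.bottom - cal.top)
        else:
            row = cal.top + frac * (cal.bottom - cal.top)
        r = int(round(row))
        lo = max(cal.top, r - half)
        hi = min(cal.bottom, r + half)
        img[lo:hi + 1, col] = ink
    return img
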