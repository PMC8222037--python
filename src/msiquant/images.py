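"""Ion-image extraction from centroided spectra.

An ion image maps each raster pixel to the summed centroid intensity
inside a fixed, symmetric, closed m/z window around a target.  Window
half-width defaults to 0.005 Da, the extraction tolerance used
throughout this workflow.  Unscanned pixels are NaN (missing), which is
deliberately distinct from 0 (scanned, no peak in the window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .grid import SpectrumGrid

__all__ = [
    "IonImage",
    "extract_ion_image",
    "log_transform",
    "lock_mass_recalibrate",
    "RecalibrationReport",
]


@dataclass
class IonImage:
    """2-D intensity map for one target m/z window.

    ``values`` is float ``[row, col]``; NaN marks pixels with no value
    (unscanned, or below detection after the log transform).  On
    log-scale images ``below_detection`` flags scanned pixels whose
    linear intensity was exactly 0.
    """

    values: np.ndarray
    target_mz: float
    tolerance: float
    transform: str = "linear"  # or "log10"
    provenance: str = ""
    below_detection: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("IonImage values must be 2-D")
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.transform not in ("linear", "log10"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def finite_values(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]


def extract_ion_image(
    grid: SpectrumGrid,
    target_mz: float,
    tolerance: float = 0.005,
    agg: str = "sum",
    provenance: str = "",
) -> IonImage:
    """Extract the ion image for ``target_mz`` +/- ``tolerance`` (closed window).

    Within-window centroids are aggregated by ``agg`` ("sum", the
    default, is robust to centroid splitting; "max" is provided as an
    alternative).  A centroid at exactly ``target_mz +/- tolerance`` is
    included.  Raises ``ValueError`` if the target lies outside the
    grid's declared m/z range.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    lo_r, hi_r = grid.mz_range
    if not (lo_r <= target_mz <= hi_r):
        raise ValueError(
            f"target m/z {target_mz} outside dataset range [{lo_r}, {hi_r}]"
        )
    if agg not in ("sum", "max"):
        raise ValueError(f"agg must be 'sum' or 'max', got {agg!r}")

    values = np.full(grid.shape, np.nan)
    x0, _, y0, _ = grid.bounds
    lo, hi = target_mz - tolerance, target_mz + tolerance
    for p in grid.pixels:
        i = np.searchsorted(p.mz, lo, side="left")
        j = np.searchsorted(p.mz, hi, side="right")
        window = p.intensity[i:j]
        if agg == "sum":
            v = float(window.sum()) if window.size else 0.0
        else:
            v = float(window.max()) if window.size else 0.0
        values[p.y - y0, p.x - x0] = v
    return IonImage(values, float(target_mz), float(tolerance), "linear", provenance)


def log_transform(img: IonImage) -> IonImage:
    """log10-transform a linear ion image.

    Positive pixels map to log10(value); zero pixels (scanned, nothing
    detected) become NaN and are flagged below-detection rather than
    being pseudo-counted; missing pixels stay missing.  Applying the
    transform twice is an error.
    """
    if img.transform != "linear":
        raise ValueError("image is already log10-transformed")
    out = np.full(img.values.shape, np.nan)
    pos = np.nan_to_num(img.values, nan=-1.0) > 0
    out[pos] = np.log10(img.values[pos])
    below = (~np.isnan(img.values)) & ~pos
    return IonImage(
        out, img.target_mz, img.tolerance, "log10", img.provenance, below_detection=below
    )


@dataclass
class RecalibrationReport:
    n_pixels: int
    n_shifted: int
    median_shift_da: float
    shifts: np.ndarray = field(repr=False, default=None)


def lock_mass_recalibrate(
    grid: SpectrumGrid,
    lock_mz: float = 195.0657,
    search_window: float = 0.01,
) -> Tuple[SpectrumGrid, RecalibrationReport]:
    """Shift each pixel's m/z axis so its lock-mass peak lands on ``lock_mz``.

    Per pixel, the most intense centroid within ``search_window`` of the
    lock mass (the protonated ferulic-acid matrix ion by default) defines
    an additive shift ``lock_mz - observed`` applied to the whole axis.
    Pixels without a lock peak are left untouched and counted in the
    report.  The instrument usually applies this online; the operation is
    provided for data acquired without it.
    """
    if search_window <= 0:
        raise ValueError("search_window must be > 0")
    from .grid import Pixel

    new_pixels = []
    shifts = []
    for p in grid.pixels:
        i = np.searchsorted(p.mz, lock_mz - search_window, side="left")
        j = np.searchsorted(p.mz, lock_mz + search_window, side="right")
        if j > i:
            k = i + int(np.argmax(p.intensity[i:j]))
            shift = lock_mz - p.mz[k]
            shifts.append(shift)
            new_pixels.append(Pixel(p.x, p.y, p.mz + shift, p.intensity.copy()))
        else:
            new_pixels.append(Pixel(p.x, p.y, p.mz.copy(), p.intensity.copy()))
    lo, hi = grid.mz_range
    pad = max((abs(s) for s in shifts), default=0.0)
    out = SpectrumGrid(
        pixels=new_pixels,
        pixel_size=grid.pixel_size,
        mz_range=(lo - pad, hi + pad),
        polarity=grid.polarity,
        metadata=dict(grid.metadata),
    )
    report = RecalibrationReport(
        n_pixels=len(grid.pixels),
        n_shifted=len(shifts),
        median_shift_da=float(np.median(shifts)) if shifts else 0.0,
        shifts=np.asarray(shifts),
    )
    return out, report
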