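"""Pixel-indexed centroided spectra with spatial coordinates.

The core in-memory container for an MSI dataset: one centroid list
(m/z, intensity) per scanned raster position.  Coordinates follow the
imzML convention — 1-based, ``x`` is the column and ``y`` the row.
Images derived from a grid are indexed ``[row, col]`` with
``row = y - y_min`` and ``col = x - x_min``; missing pixels (sparse
rasters) are permitted and are distinct from scanned-but-empty pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

__all__ = ["Pixel", "SpectrumGrid"]


@dataclass
class Pixel:
    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class SpectrumGrid:
    """Centroided MSI dataset: per-pixel peak lists plus acquisition metadata.

    Invariants (checked by :meth:`validate`): m/z arrays strictly
    ascending within each pixel, equal-length m/z / intensity arrays,
    non-negative intensities, unique coordinates, all m/z inside the
    declared ``mz_range``.
    """

    pixels: List[Pixel]
    pixel_size: Tuple[float, float] = (400.0, 400.0)  # um
    mz_range: Tuple[float, float] = (185.0, 650.0)
    polarity: str = "positive"
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        lo, hi = self.mz_range
        for p in self.pixels:
            p.mz = np.asarray(p.mz, dtype=float)
            p.intensity = np.asarray(p.intensity, dtype=float)
            if p.mz.shape != p.intensity.shape or p.mz.ndim != 1:
                raise ValueError(f"pixel ({p.x},{p.y}): mz/intensity arrays must be 1-D and equal length")
            if p.mz.size and np.any(np.diff(p.mz) <= 0):
                raise ValueError(f"pixel ({p.x},{p.y}): m/z array not strictly ascending")
            if p.intensity.size and np.any(p.intensity < 0):
                raise ValueError(f"pixel ({p.x},{p.y}): negative intensity")
            if p.mz.size and (p.mz[0] < lo or p.mz[-1] > hi):
                raise ValueError(
                    f"pixel ({p.x},{p.y}): m/z outside declared range [{lo}, {hi}]"
                )
            if (p.x, p.y) in seen:
                raise ValueError(f"duplicate pixel coordinate ({p.x},{p.y})")
            if p.x < 1 or p.y < 1:
                raise ValueError(f"coordinates are 1-based; got ({p.x},{p.y})")
            seen.add((p.x, p.y))

    def __len__(self) -> int:
        return len(self.pixels)

    def __iter__(self) -> Iterator[Pixel]:
        return iter(self.pixels)

    @property
    def bounds(self) -> Tuple[int, int, int, int]:
        """(x_min, x_max, y_min, y_max) over scanned pixels."""
        xs = [p.x for p in self.pixels]
        ys = [p.y for p in self.pixels]
        return min(xs), max(xs), min(ys), max(ys)

    @property
    def shape(self) -> Tuple[int, int]:
        """(n_rows, n_cols) of the raster bounding box."""
        x0, x1, y0, y1 = self.bounds
        return y1 - y0 + 1, x1 - x0 + 1

    def pixel_index(self, p: Pixel) -> Tuple[int, int]:
        """(row, col) position of a pixel inside the bounding box."""
        x0, _, y0, _ = self.bounds
        return p.y - y0, p.x - x0

    def scanned_mask(self) -> np.ndarray:
        """Boolean [row, col] mask of raster positions that were scanned."""
        x0, _, y0, _ = self.bounds
        mask = np.zeros(self.shape, dtype=bool)
        for p in self.pixels:
            mask[p.y - y0, p.x - x0] = True
        return mask

    def common_mz_axis(self) -> Optional[np.ndarray]:
        """The shared m/z axis if all pixels use one, else ``None``."""
        if not self.pixels:
            return None
        first = self.pixels[0].mz
        for p in self.pixels[1:]:
            if p.mz.shape != first.shape or not np.array_equal(p.mz, first):
                return None
        return first
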