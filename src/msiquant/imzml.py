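"""imzML 1.1 reading and writing, backed by pyimzml.

Adds the integrity checks the parser itself does not perform: the ibd
file must start with the same 16-byte UUID the imzML header declares,
the ibd SHA-1 must match when present, and profile-mode data are
rejected (this pipeline consumes centroided spectra only).
"""

from __future__ import annotations

import hashlib
import os
import uuid as _uuid
from typing import Union

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

from .grid import Pixel, SpectrumGrid

__all__ = ["read_imzml", "write_imzml", "ImzmlIntegrityError"]


class ImzmlIntegrityError(ValueError):
    """imzML/ibd pair is inconsistent (UUID or checksum mismatch)."""


def _file_param(parser: ImzMLParser, name: str):
    try:
        return parser.metadata.file_description.param_by_name[name]
    except (AttributeError, KeyError):
        return None


def read_imzml(path: Union[str, os.PathLike], validate_checksum: bool = True) -> SpectrumGrid:
    """Load a centroided imzML/ibd pair into a :class:`SpectrumGrid`.

    Both continuous and processed binary modes are accepted.  Raises
    ``FileNotFoundError`` for a missing ibd, :class:`ImzmlIntegrityError`
    for UUID/SHA-1 mismatches, and ``ValueError`` for profile-mode data.
    """
    path = os.fspath(path)
    ibd_path = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd_path):
        raise FileNotFoundError(f"sibling ibd file not found: {ibd_path}")

    parser = ImzMLParser(path)
    try:
        if _file_param(parser, "profile spectrum") is not None:
            raise ValueError(
                "profile-mode imzML is not supported; supply centroided data"
            )

        declared = _file_param(parser, "universally unique identifier")
        if declared is not None:
            with open(ibd_path, "rb") as fh:
                ibd_uuid = _uuid.UUID(bytes=fh.read(16))
            header_uuid = _uuid.UUID(str(declared).strip("{}"))
            if ibd_uuid != header_uuid:
                raise ImzmlIntegrityError(
                    f"UUID mismatch: imzML declares {header_uuid}, ibd contains {ibd_uuid}"
                )

        declared_sha = _file_param(parser, "ibd SHA-1")
        if validate_checksum and declared_sha is not None:
            sha = hashlib.sha1()
            with open(ibd_path, "rb") as fh:
                for chunk in iter(lambda: fh.read(1 << 20), b""):
                    sha.update(chunk)
            if sha.hexdigest().lower() != str(declared_sha).lower():
                raise ImzmlIntegrityError(
                    f"ibd SHA-1 mismatch: imzML declares {declared_sha}, "
                    f"file hashes to {sha.hexdigest()}"
                )

        pixels = []
        mz_lo, mz_hi = np.inf, -np.inf
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mz, inten = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.size and np.any(np.diff(mz) <= 0):
                raise ValueError(
                    f"pixel ({x},{y}): non-ascending m/z array; refusing to reorder silently"
                )
            if mz.size:
                mz_lo = min(mz_lo, mz[0])
                mz_hi = max(mz_hi, mz[-1])
            pixels.append(Pixel(int(x), int(y), mz, inten))

        if not pixels:
            raise ValueError(f"no spectra found in {path}")
        if not np.isfinite(mz_lo):
            mz_lo, mz_hi = 0.0, 1.0
        polarity = parser.polarity or "positive"
        meta = {"source": path}
        grid = SpectrumGrid(
            pixels=pixels,
            mz_range=(float(mz_lo), float(mz_hi)),
            polarity=polarity,
            metadata=meta,
        )
        return grid
    finally:
        # pyimzml keeps the ibd handle open on the parser
        if getattr(parser, "m", None) is not None:
            parser.m.close()


def write_imzml(
    grid: SpectrumGrid,
    path: Union[str, os.PathLike],
    mode: str = "processed",
    dtype: str = "float64",
) -> str:
    """Write a grid as an imzML/ibd pair; returns the imzML path.

    ``mode="continuous"`` requires all pixels to share one m/z axis.
    ``dtype`` controls binary encoding of both arrays ("float32" or
    "float64"); float64 round-trips bit-exactly.
    """
    path = os.fspath(path)
    if mode not in ("continuous", "processed"):
        raise ValueError(f"mode must be 'continuous' or 'processed', got {mode!r}")
    if mode == "continuous" and grid.common_mz_axis() is None:
        raise ValueError("continuous mode requires a single shared m/z axis across pixels")
    np_dtype = {"float32": np.float32, "float64": np.float64}.get(dtype)
    if np_dtype is None:
        raise ValueError(f"dtype must be 'float32' or 'float64', got {dtype!r}")

    grid.validate()
    for p in grid.pixels:
        if p.mz.size == 0:
            raise ValueError(
                f"pixel ({p.x},{p.y}) has an empty peak list; imzML cannot "
                "encode empty spectra — drop the pixel (sparse raster) instead"
            )
    with ImzMLWriter(
        path,
        mode=mode,
        polarity=grid.polarity,
        mz_dtype=np_dtype,
        intensity_dtype=np_dtype,
    ) as writer:
        for p in grid.pixels:
            writer.addSpectrum(p.mz, p.intensity, (p.x, p.y, 1))
    return path
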